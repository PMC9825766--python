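"""Dataset construction: parsing, filtering, labeling, GC matching, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from loopnet.interactions import (
    CandidateInteraction, FormatError, GenomicAnchor, InsufficientPoolError,
    build_labeled_dataset, deduplicate_interactions, filter_interactions,
    label_by_fdr, parse_interactions, sample_gc_matched_negatives,
    split_dataset, standardize_anchor, standardize_interactions,
)

from conftest import make_candidate


# ---------------------------------------------------------------------------
# parsing


def write_table(tmp_path, rows, name="inter.tsv"):
    path = tmp_path / name
    path.write_text("".join(rows))
    return path


def test_parse_maps_fields(tmp_path):
    path = write_table(tmp_path, ["chr1\t10000\t12000\tchr1\t60000\t62000\t0.02\n"])
    cands = parse_interactions(path, tissue="GM", itype="PE")
    assert len(cands) == 1
    c = cands[0]
    assert (c.anchor1.chrom, c.anchor1.start, c.anchor1.end) == ("chr1", 10000, 12000)
    assert (c.anchor2.start, c.anchor2.end) == (60000, 62000)
    assert c.fdr == 0.02 and c.tissue == "GM" and c.itype == "PE"


def test_parse_empty_file_and_comments(tmp_path):
    assert parse_interactions(write_table(tmp_path, [])) == []
    path = write_table(tmp_path, ["# comment\n", "\n"], name="c.tsv")
    assert parse_interactions(path) == []


def test_parse_bad_fdr_names_line(tmp_path):
    path = write_table(tmp_path, [
        "chr1\t0\t2000\tchr1\t5000\t7000\t0.5\n",
        "chr1\t0\t2000\tchr1\t5000\t7000\t1.5\n",
    ])
    with pytest.raises(FormatError, match=":2"):
        parse_interactions(path)


def test_parse_missing_columns(tmp_path):
    path = write_table(tmp_path, ["chr1\t0\t2000\tchr1\t5000\n"])
    with pytest.raises(FormatError, match="columns"):
        parse_interactions(path)


# ---------------------------------------------------------------------------
# filtering and standardization


def test_filter_distance_boundary():
    keep_eq = make_candidate(dist=1_000_000)
    drop_gt = make_candidate(dist=1_000_001)
    inter = CandidateInteraction(
        GenomicAnchor("chr1", 0, 2000), GenomicAnchor("chr2", 0, 2000), 0.05
    )
    out = filter_interactions([keep_eq, drop_gt, inter])
    assert out == [keep_eq]


def test_filter_preserves_order_and_is_monotone():
    rng = np.random.default_rng(0)
    cands = [make_candidate(dist=int(d)) for d in rng.integers(1000, 2_000_000, size=200)]
    low = filter_interactions(cands, max_distance=500_000)
    high = filter_interactions(cands, max_distance=1_500_000)
    assert set(map(id, low)) <= set(map(id, high))
    high_ids = set(map(id, high))
    assert [id(c) for c in cands if id(c) in high_ids] == [id(c) for c in high]  # order kept


def test_standardize_examples():
    out = standardize_anchor(GenomicAnchor("chr1", 10_000, 14_000))
    assert (out.start, out.end) == (11_000, 13_000)
    fixed = standardize_anchor(GenomicAnchor("chr1", 0, 2000))
    assert (fixed.start, fixed.end) == (0, 2000)
    with pytest.raises(ValueError):
        standardize_anchor(GenomicAnchor("chr1", 500, 700))


def test_standardize_odd_length_uses_floor():
    out = standardize_anchor(GenomicAnchor("chr1", 10_000, 10_005))
    assert out.midpoint == 10_002
    assert out.end - out.start == 2000


def test_standardize_drops_chromosome_end_overhang():
    c = make_candidate(mid1=10_000, dist=20_000)
    kept = standardize_interactions([c], chrom_sizes={"chr1": 30_500})
    assert kept == []
    kept = standardize_interactions([c], chrom_sizes={"chr1": 40_000})
    assert len(kept) == 1 and kept[0].anchor1.length == 2000


# ---------------------------------------------------------------------------
# labeling


@pytest.mark.parametrize("pos_cut,neg_cut", [(0.1, 0.5), (0.05, 0.5), (0.1, 0.7), (0.1, 0.9)])
def test_label_by_fdr_regimes(pos_cut, neg_cut):
    cands = [make_candidate(fdr=f) for f in (0.04, 0.05, 0.3, 0.6, 0.71, 0.95)]
    pos, pool = label_by_fdr(cands, pos_cut, neg_cut)
    assert all(c.fdr < pos_cut for c in pos)
    assert all(c.fdr > neg_cut for c in pool)
    assert len(pos) + len(pool) <= len(cands)


def test_label_by_fdr_examples_and_errors():
    pos, pool = label_by_fdr([make_candidate(fdr=0.05), make_candidate(fdr=0.6),
                              make_candidate(fdr=0.3)])
    assert [c.fdr for c in pos] == [0.05]
    assert [c.fdr for c in pool] == [0.6]
    with pytest.raises(ValueError):
        label_by_fdr([], pos_cut=0.6, neg_cut=0.5)


def test_deduplicate_keeps_smallest_fdr():
    a = make_candidate(fdr=0.3)
    b = make_candidate(fdr=0.05)
    c = make_candidate(mid1=50_000, fdr=0.2)
    out = deduplicate_interactions([a, b, c])
    assert len(out) == 2 and out[0].fdr == 0.05 and out[1] is c


# ---------------------------------------------------------------------------
# GC-matched negatives


def test_gc_matching_exhaustive_two_level_pool():
    positives = [make_candidate(fdr=0.01) for _ in range(50)]
    pos_gc = [0.5] * 50
    pool = [make_candidate(fdr=0.9) for _ in range(200)]
    pool_gc = [0.2] * 100 + [0.5] * 100
    negs, neg_gc = sample_gc_matched_negatives(positives, pool, pos_gc, pool_gc, seed=0)
    assert len(negs) == 50
    assert all(g == 0.5 for g in neg_gc)


@pytest.mark.parametrize("ratio", [1, 5])
def test_gc_matching_ratio(ratio):
    rng = np.random.default_rng(3)
    positives = [make_candidate(fdr=0.01) for _ in range(40)]
    pos_gc = rng.uniform(0.3, 0.7, size=40)
    pool = [make_candidate(fdr=0.9) for _ in range(400)]
    pool_gc = rng.uniform(0.3, 0.7, size=400)
    negs, _ = sample_gc_matched_negatives(positives, pool, pos_gc, pool_gc, ratio=ratio, seed=1)
    assert len(negs) == ratio * 40


def test_gc_matching_insufficient_pool():
    positives = [make_candidate(fdr=0.01) for _ in range(10)]
    pool = [make_candidate(fdr=0.9) for _ in range(5)]
    with pytest.raises(InsufficientPoolError, match="deficit"):
        sample_gc_matched_negatives(positives, pool, [0.5] * 10, [0.5] * 5, seed=0)


def test_gc_matching_deterministic_and_distribution_matched():
    rng = np.random.default_rng(7)
    n_pos, n_pool = 1000, 5000
    positives = [make_candidate(fdr=0.01) for _ in range(n_pos)]
    pos_gc = rng.uniform(0.35, 0.65, size=n_pos)
    pool = [make_candidate(fdr=0.9) for _ in range(n_pool)]
    pool_gc = rng.uniform(0.3, 0.7, size=n_pool)
    negs1, gc1 = sample_gc_matched_negatives(positives, pool, pos_gc, pool_gc, seed=11)
    negs2, gc2 = sample_gc_matched_negatives(positives, pool, pos_gc, pool_gc, seed=11)
    assert gc1 == gc2 and [id(c) for c in negs1] == [id(c) for c in negs2]
    stat = ks_2samp(pos_gc, gc1).statistic
    assert stat < 0.08


# ---------------------------------------------------------------------------
# splits


def test_split_sizes_and_determinism():
    s = split_dataset(100, seed=4)
    assert (len(s.train), len(s.validation), len(s.test)) == (70, 15, 15)
    s2 = split_dataset(100, seed=4)
    assert np.array_equal(s.train, s2.train) and np.array_equal(s.test, s2.test)
    pre = split_dataset(20, fractions=(0.85, 0.15), seed=0)
    assert (len(pre.train), len(pre.validation), len(pre.test)) == (17, 3, 0)


def test_split_errors():
    with pytest.raises(ValueError):
        split_dataset(2, fractions=(0.7, 0.15, 0.15), seed=0)
    with pytest.raises(ValueError):
        split_dataset(100, fractions=(0.5, 0.2), seed=0)


def test_splits_partition_many_draws():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(3, 500))
        seed = int(rng.integers(0, 2**31 - 1))
        s = split_dataset(n, seed=seed)
        merged = np.concatenate([s.train, s.validation, s.test])
        assert merged.size == n
        assert np.array_equal(np.sort(merged), np.arange(n))


@given(n=st.integers(3, 300), seed=st.integers(0, 2**31 - 1),
       f=st.sampled_from([(0.7, 0.15, 0.15), (0.85, 0.15), (0.5, 0.25, 0.25)]))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_split_fraction_rounding_property(n, seed, f):
    if n < len(f):
        return
    s = split_dataset(n, fractions=f, seed=seed)
    parts = [s.train, s.validation, s.test][: len(f)]
    for frac, part in zip(f[:-1], parts[:-1]):
        assert len(part) == int(np.floor(frac * n))
    assert sum(len(p) for p in parts) == n


# ---------------------------------------------------------------------------
# end-to-end dataset invariants


def test_build_labeled_dataset_invariants(fake_reference):
    rng = np.random.default_rng(5)
    cands = []
    for _ in range(300):
        mid1 = int(rng.integers(2000, 80_000))
        dist = int(rng.integers(1000, 110_000))
        fdr = float(rng.uniform(0, 1))
        cands.append(make_candidate(mid1=mid1, dist=dist, fdr=fdr,
                                    chrom=rng.choice(["chr1", "chr2"])))
    dataset = build_labeled_dataset(cands, fake_reference, seed=9)
    assert dataset, "expected a nonempty dataset"
    for d in dataset:
        assert d.distance <= 1_000_000
        assert d.anchor1.length == 2000 and d.anchor2.length == 2000
        if d.label == 1:
            assert d.fdr < 0.1
        else:
            assert d.fdr > 0.5
        assert 0.0 <= d.gc <= 1.0
    n_pos = sum(d.label for d in dataset)
    assert len(dataset) == 2 * n_pos
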