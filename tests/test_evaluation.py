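"""Metrics and experiment orchestration against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from loopnet.evaluation import (
    ExperimentResult, auc, auprc, compare_methods, cross_predict,
    median_auc_table, rank_methods, results_to_frame, run_experiments,
)
from loopnet.features import BundleSet
from loopnet.nn.model import ModelConfig, build_model

from conftest import random_bundles


def auc_pairwise_oracle(labels, scores):
    """O(n^2) Mann-Whitney oracle: every (positive, negative) pair counts 1
    when the positive outscores the negative and 1/2 on a tie."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def test_auc_examples():
    assert auc([1, 0], [0.9, 0.1]) == 1.0
    assert auc([1, 0], [0.5, 0.5]) == 0.5
    assert auc([0, 1], [0.9, 0.1]) == 0.0


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([1, 1, 1], [0.1, 0.2, 0.3])


def test_auc_matches_pairwise_oracle_exactly():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 60))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.integers(0, 10, n).astype(float)  # integer scores force ties
        assert auc(labels, scores) == auc_pairwise_oracle(labels, scores)


def test_auc_agrees_with_sklearn():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 200)
    labels[:2] = [0, 1]
    scores = rng.normal(size=200)
    assert auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, 30)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = rng.normal(size=30)
    base = auc(labels, scores)
    assert auc(labels, 3 * scores + 2) == pytest.approx(base, abs=1e-12)
    assert auc(labels, np.exp(scores)) == pytest.approx(base, abs=1e-12)


def test_auprc_basics():
    assert auprc([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2]) == 1.0
    # one positive ranked second among three: AP = 1/2
    assert auprc([0, 1, 0], [0.9, 0.5, 0.1]) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# rank-sum comparison


def ranksum_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p-value by enumerating every assignment of
    the pooled values into two groups of the observed sizes."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), len(x))]
    mean = np.mean(sums)
    return sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12) / len(sums)


def test_compare_methods_examples():
    frame = pd.DataFrame({"m1": [0.7, 0.8, 0.9], "m2": [0.7, 0.8, 0.9]})
    assert compare_methods(frame, "m1", "m2") == 1.0
    frame = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [4.0, 5.0, 6.0]})
    assert compare_methods(frame, "m1", "m2") == pytest.approx(0.1)
    with pytest.raises(ValueError):
        compare_methods(pd.DataFrame({"m1": [1, 2], "m2": [3, 4]}), "m1", "m2")


def test_compare_methods_matches_full_enumeration():
    rng = np.random.default_rng(5)
    for n in (4, 5, 6):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        frame = pd.DataFrame({"m1": x, "m2": y})
        assert compare_methods(frame, "m1", "m2") == pytest.approx(
            ranksum_enumeration_oracle(x, y), abs=1e-12
        )


# ---------------------------------------------------------------------------
# ranks


def make_results(mauc_by_tissue_method):
    rows = []
    for tissue, per_method in mauc_by_tissue_method.items():
        for method, aucs in per_method.items():
            for r, a in enumerate(aucs, start=1):
                rows.append(ExperimentResult(tissue, "PE", method, r, a, a, r))
    return rows


def test_rank_methods_examples():
    res = make_results({"t1": {"m1": [0.9, 0.9], "m2": [0.8, 0.8]}})
    ranks = rank_methods(res)
    assert ranks.loc["t1", "m1"] == 1 and ranks.loc["t1", "m2"] == 2
    tied = make_results({"t1": {"m1": [0.8], "m2": [0.8]}})
    r = rank_methods(tied)
    assert r.loc["t1", "m1"] == 1.5 and r.loc["t1", "m2"] == 1.5


def test_ranks_are_permutation_per_tissue():
    rng = np.random.default_rng(2)
    res = make_results({
        f"t{i}": {m: list(rng.uniform(0.5, 1.0, 10)) for m in ("a", "b", "c")}
        for i in range(6)
    })
    ranks = rank_methods(res)
    for _, row in ranks.iterrows():
        assert row.sum() == pytest.approx(6.0)  # 1+2+3


def test_rank_methods_missing_cell():
    res = make_results({"t1": {"m1": [0.9], "m2": [0.8]}, "t2": {"m1": [0.7]}})
    with pytest.raises(ValueError, match="missing"):
        rank_methods(res)


# ---------------------------------------------------------------------------
# experiment loop and cross prediction

D_CFG = ModelConfig(features=("D",), hidden_units=8, dropout=0.0, seed=0)


class DistanceModel:
    """Deterministic stand-in model scoring by (negated) distance."""

    cfg = D_CFG

    def predict(self, bundles):
        return 1.0 - np.asarray(bundles.arrays["D"], dtype=float)


def test_run_experiments_layout_and_determinism():
    bundles = {"t1": random_bundles(60, D_CFG, seed=0, signal=True)}
    methods = {"dist": lambda b, s, seed: DistanceModel()}
    res1 = run_experiments(bundles, methods, repeats=10)
    assert len(res1) == 10
    assert sorted(r.repeat for r in res1) == list(range(1, 11))
    res2 = run_experiments(bundles, methods, repeats=10)
    assert [r.auc for r in res1] == [r.auc for r in res2]
    with pytest.raises(ValueError, match="distinct"):
        run_experiments(bundles, methods, repeats=3, seeds=[1, 1, 2])
    smoke = run_experiments(bundles, methods, repeats=2)
    assert len(smoke) == 2


def test_cross_predict_no_weight_update(tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    before = {k: v.copy() for k, v in net.state_dict().items()}
    other = random_bundles(30, tiny_model_cfg, seed=3, signal=True)
    res = cross_predict(net, other, tissue="t1", source_itype="PE", target_itype="PP")
    assert res.itype == "PE-to-PP"
    assert 0.0 <= res.auc <= 1.0
    for k, v in net.state_dict().items():
        assert np.array_equal(before[k], v)


def test_cross_predict_incompatible_features(tiny_model_cfg):
    net = build_model(tiny_model_cfg)  # needs S, R, D
    d_only = random_bundles(10, D_CFG, seed=4)
    with pytest.raises(ValueError, match="lacks"):
        cross_predict(net, d_only)


def test_cross_predict_same_type_reduces_to_testing(tiny_model_cfg):
    net = build_model(tiny_model_cfg)
    bundles = random_bundles(30, tiny_model_cfg, seed=5)
    res = cross_predict(net, bundles, source_itype="PE", target_itype="PE")
    assert res.auc == pytest.approx(auc(bundles.labels, net.predict(bundles)))
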