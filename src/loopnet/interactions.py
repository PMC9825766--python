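"""Labeled-dataset construction from promoter-capture Hi-C interaction summaries.

A pcHi-C summary lists candidate anchor pairs with a per-interaction FDR.
This module parses such tables (BEDPE-like TSV, 0-based half-open BED
coordinates), keeps intra-chromosomal pairs within a distance bound,
standardizes every anchor to a fixed-width window around its midpoint
(2 kb by default), labels candidates by FDR (significant interactions are
positives, clearly non-significant ones form a negative pool) and draws a
GC-matched negative sample so that nucleotide composition cannot act as a
confounder between the classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1000
DEFAULT_MAX_DISTANCE = 1_000_000
DEFAULT_POS_FDR = 0.1
DEFAULT_NEG_FDR = 0.5


class FormatError(ValueError):
    """A malformed interaction table (missing columns, bad row)."""


class InsufficientPoolError(ValueError):
    """Negative pool too small for the requested sample size."""


@dataclass(frozen=True)
class GenomicAnchor:
    """One side of a chromatin interaction, as a 0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"anchor end must exceed start: {self}")
        if self.start < 0:
            raise ValueError(f"anchor start must be >= 0: {self}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateInteraction:
    anchor1: GenomicAnchor
    anchor2: GenomicAnchor
    fdr: float
    itype: str = "PE"
    tissue: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")

    @property
    def distance(self) -> int:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("distance undefined for inter-chromosomal pair")
        return abs(self.anchor1.midpoint - self.anchor2.midpoint)


@dataclass(frozen=True)
class LabeledInteraction:
    anchor1: GenomicAnchor
    anchor2: GenomicAnchor
    fdr: float
    itype: str
    tissue: str
    label: int
    distance: int
    gc: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc must lie in [0, 1], got {self.gc}")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test index sets over a dataset of size n."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def parts(self) -> tuple[np.ndarray, ...]:
        return tuple(p for p in (self.train, self.validation, self.test) if p.size or True)


# ---------------------------------------------------------------------------
# parsing


def parse_interactions(path: str | Path, tissue: str = "", itype: str = "PE") -> list[CandidateInteraction]:
    """Parse a BEDPE-like interaction table into candidate interactions.

    Expected tab-separated columns: chrom1 start1 end1 chrom2 start2 end2 fdr
    (extra columns ignored; lines beginning with '#' are comments; a header
    line naming the columns is tolerated). Malformed rows raise
    :class:`FormatError` naming the offending line number.
    """
    path = Path(path)
    out: list[CandidateInteraction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chrom1", "chr1") and not fields[1].isdigit():
                continue  # header
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
            try:
                a1 = GenomicAnchor(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicAnchor(fields[3], int(fields[4]), int(fields[5]))
                fdr = float(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not (0.0 <= fdr <= 1.0):
                raise FormatError(f"{path}:{lineno}: fdr outside [0, 1]: {fdr}")
            out.append(CandidateInteraction(a1, a2, fdr, itype=itype, tissue=tissue))
    return out


def filter_interactions(
    cands: Sequence[CandidateInteraction], max_distance: int = DEFAULT_MAX_DISTANCE
) -> list[CandidateInteraction]:
    """Keep intra-chromosomal pairs with midpoint distance <= max_distance.

    The distance bound is inclusive: a pair exactly at the bound is retained,
    only strictly longer-range pairs are removed. Input order is preserved.
    """
    kept = []
    for c in cands:
        if c.anchor1.chrom != c.anchor2.chrom:
            continue
        if c.distance > max_distance:
            continue
        kept.append(c)
    return kept


def standardize_anchor(anchor: GenomicAnchor, flank: int = DEFAULT_FLANK) -> GenomicAnchor:
    """Recenter an anchor to [mid - flank, mid + flank).

    The midpoint uses integer floor for odd-length anchors. Anchors whose
    window would underflow the chromosome start are rejected.
    """
    mid = anchor.midpoint
    if mid - flank < 0:
        raise ValueError(
            f"anchor {anchor.chrom}:{anchor.start}-{anchor.end} too close to chromosome "
            f"start for flank {flank}"
        )
    return GenomicAnchor(anchor.chrom, mid - flank, mid + flank)


def standardize_interactions(
    cands: Sequence[CandidateInteraction],
    flank: int = DEFAULT_FLANK,
    chrom_sizes: dict[str, int] | None = None,
) -> list[CandidateInteraction]:
    """Standardize both anchors of each candidate; drop candidates whose
    window underflows the chromosome start or (when sizes are known)
    overhangs the chromosome end. Drops are logged, not padded."""
    out = []
    dropped = 0
    for c in cands:
        try:
            a1 = standardize_anchor(c.anchor1, flank)
            a2 = standardize_anchor(c.anchor2, flank)
        except ValueError:
            dropped += 1
            continue
        if chrom_sizes is not None:
            if a1.end > chrom_sizes.get(a1.chrom, np.inf) or a2.end > chrom_sizes.get(a2.chrom, np.inf):
                dropped += 1
                continue
        out.append(replace(c, anchor1=a1, anchor2=a2))
    if dropped:
        logger.warning("dropped %d interactions whose standardized anchors leave the chromosome", dropped)
    return out


def deduplicate_interactions(cands: Sequence[CandidateInteraction]) -> list[CandidateInteraction]:
    """Collapse duplicates (identical standardized anchor pairs, unordered),
    keeping the smallest FDR. First-seen order is preserved."""
    best: dict[tuple, CandidateInteraction] = {}
    order: list[tuple] = []
    for c in cands:
        k1 = (c.anchor1.chrom, c.anchor1.start, c.anchor1.end)
        k2 = (c.anchor2.chrom, c.anchor2.start, c.anchor2.end)
        key = (min(k1, k2), max(k1, k2))
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.fdr < best[key].fdr:
            best[key] = c
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# labeling


def label_by_fdr(
    cands: Sequence[CandidateInteraction],
    pos_cut: float = DEFAULT_POS_FDR,
    neg_cut: float = DEFAULT_NEG_FDR,
) -> tuple[list[CandidateInteraction], list[CandidateInteraction]]:
    """Split candidates into positives (fdr < pos_cut) and a negative pool
    (fdr > neg_cut); candidates between the cutoffs are discarded."""
    if pos_cut > neg_cut:
        raise ValueError(f"pos_cut ({pos_cut}) must not exceed neg_cut ({neg_cut})")
    positives = [c for c in cands if c.fdr < pos_cut]
    pool = [c for c in cands if c.fdr > neg_cut]
    return positives, pool


def gc_content(seq: str) -> float:
    """Fraction of G/C among unambiguous bases (case-insensitive)."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def interaction_gc(cand: CandidateInteraction, reference) -> float:
    """GC of the concatenated standardized anchor sequences.

    GC is matched on the pair as a whole rather than per anchor; per-anchor
    matching is available by calling :func:`gc_content` on each side.
    """
    s1 = reference.fetch(cand.anchor1.chrom, cand.anchor1.start, cand.anchor1.end)
    s2 = reference.fetch(cand.anchor2.chrom, cand.anchor2.start, cand.anchor2.end)
    return gc_content(s1 + s2)


def sample_gc_matched_negatives(
    positives: Sequence[CandidateInteraction],
    pool: Sequence[CandidateInteraction],
    pos_gc: Sequence[float],
    pool_gc: Sequence[float],
    ratio: int = 1,
    bins: int = 10,
    seed: int = 0,
) -> tuple[list[CandidateInteraction], list[float]]:
    """Draw ratio * len(positives) negatives whose GC histogram matches the
    positives'.

    Bin edges are the deciles (``bins`` quantiles) of the positive GC
    distribution; each bin's target count is ratio times the positive count
    in that bin. Within-bin shortfalls are filled by the unused pool members
    nearest in GC to the bin's midpoint. Sampling is without replacement and
    deterministic given ``seed``.
    """
    if not positives:
        return [], []
    pos_gc = np.asarray(pos_gc, dtype=float)
    pool_gc = np.asarray(pool_gc, dtype=float)
    need_total = ratio * len(positives)
    if len(pool) < need_total:
        raise InsufficientPoolError(
            f"negative pool has {len(pool)} candidates but {need_total} are required "
            f"(deficit {need_total - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    edges = np.quantile(pos_gc, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    pos_bin = np.clip(np.searchsorted(edges, pos_gc, side="right") - 1, 0, bins - 1)
    pool_bin = np.clip(np.searchsorted(edges, pool_gc, side="right") - 1, 0, bins - 1)

    chosen = np.zeros(len(pool), dtype=bool)
    picked: list[int] = []
    shortfalls: list[tuple[int, float]] = []  # (missing count, bin gc midpoint)
    for b in range(bins):
        want = ratio * int((pos_bin == b).sum())
        if want == 0:
            continue
        avail = np.flatnonzero((pool_bin == b) & ~chosen)
        take = min(want, avail.size)
        if take:
            sel = rng.choice(avail, size=take, replace=False)
            chosen[sel] = True
            picked.extend(sel.tolist())
        if take < want:
            shortfalls.append((want - take, float(pos_gc[pos_bin == b].mean())))
    for missing, center in shortfalls:
        avail = np.flatnonzero(~chosen)
        order = avail[np.argsort(np.abs(pool_gc[avail] - center), kind="stable")]
        sel = order[:missing]
        chosen[sel] = True
        picked.extend(sel.tolist())
    picked_arr = np.array(sorted(picked), dtype=int)
    return [pool[i] for i in picked_arr], [float(pool_gc[i]) for i in picked_arr]


def split_dataset(
    n: int, fractions: Sequence[float] = (0.70, 0.15, 0.15), seed: int = 0
) -> DatasetSplit:
    """Random disjoint partition of range(n) into len(fractions) parts.

    Rounding rule: every part but the last gets the floor of its share and
    the last part takes the remainder. Two-way (0.85, 0.15) splits used for
    pretraining put the remainder in an empty test set.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if n < len(fractions):
        raise ValueError(f"cannot split {n} items into {len(fractions)} parts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = [int(np.floor(f * n)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    parts = []
    at = 0
    for s in sizes:
        parts.append(np.sort(perm[at : at + s]))
        at += s
    while len(parts) < 3:
        parts.append(np.array([], dtype=int))
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)


# ---------------------------------------------------------------------------
# dataset assembly and IO


def build_labeled_dataset(
    cands: Iterable[CandidateInteraction],
    reference,
    pos_cut: float = DEFAULT_POS_FDR,
    neg_cut: float = DEFAULT_NEG_FDR,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    flank: int = DEFAULT_FLANK,
    ratio: int = 1,
    bins: int = 10,
    seed: int = 0,
) -> list[LabeledInteraction]:
    """Full dataset construction: filter -> standardize -> deduplicate ->
    FDR-label -> GC-matched negative sampling.

    ``reference`` must expose ``fetch(chrom, start, end) -> str`` and
    ``chrom_sizes() -> dict`` (see :class:`loopnet.features.ReferenceGenome`).
    """
    cands = filter_interactions(list(cands), max_distance)
    cands = standardize_interactions(cands, flank, chrom_sizes=reference.chrom_sizes())
    cands = deduplicate_interactions(cands)
    positives, pool = label_by_fdr(cands, pos_cut, neg_cut)
    pos_gc = [interaction_gc(c, reference) for c in positives]
    pool_gc = [interaction_gc(c, reference) for c in pool]
    negatives, neg_gc = sample_gc_matched_negatives(
        positives, pool, pos_gc, pool_gc, ratio=ratio, bins=bins, seed=seed
    )

    def _mk(c: CandidateInteraction, label: int, gc: float) -> LabeledInteraction:
        return LabeledInteraction(
            anchor1=c.anchor1, anchor2=c.anchor2, fdr=c.fdr, itype=c.itype,
            tissue=c.tissue, label=label, distance=c.distance, gc=gc,
        )

    out = [_mk(c, 1, g) for c, g in zip(positives, pos_gc)]
    out += [_mk(c, 0, g) for c, g in zip(negatives, neg_gc)]
    return out


_DATASET_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "fdr", "type", "tissue", "label", "distance", "gc",
]


def dataset_to_frame(dataset: Sequence[LabeledInteraction]) -> pd.DataFrame:
    rows = [
        (
            d.anchor1.chrom, d.anchor1.start, d.anchor1.end,
            d.anchor2.chrom, d.anchor2.start, d.anchor2.end,
            d.fdr, d.itype, d.tissue, d.label, d.distance, d.gc,
        )
        for d in dataset
    ]
    return pd.DataFrame(rows, columns=_DATASET_COLUMNS)


def frame_to_dataset(df: pd.DataFrame) -> list[LabeledInteraction]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LabeledInteraction(
                anchor1=GenomicAnchor(row.chrom1, int(row.start1), int(row.end1)),
                anchor2=GenomicAnchor(row.chrom2, int(row.start2), int(row.end2)),
                fdr=float(row.fdr), itype=row.type, tissue=row.tissue,
                label=int(row.label), distance=int(row.distance), gc=float(row.gc),
            )
        )
    return out


def write_dataset(dataset: Sequence[LabeledInteraction], path: str | Path) -> None:
    """Write a labeled dataset as a tab-separated table with a header line."""
    dataset_to_frame(dataset).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> list[LabeledInteraction]:
    return frame_to_dataset(pd.read_csv(path, sep="\t"))


def write_split(split: DatasetSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("part\tindex\n")
        for name, idx in (("train", split.train), ("validation", split.validation), ("test", split.test)):
            for i in idx:
                fh.write(f"{name}\t{int(i)}\n")


def read_split(path: str | Path, seed: int = -1) -> DatasetSplit:
    df = pd.read_csv(path, sep="\t")
    get = lambda part: df.loc[df["part"] == part, "index"].to_numpy(dtype=int)
    return DatasetSplit(train=get("train"), validation=get("validation"), test=get("test"), seed=seed)
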