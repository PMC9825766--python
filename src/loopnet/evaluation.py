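"""Scoring and experiment orchestration.

Models are scored by AUC (area under the ROC curve, equal to the
Mann-Whitney probability that a random positive outscores a random
negative, ties counting one half) and AUPRC (area under the
precision-recall curve, computed as average precision). The experiment
design repeats the 70/15/15 random split ten times per tissue and method;
per-tissue methods are ranked by the median AUC over repeats ("mAUC") and
methods are compared across tissues with a two-sided Wilcoxon rank-sum
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .features import BundleSet
from .interactions import split_dataset


@dataclass(frozen=True)
class ExperimentResult:
    tissue: str
    itype: str
    method: str
    repeat: int
    auc: float
    auprc: float
    seed: int


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ranking metric")
    return labels


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC via midranks: the probability a positive outranks a
    negative, with tied scores counting one half."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)  # midranks handle ties
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision (step-wise summation, no interpolation)."""
    labels = _check_labels(labels)
    return float(average_precision_score(labels, scores))


def run_experiments(
    bundles_by_tissue: Mapping[str, BundleSet],
    methods: Mapping[str, Callable],
    repeats: int = 10,
    seeds: Sequence[int] | None = None,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    itype: str = "PE",
) -> list[ExperimentResult]:
    """Repeat the random-split experiment for every tissue and method.

    Each method is a callable ``(bundles, split, seed) -> model`` where the
    model exposes ``predict``; each repeat re-splits the data with its own
    seed and re-trains, and AUC/AUPRC on the held-out test part are
    recorded.
    """
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("one seed per repeat is required")
    if len(set(seeds)) != len(seeds):
        raise ValueError("repeat seeds must be distinct")
    results = []
    for tissue, bundles in bundles_by_tissue.items():
        for r, seed in enumerate(seeds, start=1):
            split = split_dataset(len(bundles), fractions=fractions, seed=seed)
            test = bundles.subset(split.test)
            for name, trainer in methods.items():
                model = trainer(bundles, split, seed)
                scores = model.predict(test)
                results.append(
                    ExperimentResult(
                        tissue=tissue, itype=itype, method=name, repeat=r,
                        auc=auc(test.labels, scores),
                        auprc=auprc(test.labels, scores), seed=seed,
                    )
                )
    return results


def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.tissue, r.itype, r.method, r.repeat, r.auc, r.auprc, r.seed) for r in results],
        columns=["tissue", "type", "method", "repeat", "auc", "auprc", "seed"],
    )


def median_auc_table(results: Sequence[ExperimentResult] | pd.DataFrame) -> pd.DataFrame:
    """mAUC (median AUC over repeats) per tissue x method."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    return df.pivot_table(index="tissue", columns="method", values="auc", aggfunc="median")


def rank_methods(results: Sequence[ExperimentResult] | pd.DataFrame) -> pd.DataFrame:
    """Per-tissue ranks of methods by mAUC (rank 1 = best; ties share the
    average rank). Raises if any (tissue, method) cell is missing."""
    m = median_auc_table(results)
    if m.shape[1] < 2:
        raise ValueError("ranking requires at least two methods")
    if m.isna().any().any():
        missing = [(t, c) for t, row in m.iterrows() for c in m.columns if pd.isna(row[c])]
        raise ValueError(f"missing result cells: {missing}")
    return m.rank(axis=1, ascending=False, method="average")


def compare_methods(
    mauc_by_tissue: pd.DataFrame | Mapping[str, Sequence[float]],
    method1: str,
    method2: str,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value on two methods' per-tissue mAUC
    vectors: exact enumeration for group sizes <= 10 without ties, otherwise
    the tie-corrected normal approximation."""
    if not isinstance(mauc_by_tissue, pd.DataFrame):
        mauc_by_tissue = pd.DataFrame(mauc_by_tissue)
    x = np.asarray(mauc_by_tissue[method1], dtype=float)
    y = np.asarray(mauc_by_tissue[method2], dtype=float)
    if x.size != y.size:
        raise ValueError("per-tissue mAUC vectors must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 tissues are required for the rank-sum comparison")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def cross_predict(
    model,
    bundles: BundleSet,
    tissue: str = "",
    source_itype: str = "PE",
    target_itype: str = "PP",
    method: str = "",
) -> ExperimentResult:
    """Evaluate a model trained on one interaction type against a dataset of
    the other type, without any weight update."""
    missing = [m for m in model.cfg.features if m not in bundles.arrays]
    if missing:
        raise ValueError(f"dataset lacks feature modalities {missing} required by the model")
    scores = model.predict(bundles.with_features(model.cfg.features))
    return ExperimentResult(
        tissue=tissue, itype=f"{source_itype}-to-{target_itype}",
        method=method or "cross", repeat=1,
        auc=auc(bundles.labels, scores), auprc=auprc(bundles.labels, scores), seed=-1,
    )
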