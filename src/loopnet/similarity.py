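"""Gene-overlap biological similarity between tissues.

For each tissue, every anchor of every positive interaction is assigned its
nearest gene (smallest distance from the anchor midpoint to a transcription
start site); the union of those genes forms the tissue's gene set. The
similarity between two tissues is the proportion of shared genes among all
genes of both — the Jaccard index of the two gene sets. The most similar
tissues to a target can then be chosen for pretraining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import GenomicAnchor, LabeledInteraction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals with ids and strands; TSS = start on '+', end-1 on '-'."""

    frame: pd.DataFrame  # columns: chrom, start, end, name, strand, tss

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
        return cls(df[["chrom", "start", "end", "name", "strand", "tss"]])

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]


def nearest_gene(anchor: GenomicAnchor, annotation: GeneAnnotation) -> str:
    """Gene whose TSS is closest to the anchor midpoint; ties broken by
    smaller TSS coordinate, then lexicographic gene id."""
    genes = annotation.genes_on(anchor.chrom)
    if genes.empty:
        raise ValueError(f"no genes annotated on chromosome {anchor.chrom!r}")
    dist = np.abs(genes["tss"].to_numpy() - anchor.midpoint)
    order = sorted(
        zip(dist, genes["tss"].to_numpy(), genes["name"].to_numpy()),
        key=lambda t: (t[0], t[1], t[2]),
    )
    return order[0][2]


def tissue_gene_set(
    positives: Sequence[LabeledInteraction], annotation: GeneAnnotation
) -> set[str]:
    """Nearest genes of both anchors over all positive interactions."""
    genes: set[str] = set()
    for inter in positives:
        if getattr(inter, "label", 1) != 1:
            continue
        genes.add(nearest_gene(inter.anchor1, annotation))
        genes.add(nearest_gene(inter.anchor2, annotation))
    if not genes:
        logger.warning("no positive interactions: empty tissue gene set")
    return genes


def similarity(genes1: set[str], genes2: set[str]) -> float:
    """Proportion of common genes among all genes in both tissues (Jaccard);
    0 when both sets are empty."""
    union = genes1 | genes2
    if not union:
        return 0.0
    return len(genes1 & genes2) / len(union)


def similarity_matrix(gene_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    tissues = list(gene_sets)
    mat = pd.DataFrame(np.zeros((len(tissues), len(tissues))), index=tissues, columns=tissues)
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i:]:
            s = similarity(gene_sets[t1], gene_sets[t2])
            mat.loc[t1, t2] = s
            mat.loc[t2, t1] = s
    return mat


def top_k_similar(matrix: pd.DataFrame, target: str, k: int = 5) -> list[str]:
    """The k tissues most similar to the target (target excluded), sorted by
    similarity descending with lexicographic tie-breaks."""
    if target not in matrix.index:
        raise ValueError(f"target tissue {target!r} not in similarity matrix")
    others = [t for t in matrix.index if t != target]
    if k > len(others):
        raise ValueError(f"k={k} exceeds the {len(others)} available tissues")
    ranked = sorted(others, key=lambda t: (-matrix.loc[target, t], t))
    return ranked[:k]
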