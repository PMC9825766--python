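"""Synthetic study generator.

Produces every input the toolkit consumes — a random genome (FASTA), a gene
annotation (BED), per-tissue coverage tracks (bedGraph) and per-tissue
interaction tables (BEDPE-like TSV with FDR) — with controllable planted
signal, so the whole pipeline and all three training paradigms can be
exercised end to end without external data.

Planted signal, per positive interaction:

* a *shared* sequence motif written into each anchor with probability
  ``p_shared`` (the same motif in every tissue — the cross-tissue common
  feature that pretraining can learn);
* a *private*, tissue-specific motif with probability ``p_private``;
* multiplicative coverage enrichment (``enrichment_fold``) at the positive
  anchors of the matching tissue's tracks;
* shorter anchor distances than negatives in ``shifted`` distance mode; in
  ``matched`` mode positives and negatives share one distance sampler, so
  distance carries no label information.

FDRs are drawn from Uniform(0, 0.1) for true positives and Uniform(0.5, 1)
for negatives, so FDR labeling at the default cutoffs recovers the planted
truth exactly. Negatives are drawn from the same genomic background as
positives (same GC composition), making them GC-matched by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CoverageTrack
from .interactions import CandidateInteraction, GenomicAnchor

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_MARKS = ("openchrom", "H3K4me3", "H3K4me1", "H3K27ac")


@dataclass(frozen=True)
class SimulationConfig:
    n_chroms: int = 12
    chrom_len: int = 2_000_000
    gc: float = 0.5
    n_genes_per_chrom: int = 25
    tissues: tuple[str, ...] = ("T1", "T2", "T3", "T4")
    n_positives: int = 500            # per tissue; override per call for small/large regimes
    neg_pool_factor: float = 2.0      # negative-pool size as a multiple of positives
    shared_motif: str = "GTACGCATGC"
    private_motif_len: int = 10
    p_shared: float = 0.8
    p_private: float = 0.3
    motif_copies: int = 8             # sites per motif-carrying anchor (homotypic cluster)
    marks: tuple[str, ...] = DEFAULT_MARKS
    background_rate: float = 1.0      # Poisson mean per coverage bin
    coverage_bin: int = 50
    enrichment_fold: float = 5.0
    distance_mode: str = "shifted"    # shifted | matched
    pos_distance: tuple[int, int] = (5_000, 300_000)
    neg_distance: tuple[int, int] = (200_000, 950_000)
    matched_distance: tuple[int, int] = (5_000, 950_000)
    anchor_len_choices: tuple[int, ...] = (2000, 3000, 4000, 6000)
    fdr_pos: tuple[float, float] = (0.0, 0.1)
    fdr_neg: tuple[float, float] = (0.5, 1.0)
    flank: int = 1000
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_shared, self.p_private):
            if not 0.0 <= p <= 1.0:
                raise ValueError("motif probabilities must lie in [0, 1]")
        if self.n_positives <= 0 or self.n_chroms <= 0 or self.chrom_len <= 0:
            raise ValueError("counts must be positive")
        if self.distance_mode not in ("shifted", "matched"):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")
        max_dist = max(self.neg_distance[1], self.pos_distance[1], self.matched_distance[1])
        margin = max(self.anchor_len_choices) // 2 + 100
        if self.chrom_len < max_dist + 2 * margin:
            raise ValueError(
                f"chrom_len {self.chrom_len} too small for max anchor distance {max_dist}"
            )

    def distance_ranges(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(positive, negative) distance sampler bounds; identical samplers
        in matched mode."""
        if self.distance_mode == "matched":
            return self.matched_distance, self.matched_distance
        return self.pos_distance, self.neg_distance


class SyntheticGenome:
    """Mutable random genome; satisfies the reference protocol
    (fetch / chrom_sizes) used by dataset construction and featurization."""

    def __init__(self, chroms: dict[str, np.ndarray]):
        self.chroms = chroms  # chrom -> uint8 array of ASCII base codes

    def chrom_sizes(self) -> dict[str, int]:
        return {c: a.size for c, a in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        arr = self.chroms[chrom]
        if start < 0 or end > arr.size:
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return arr[start:end].tobytes().decode("ascii")

    def plant(self, chrom: str, pos: int, motif: str) -> None:
        enc = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
        self.chroms[chrom][pos: pos + enc.size] = enc

    def gc_fraction(self) -> float:
        g, c = ord("G"), ord("C")
        total = sum(a.size for a in self.chroms.values())
        gc = sum(int(((a == g) | (a == c)).sum()) for a in self.chroms.values())
        return gc / total

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.chroms.items():
                fh.write(f">{chrom}\n")
                seq = arr.tobytes().decode("ascii")
                for at in range(0, len(seq), width):
                    fh.write(seq[at: at + width] + "\n")


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *key])


def generate_genome(cfg: SimulationConfig) -> tuple[SyntheticGenome, pd.DataFrame]:
    """Random genome with the configured GC composition plus a uniform gene
    annotation. Deterministic given the config seed."""
    rng = _rng(cfg, 0)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    chroms = {}
    for i in range(cfg.n_chroms):
        codes = rng.choice(_BASES, size=cfg.chrom_len, p=p)
        chroms[f"chr{i + 1}"] = codes.astype(np.uint8)
    genome = SyntheticGenome(chroms)

    rows = []
    for i, chrom in enumerate(chroms):
        if cfg.n_genes_per_chrom == 0:
            continue
        starts = np.sort(rng.integers(0, cfg.chrom_len - 1000, size=cfg.n_genes_per_chrom))
        strands = rng.choice(["+", "-"], size=cfg.n_genes_per_chrom)
        for j, (s, strand) in enumerate(zip(starts, strands)):
            rows.append((chrom, int(s), int(s) + 1000, f"gene_{chrom}_{j}", 0, strand))
    if not rows:
        logger.warning("0 genes requested: emitting an empty annotation")
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return genome, genes


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", header=False, index=False)


def _private_motif(cfg: SimulationConfig, tissue_index: int) -> str:
    rng = _rng(cfg, 1, tissue_index)
    while True:
        motif = "".join(rng.choice(list("ACGT"), size=cfg.private_motif_len))
        if motif != cfg.shared_motif:
            return motif


@dataclass
class TissueInteractions:
    tissue: str
    itype: str
    interactions: list[CandidateInteraction]
    truth: np.ndarray               # planted 0/1 labels, aligned with interactions
    private_motif: str
    positive_anchors: list[GenomicAnchor]  # standardized, for coverage enrichment


def generate_tissue_interactions(
    cfg: SimulationConfig,
    genome: SyntheticGenome,
    tissue: str,
    itype: str = "PE",
    n_positives: int | None = None,
) -> TissueInteractions:
    """Draw one tissue's candidate interactions and plant motifs into the
    genome at its positive anchors. The negative pool has
    ``neg_pool_factor`` times the positive count."""
    t_index = cfg.tissues.index(tissue) if tissue in cfg.tissues else hash(tissue) % 1000
    rng = _rng(cfg, 2, t_index, 0 if itype == "PE" else 1)
    n_pos = n_positives or cfg.n_positives
    n_neg = int(round(cfg.neg_pool_factor * n_pos))
    pos_range, neg_range = cfg.distance_ranges()
    private_motif = _private_motif(cfg, t_index)
    chrom_names = list(genome.chroms)
    margin = max(cfg.anchor_len_choices) // 2 + 50

    interactions: list[CandidateInteraction] = []
    truth = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    positive_anchors: list[GenomicAnchor] = []

    for label, count, dist_range, fdr_range in (
        (1, n_pos, pos_range, cfg.fdr_pos),
        (0, n_neg, neg_range, cfg.fdr_neg),
    ):
        for _ in range(count):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            dist = int(rng.integers(dist_range[0], dist_range[1] + 1))
            lo = margin
            hi = cfg.chrom_len - margin - dist
            mid1 = int(rng.integers(lo, hi))
            mid2 = mid1 + dist
            anchors = []
            for mid in (mid1, mid2):
                length = int(rng.choice(cfg.anchor_len_choices))
                start = mid - length // 2
                anchors.append(GenomicAnchor(chrom, start, start + length))
            fdr = float(rng.uniform(*fdr_range))
            interactions.append(
                CandidateInteraction(anchors[0], anchors[1], fdr, itype=itype, tissue=tissue)
            )
            if label == 1:
                for anchor in anchors:
                    mid = anchor.midpoint
                    window_start = mid - cfg.flank
                    positive_anchors.append(GenomicAnchor(chrom, window_start, mid + cfg.flank))
                    span = 2 * cfg.flank
                    half = span // 2
                    # shared sites go in the left half of the window, private
                    # sites in the right half, so the two never overwrite
                    # each other
                    if rng.random() < cfg.p_shared:
                        for off in rng.integers(0, half - len(cfg.shared_motif),
                                                size=cfg.motif_copies):
                            genome.plant(chrom, window_start + int(off), cfg.shared_motif)
                    if rng.random() < cfg.p_private:
                        for off in rng.integers(half, span - len(private_motif),
                                                size=cfg.motif_copies):
                            genome.plant(chrom, window_start + int(off), private_motif)

    return TissueInteractions(
        tissue=tissue, itype=itype, interactions=interactions, truth=truth,
        private_motif=private_motif, positive_anchors=positive_anchors,
    )


def generate_tracks(
    cfg: SimulationConfig,
    genome: SyntheticGenome,
    tissue_data: TissueInteractions,
) -> dict[str, CoverageTrack]:
    """Per-mark coverage: Poisson background drawn per ``coverage_bin`` bases,
    multiplied by ``enrichment_fold`` in bins overlapping the tissue's
    positive anchors."""
    t_index = cfg.tissues.index(tissue_data.tissue) if tissue_data.tissue in cfg.tissues else 0
    sizes = genome.chrom_sizes()
    tracks = {}
    for m, mark in enumerate(cfg.marks):
        rng = _rng(cfg, 3, t_index, m)
        arrays = {}
        for chrom, n in sizes.items():
            n_bins = -(-n // cfg.coverage_bin)
            bins = rng.poisson(cfg.background_rate, size=n_bins).astype(np.float32)
            for anchor in tissue_data.positive_anchors:
                if anchor.chrom != chrom:
                    continue
                b0 = anchor.start // cfg.coverage_bin
                b1 = -(-anchor.end // cfg.coverage_bin)
                bins[b0:b1] *= cfg.enrichment_fold
            arrays[chrom] = np.repeat(bins, cfg.coverage_bin)[:n]
        tracks[mark] = CoverageTrack(arrays, name=f"{tissue_data.tissue}.{mark}")
    return tracks


def write_track_bedgraph(track: CoverageTrack, path: str | Path, bin_size: int = 50) -> None:
    """Write a track as bedGraph at bin resolution (values are constant
    within generator bins, so this is lossless for generated tracks)."""
    with open(path, "w") as fh:
        for chrom, arr in track._arrays.items():
            n = arr.size
            starts = np.arange(0, n, bin_size)
            ends = np.minimum(starts + bin_size, n)
            vals = arr[starts]
            frame = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vals})
            frame.to_csv(fh, sep="\t", header=False, index=False)


def write_interactions_tsv(
    data: TissueInteractions, path: str | Path, truth_path: str | Path | None = None
) -> None:
    """BEDPE-like TSV consumed by the parser; planted truth labels go to a
    separate side file so they never leak into the pipeline input."""
    with open(path, "w") as fh:
        fh.write("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tfdr\ttype\n")
        for c in data.interactions:
            fh.write(
                f"{c.anchor1.chrom}\t{c.anchor1.start}\t{c.anchor1.end}\t"
                f"{c.anchor2.chrom}\t{c.anchor2.start}\t{c.anchor2.end}\t"
                f"{c.fdr:.6g}\t{c.itype}\n"
            )
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("label\n")
            for t in data.truth:
                fh.write(f"{int(t)}\n")


def simulate_study(
    cfg: SimulationConfig,
    outdir: str | Path,
    itypes: Sequence[str] = ("PE",),
    n_positives: Mapping[str, int] | None = None,
    write_tracks: bool = True,
) -> dict:
    """Generate and write a complete multi-tissue study.

    Returns a manifest of paths plus the in-memory genome and per-tissue
    interaction data (handy for tests and pipelines that skip file IO).
    """
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome(cfg)
    tissue_data: dict[tuple[str, str], TissueInteractions] = {}
    for tissue in cfg.tissues:
        for itype in itypes:
            n_pos = n_positives.get(tissue) if n_positives else None
            tissue_data[(tissue, itype)] = generate_tissue_interactions(
                cfg, genome, tissue, itype=itype, n_positives=n_pos
            )

    manifest: dict = {"genome": str(outdir / "genome.fa"), "genes": str(outdir / "genes.bed"),
                      "interactions": {}, "tracks": {}}
    genome.write_fasta(outdir / "genome.fa")
    write_genes_bed(genes, outdir / "genes.bed")
    for (tissue, itype), data in tissue_data.items():
        ipath = outdir / f"{tissue}.{itype}.interactions.tsv"
        tpath = outdir / f"{tissue}.{itype}.truth.tsv"
        write_interactions_tsv(data, ipath, tpath)
        manifest["interactions"][f"{tissue}.{itype}"] = str(ipath)
    if write_tracks:
        for tissue in cfg.tissues:
            data = tissue_data[(tissue, itypes[0])]
            tracks = generate_tracks(cfg, genome, data)
            paths = {}
            for mark, track in tracks.items():
                path = outdir / "tracks" / f"{tissue}.{mark}.bedGraph"
                write_track_bedgraph(track, path, bin_size=cfg.coverage_bin)
                paths[mark] = str(path)
            manifest["tracks"][tissue] = paths
    manifest["_genome"] = genome
    manifest["_genes"] = genes
    manifest["_tissue_data"] = tissue_data
    return manifest
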