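"""Model-ready features for anchor pairs.

Three feature modalities feed the classifier, mirroring what each anchor of
a candidate interaction looks like in the genome and in the tissue:

* ``S`` — per-anchor one-hot DNA sequence, a (2000, 4) matrix per anchor
  with column order A, C, G, T and all-zero rows for ambiguous bases;
* ``R`` — per-anchor windowed epigenetic read features: counts-per-million
  normalized coverage averaged in 1000-bp windows slid by 50 bp across the
  2-kb anchor, giving 21 values per track (open chromatin, H3K4me3,
  H3K4me1, H3K27ac by default);
* ``D`` — the scalar distance between the two anchor midpoints, scaled by
  the 1-Mb distance filter bound into [0, 1].

Optional auxiliary tracks (per-base conservation scores or DNA-shape
features) are windowed exactly like read tracks and travel under ``aux``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .interactions import LabeledInteraction, GenomicAnchor

logger = logging.getLogger(__name__)

WINDOW = 1000
STEP = 50
DISTANCE_SCALE = 1_000_000
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class EncodingError(ValueError):
    """A sequence character outside {A,C,G,T,N} (case-insensitive)."""


class ResourceError(ValueError):
    """A requested feature modality lacks its backing resource."""


# ---------------------------------------------------------------------------
# resources


class ReferenceGenome:
    """Thin FASTA accessor (pyfaidx-backed); returns uppercase forward-strand
    sequence for 0-based half-open coordinates."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        sizes = self.chrom_sizes()
        if chrom not in sizes:
            raise KeyError(f"chromosome {chrom!r} not in reference {self.path}")
        if start < 0 or end > sizes[chrom]:
            raise ValueError(
                f"{chrom}:{start}-{end} outside chromosome bounds (length {sizes[chrom]})"
            )
        return str(self._fasta[chrom][start:end])


class CoverageTrack:
    """Per-base numeric track loaded from bedGraph (or bigWig when pyBigWig
    is importable). Whole chromosomes are materialized once and sliced per
    anchor; bases not covered by any interval are imputed as 0 (counted and
    logged)."""

    def __init__(self, arrays: Mapping[str, np.ndarray], name: str = "track"):
        self.name = name
        self._arrays = {c: np.asarray(a, dtype=np.float32) for c, a in arrays.items()}

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom_sizes: Mapping[str, int], name: str | None = None) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
        arrays = {c: np.zeros(n, dtype=np.float32) for c, n in chrom_sizes.items()}
        covered = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = arrays.get(chrom)
            if arr is None:
                continue
            for s, e, v in zip(sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy()):
                arr[s:e] = v
                covered += e - s
        total = sum(len(a) for a in arrays.values())
        if covered < total:
            logger.info("%s: %d of %d bases uncovered, imputed as 0", path, total - covered, total)
        return cls(arrays, name=name or Path(path).stem)

    @classmethod
    def from_bigwig(cls, path: str | Path, name: str | None = None) -> "CoverageTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        arrays = {}
        for chrom, n in bw.chroms().items():
            vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, n), dtype=np.float32))
            arrays[chrom] = vals
        bw.close()
        return cls(arrays, name=name or Path(path).stem)

    @classmethod
    def open(cls, path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> "CoverageTrack":
        p = Path(path)
        if p.suffix.lower() in (".bw", ".bigwig"):
            return cls.from_bigwig(p)
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to load a bedGraph track")
        return cls.from_bedgraph(p, chrom_sizes)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self._arrays[chrom]
        if start < 0 or end > arr.size:
            raise ValueError(f"{chrom}:{start}-{end} outside track bounds")
        return arr[start:end]

    def library_size(self) -> float:
        """Total signal over the genome, used for counts-per-million scaling."""
        return float(sum(a.sum() for a in self._arrays.values()))


# ---------------------------------------------------------------------------
# elementary featurizers


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode DNA: A->[1,0,0,0], C->[0,1,0,0], G->[0,0,1,0],
    T->[0,0,0,1]; N (ambiguous) -> all-zero row. Case-insensitive."""
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq.upper()):
        if ch in _BASE_INDEX:
            out[i, _BASE_INDEX[ch]] = 1.0
        elif ch != "N":
            raise EncodingError(f"unsupported base {ch!r} at position {i}")
    return out


def fetch_anchor_sequence(anchor: GenomicAnchor, reference: ReferenceGenome) -> str:
    """Forward-strand, uppercase sequence of the standardized anchor."""
    return reference.fetch(anchor.chrom, anchor.start, anchor.end)


def bin_track(values: np.ndarray, window: int = WINDOW, step: int = STEP) -> np.ndarray:
    """Sliding-window means over a per-base vector.

    Window ``i`` covers ``values[i*step : i*step + window]``; the number of
    windows is (len - window)/step + 1, which must be integral (21 for the
    default 2000/1000/50 geometry).
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    if (n - window) % step != 0:
        raise ValueError(f"(length - window) = {n - window} not divisible by step {step}")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.arange(0, n - window + 1, step)
    return ((csum[starts + window] - csum[starts]) / window).astype(np.float64)


def normalize_coverage(raw: np.ndarray, library_size: float) -> np.ndarray:
    """Counts-per-million scaling: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    return np.asarray(raw, dtype=np.float64) * 1e6 / library_size


def compute_distance(a1: GenomicAnchor, a2: GenomicAnchor) -> int:
    if a1.chrom != a2.chrom:
        raise ValueError("anchors on different chromosomes have no distance")
    return abs(a1.midpoint - a2.midpoint)


def scale_distance(bp: float, scale: float = DISTANCE_SCALE) -> float:
    """Map a base-pair distance into [0, 1] by the distance-filter bound."""
    return bp / scale


# ---------------------------------------------------------------------------
# bundles

MODALITIES = ("S", "R", "D", "aux")


@dataclass
class BundleSet:
    """Feature bundles for a set of interactions, as stacked arrays.

    Shapes (N interactions, 2 anchors as leading channel axis):
      S   (N, 2, anchor_len, 4)      one-hot sequence
      R   (N, 2, n_windows, M)       windowed read features, M tracks
      aux (N, 2, n_windows, K)       windowed conservation/shape features
      D   (N,)                       scaled distance
      y   (N,)                       labels (float32 0/1), optional
    """

    arrays: dict[str, np.ndarray]
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.arrays)

    def __len__(self) -> int:
        return len(next(iter(self.arrays.values())))

    def subset(self, idx: np.ndarray) -> "BundleSet":
        return BundleSet(
            arrays={k: v[idx] for k, v in self.arrays.items()},
            labels=None if self.labels is None else self.labels[idx],
            meta=dict(self.meta),
        )

    def with_features(self, active: Sequence[str]) -> "BundleSet":
        missing = [m for m in active if m not in self.arrays]
        if missing:
            raise ResourceError(f"bundle lacks modalities {missing}")
        return BundleSet(
            arrays={k: self.arrays[k] for k in active},
            labels=self.labels, meta=dict(self.meta),
        )

    @staticmethod
    def concat(sets: Sequence["BundleSet"]) -> "BundleSet":
        keys = sets[0].arrays.keys()
        if any(s.arrays.keys() != keys for s in sets):
            raise ValueError("bundle sets have differing modalities")
        arrays = {k: np.concatenate([s.arrays[k] for s in sets]) for k in keys}
        labels = None
        if all(s.labels is not None for s in sets):
            labels = np.concatenate([s.labels for s in sets])
        return BundleSet(arrays=arrays, labels=labels)

    # -- on-disk container: one .npy per component plus a JSON manifest
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"components": list(self.arrays), "has_labels": self.labels is not None,
                    "meta": self.meta}
        for k, v in self.arrays.items():
            np.save(directory / f"{k}.npy", v)
        if self.labels is not None:
            np.save(directory / "labels.npy", self.labels)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "BundleSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        arrays = {k: np.load(directory / f"{k}.npy") for k in manifest["components"]}
        labels = np.load(directory / "labels.npy") if manifest["has_labels"] else None
        return cls(arrays=arrays, labels=labels, meta=manifest.get("meta", {}))


def build_feature_bundles(
    dataset: Sequence[LabeledInteraction],
    reference: ReferenceGenome | None = None,
    tracks: Sequence[CoverageTrack] | None = None,
    aux_tracks: Sequence[CoverageTrack] | None = None,
    active: Sequence[str] = ("S", "R", "D"),
    window: int = WINDOW,
    step: int = STEP,
    distance_scale: float = DISTANCE_SCALE,
) -> BundleSet:
    """Assemble the model input for each interaction.

    Exactly the requested modalities are produced; a modality whose backing
    resource is absent raises :class:`ResourceError` naming it. Output order
    follows input order and the construction is deterministic.
    """
    active = tuple(active)
    unknown = [m for m in active if m not in MODALITIES]
    if unknown:
        raise ValueError(f"unknown feature modalities {unknown}")
    if not active:
        raise ValueError("at least one feature modality must be active")
    if "S" in active and reference is None:
        raise ResourceError("modality 'S' requires a reference genome")
    if "R" in active and not tracks:
        raise ResourceError("modality 'R' requires coverage tracks")
    if "aux" in active and not aux_tracks:
        raise ResourceError("modality 'aux' requires auxiliary tracks")

    n = len(dataset)
    arrays: dict[str, np.ndarray] = {}

    if "S" in active:
        length = dataset[0].anchor1.length if n else 0
        S = np.zeros((n, 2, length, 4), dtype=np.float32)
        for i, d in enumerate(dataset):
            for a, anchor in enumerate((d.anchor1, d.anchor2)):
                S[i, a] = one_hot_encode(fetch_anchor_sequence(anchor, reference))
        arrays["S"] = S

    def _windowed(track_list: Sequence[CoverageTrack]) -> np.ndarray:
        n_windows = (dataset[0].anchor1.length - window) // step + 1 if n else 0
        out = np.zeros((n, 2, n_windows, len(track_list)), dtype=np.float32)
        libs = [t.library_size() for t in track_list]
        for t, (track, lib) in enumerate(zip(track_list, libs)):
            for i, d in enumerate(dataset):
                for a, anchor in enumerate((d.anchor1, d.anchor2)):
                    raw = track.values(anchor.chrom, anchor.start, anchor.end)
                    out[i, a, :, t] = bin_track(normalize_coverage(raw, lib), window, step)
        return out

    if "R" in active:
        arrays["R"] = _windowed(tracks)
    if "aux" in active:
        arrays["aux"] = _windowed(aux_tracks)
    if "D" in active:
        arrays["D"] = np.array(
            [scale_distance(d.distance, distance_scale) for d in dataset], dtype=np.float32
        )

    labels = np.array([d.label for d in dataset], dtype=np.float32) if n else np.zeros(0, np.float32)
    return BundleSet(arrays=arrays, labels=labels, meta={"active": list(active)})
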