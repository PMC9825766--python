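import numpy as np
import pytest

from loopnet.features import BundleSet
from loopnet.interactions import CandidateInteraction, GenomicAnchor
from loopnet.nn.model import ModelConfig


class FakeReference:
    """In-memory reference genome for unit tests."""

    def __init__(self, chroms: dict[str, str]):
        self.chroms = chroms

    def chrom_sizes(self):
        return {c: len(s) for c, s in self.chroms.items()}

    def fetch(self, chrom, start, end):
        seq = self.chroms[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"{chrom}:{start}-{end} out of bounds")
        return seq[start:end].upper()


@pytest.fixture
def fake_reference():
    rng = np.random.default_rng(1)
    chroms = {
        "chr1": "".join(rng.choice(list("ACGT"), size=200_000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=200_000)),
    }
    return FakeReference(chroms)


def make_candidate(chrom="chr1", mid1=10_000, dist=20_000, fdr=0.05, length=2000,
                   itype="PE", tissue="T1"):
    a1 = GenomicAnchor(chrom, mid1 - length // 2, mid1 + length // 2)
    mid2 = mid1 + dist
    a2 = GenomicAnchor(chrom, mid2 - length // 2, mid2 + length // 2)
    return CandidateInteraction(a1, a2, fdr, itype=itype, tissue=tissue)


@pytest.fixture
def tiny_model_cfg():
    """Small but structurally complete architecture for fast training tests."""
    return ModelConfig(
        features=("S", "R", "D"), anchor_len=100, n_windows=21, n_read_tracks=3,
        filters=(8, 6, 4, 4), dilations=(1, 2, 3, 4), seq_kernel=(10, 4),
        seq_stride=(5, 4), fusion_filters=8, hidden_units=16, dropout=0.1, seed=0,
    )


def random_bundles(n, cfg: ModelConfig, seed=0, signal=False):
    """Random feature bundles matching a model config; with ``signal`` the
    distance feature separates the classes."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n).astype(np.float32)
    arrays = {}
    if "S" in cfg.features:
        idx = rng.integers(0, 4, size=(n, 2, cfg.anchor_len))
        S = np.zeros((n, 2, cfg.anchor_len, 4), dtype=np.float32)
        np.put_along_axis(S, idx[..., None], 1.0, axis=3)
        arrays["S"] = S
    if "R" in cfg.features:
        arrays["R"] = rng.random((n, 2, cfg.n_windows, cfg.n_read_tracks)).astype(np.float32)
    if "aux" in cfg.features:
        arrays["aux"] = rng.random((n, 2, cfg.n_windows, cfg.n_aux_tracks)).astype(np.float32)
    if "D" in cfg.features:
        d = rng.random(n).astype(np.float32)
        if signal:
            d = (0.3 * d + 0.5 * (1 - labels)).astype(np.float32)
        arrays["D"] = d
    return BundleSet(arrays=arrays, labels=labels)
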