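"""The interaction classifier: per-modality dense blocks, a fusion
convolution, distance concatenation and a fully connected head.

Architecture (defaults): one-hot sequence (2000x4, two anchors as input
channels) and windowed read features (21xM, two anchors as channels) each
pass through their own four-layer dense block (filters 64/32/16/16,
dilations 1-4). The sequence block's first layer uses kernel 20x4 with
stride 10x4; the read block's first layer uses kernel 3x1 with stride 1x1;
all later in-block layers are stride 1x1 with 'same' padding so the
concatenation shapes align. Block outputs are flattened to (positions x
channels) grids, stacked row-wise across modalities and fused by a 4x4
convolution with stride 4x4, followed by global average pooling. The pooled
vector, concatenated with the scaled anchor distance when active, feeds a
256-unit fully connected layer with ReLU and a sigmoid output unit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .blocks import ConvUnit, DenseBlock
from .layers import Linear, Parameter

CONV_MODALITIES = ("S", "R", "aux")


@dataclass(frozen=True)
class ModelConfig:
    """Declarative architecture description.

    ``features`` selects the active modalities out of S (sequence), R
    (reads), D (distance) and aux (conservation / DNA-shape); any nonempty
    subset is a valid ablation.
    """

    features: tuple[str, ...] = ("S", "R", "D")
    anchor_len: int = 2000
    n_read_tracks: int = 4
    n_aux_tracks: int = 1
    n_windows: int = 21
    filters: tuple[int, ...] = (64, 32, 16, 16)
    dilations: tuple[int, ...] = (1, 2, 3, 4)
    seq_kernel: tuple[int, int] = (20, 4)
    seq_stride: tuple[int, int] = (10, 4)
    read_kernel: tuple[int, int] = (3, 1)
    read_stride: tuple[int, int] = (1, 1)
    inner_kernel: tuple[int, int] = (3, 1)
    fusion_kernel: tuple[int, int] = (4, 4)
    fusion_stride: tuple[int, int] = (4, 4)
    fusion_filters: int = 64
    hidden_units: int = 256
    dropout: float = 0.2
    prelu_init: float = 0.25
    seed: int = 0

    def __post_init__(self):
        feats = tuple(self.features)
        if not feats:
            raise ValueError("at least one feature modality must be active")
        unknown = [f for f in feats if f not in ("S", "R", "D", "aux")]
        if unknown:
            raise ValueError(f"unknown feature modalities {unknown}")
        if self.hidden_units <= 0 or self.fusion_filters <= 0:
            raise ValueError("layer widths must be positive")
        if any(f <= 0 for f in self.filters) or any(d < 1 for d in self.dilations):
            raise ValueError("filters must be positive and dilations >= 1")
        object.__setattr__(self, "features", feats)

    @property
    def conv_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.features if f in CONV_MODALITIES)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        for key in ("features", "filters", "dilations", "seq_kernel", "seq_stride",
                    "read_kernel", "read_stride", "inner_kernel", "fusion_kernel",
                    "fusion_stride"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def _modality_input_shape(cfg: ModelConfig, mod: str) -> tuple[int, int]:
    if mod == "S":
        return (cfg.anchor_len, 4)
    if mod == "R":
        return (cfg.n_windows, cfg.n_read_tracks)
    if mod == "aux":
        return (cfg.n_windows, cfg.n_aux_tracks)
    raise ValueError(mod)


class FeatureExtractor:
    """Per-modality dense blocks + fusion convolution + global average
    pooling; emits one fused feature vector per interaction."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks: dict[str, DenseBlock] = {}
        grid_rows = 0
        for mod in cfg.conv_features:
            in_shape = _modality_input_shape(cfg, mod)
            first_kernel = cfg.seq_kernel if mod == "S" else cfg.read_kernel
            first_stride = cfg.seq_stride if mod == "S" else cfg.read_stride
            block = DenseBlock(
                in_channels=2, in_shape=in_shape, filters=cfg.filters,
                dilations=cfg.dilations, first_kernel=first_kernel,
                first_stride=first_stride, inner_kernel=cfg.inner_kernel,
                dropout=cfg.dropout, prelu_init=cfg.prelu_init, rng=rng,
            )
            self.blocks[mod] = block
            grid_rows += block.out_shape[0] * block.out_shape[1]
        self.grid_shape = (grid_rows, sum(cfg.filters)) if self.blocks else (0, 0)
        self.fusion = None
        self.out_dim = 0
        if self.blocks:
            if self.grid_shape[0] < cfg.fusion_kernel[0] or self.grid_shape[1] < cfg.fusion_kernel[1]:
                raise ValueError(
                    f"fused grid {self.grid_shape} smaller than fusion kernel {cfg.fusion_kernel}"
                )
            self.fusion = ConvUnit(
                1, cfg.fusion_filters, cfg.fusion_kernel, cfg.fusion_stride,
                padding="valid", dropout=cfg.dropout, prelu_init=cfg.prelu_init, rng=rng,
            )
            self.fusion_out_shape = self.fusion.out_shape(self.grid_shape)
            self.out_dim = cfg.fusion_filters
        self._cache = None

    # -- parameter plumbing
    def params(self) -> list[Parameter]:
        ps = [p for b in self.blocks.values() for p in b.params()]
        if self.fusion is not None:
            ps += self.fusion.params()
        return ps

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for mod, block in self.blocks.items():
            out.update(block.state_dict(prefix=f"{prefix}block_{mod}."))
        if self.fusion is not None:
            out.update(self.fusion.state_dict(prefix=f"{prefix}fusion."))
        return out

    def load_state_dict(self, state, prefix: str = "") -> None:
        for mod, block in self.blocks.items():
            block.load_state_dict(state, prefix=f"{prefix}block_{mod}.")
        if self.fusion is not None:
            self.fusion.load_state_dict(state, prefix=f"{prefix}fusion.")

    # -- computation
    def forward(self, batch: Mapping[str, np.ndarray], train: bool = False) -> np.ndarray:
        if not self.blocks:
            n = len(batch["D"])
            return np.zeros((n, 0), dtype=np.float32)
        grids = []
        block_shapes = {}
        for mod, block in self.blocks.items():
            if mod not in batch:
                raise ValueError(f"batch lacks modality {mod!r} required by the model")
            y = block.forward(np.ascontiguousarray(batch[mod], dtype=np.float32), train=train)
            block_shapes[mod] = y.shape
            n, c, h, w = y.shape
            grids.append(y.transpose(0, 2, 3, 1).reshape(n, h * w, c))
        grid = np.concatenate(grids, axis=1)[:, None, :, :]  # (N,1,rows,channels)
        fused = self.fusion.forward(grid, train=train)  # (N,F,oh,ow)
        feat = fused.mean(axis=(2, 3))
        if train:
            self._cache = (block_shapes, fused.shape)
        return feat

    def backward(self, dfeat: np.ndarray) -> None:
        block_shapes, fused_shape = self._cache
        self._cache = None
        n, f, oh, ow = fused_shape
        dfused = np.broadcast_to(dfeat[:, :, None, None] / (oh * ow), fused_shape).astype(np.float32)
        dgrid = self.fusion.backward(dfused)[:, 0]  # (N,rows,channels)
        at = 0
        for mod, block in self.blocks.items():
            _, c, h, w = block_shapes[mod]
            rows = h * w
            dy = dgrid[:, at: at + rows, :].reshape(n, h, w, c).transpose(0, 3, 1, 2)
            block.backward(np.ascontiguousarray(dy))
            at += rows

    def describe(self) -> dict:
        out = {
            "blocks": {mod: block.describe() for mod, block in self.blocks.items()},
            "grid_shape": tuple(self.grid_shape),
            "fused_dim": self.out_dim,
        }
        if self.fusion is not None:
            out["fusion"] = self.fusion.spec()
            out["fusion_out_shape"] = tuple(self.fusion_out_shape)
        return out


class _Head:
    """Fully connected classifier: Linear -> ReLU -> Linear -> (sigmoid)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.fc1 = Linear(in_dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, 1, rng=rng)
        self.fc2.W.data *= 0.1  # start near p=0.5
        self._relu_mask = None

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def state_dict(self, prefix=""):
        out = self.fc1.state_dict(prefix=f"{prefix}fc1.")
        out.update(self.fc2.state_dict(prefix=f"{prefix}fc2."))
        return out

    def load_state_dict(self, state, prefix=""):
        self.fc1.load_state_dict(state, prefix=f"{prefix}fc1.")
        self.fc2.load_state_dict(state, prefix=f"{prefix}fc2.")

    def forward(self, x, train=False):
        h = self.fc1.forward(x, train=train)
        mask = h > 0
        h = h * mask
        if train:
            self._relu_mask = mask
        return self.fc2.forward(h, train=train)[:, 0]

    def backward(self, dz):
        dh = self.fc2.backward(dz[:, None])
        dh = dh * self._relu_mask
        self._relu_mask = None
        return self.fc1.backward(dh)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class InteractionNet:
    """The base (single-tissue) classifier; also serves as the shared or
    private feature extractor in the multi-task and transfer paradigms.

    Contract: ``predict`` returns probabilities strictly inside (0, 1);
    ``extract`` returns the fused post-pooling feature vectors and is
    deterministic in inference mode; ``freeze_extractor`` pins the extractor
    so that subsequent training only updates the classifier head;
    ``save``/``load`` round-trip the configuration and all weights.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.extractor = FeatureExtractor(cfg, rng)
        self._d_dim = 1 if "D" in cfg.features else 0
        self.head = _Head(self.extractor.out_dim + self._d_dim, cfg.hidden_units, rng)
        self._frozen = False
        self._cache_dfeat_dim = None

    # -- training interface
    def trainable_params(self) -> list[Parameter]:
        ps = [] if self._frozen else list(self.extractor.params())
        return ps + self.head.params()

    def all_params(self) -> list[Parameter]:
        return list(self.extractor.params()) + self.head.params()

    def forward_logits(self, batch: Mapping[str, np.ndarray], train: bool = False) -> np.ndarray:
        extractor_train = train and not self._frozen
        feat = self.extractor.forward(batch, train=extractor_train)
        if self._d_dim:
            feat = np.concatenate([feat, np.asarray(batch["D"], np.float32)[:, None]], axis=1)
        self._cache_dfeat_dim = feat.shape[1] - self._d_dim
        return self.head.forward(feat, train=train)

    def backward_logits(self, dz: np.ndarray) -> None:
        dfeat = self.head.backward(dz)
        if not self._frozen and self.extractor.blocks:
            self.backward_extractor(dfeat[:, : self._cache_dfeat_dim])

    def backward_extractor(self, dfeat: np.ndarray) -> None:
        self.extractor.backward(dfeat)

    # -- user-facing contract
    def predict(self, bundles, batch_size: int = 256) -> np.ndarray:
        arrays = bundles.arrays if hasattr(bundles, "arrays") else bundles
        n = len(next(iter(arrays.values())))
        out = np.empty(n, dtype=np.float64)
        for at in range(0, n, batch_size):
            batch = {k: v[at: at + batch_size] for k, v in arrays.items()}
            out[at: at + batch_size] = _sigmoid(self.forward_logits(batch, train=False))
        return np.clip(out, 1e-12, 1 - 1e-12)

    def extract(self, bundles, batch_size: int = 256) -> np.ndarray:
        arrays = bundles.arrays if hasattr(bundles, "arrays") else bundles
        n = len(next(iter(arrays.values())))
        out = np.empty((n, self.extractor.out_dim), dtype=np.float32)
        for at in range(0, n, batch_size):
            batch = {k: v[at: at + batch_size] for k, v in arrays.items()}
            out[at: at + batch_size] = self.extractor.forward(batch, train=False)
        return out

    def freeze_extractor(self) -> None:
        self._frozen = True

    def unfreeze_extractor(self) -> None:
        self._frozen = False

    # -- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        out = self.extractor.state_dict(prefix="extractor.")
        out.update(self.head.state_dict(prefix="head."))
        return out

    def load_state_dict(self, state) -> None:
        self.extractor.load_state_dict(state, prefix="extractor.")
        self.head.load_state_dict(state, prefix="head.")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(self.cfg.to_json())
        np.savez(directory / "weights.npz", **self.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "InteractionNet":
        directory = Path(directory)
        cfg = ModelConfig.from_json((directory / "config.json").read_text())
        net = cls(cfg)
        with np.load(directory / "weights.npz") as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net

    def describe(self) -> dict:
        out = self.extractor.describe()
        out["features"] = tuple(self.cfg.features)
        out["classifier_hidden"] = self.cfg.hidden_units
        out["classifier_input"] = self.head.in_dim
        out["n_parameters"] = int(sum(p.data.size for p in self.all_params()))
        return out


def build_model(cfg: ModelConfig) -> InteractionNet:
    return InteractionNet(cfg)


def build_ablation(cfg: ModelConfig, active: Sequence[str]) -> InteractionNet:
    """A model consuming exactly the ``active`` modality subset."""
    from dataclasses import replace

    return InteractionNet(replace(cfg, features=tuple(active)))


class MultiTaskNet:
    """Shared/private ("shared knowledge transfer") classifier.

    A pretrained shared extractor is frozen; a private extractor of
    identical architecture is trained on the target tissue; the classifier
    consumes [common || private] fused features (plus distance when active).
    """

    def __init__(self, cfg: ModelConfig, shared: InteractionNet):
        compat = (
            shared.cfg.conv_features == cfg.conv_features
            and shared.cfg.anchor_len == cfg.anchor_len
            and shared.cfg.n_windows == cfg.n_windows
            and shared.cfg.n_read_tracks == cfg.n_read_tracks
            and shared.cfg.filters == cfg.filters
            and shared.cfg.fusion_filters == cfg.fusion_filters
        )
        if not compat:
            raise ValueError("shared extractor architecture incompatible with target config")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        self.shared = shared.extractor  # frozen by construction: never backpropagated
        self.private = FeatureExtractor(cfg, rng)
        self._d_dim = 1 if "D" in cfg.features else 0
        self.head = _Head(self.shared.out_dim + self.private.out_dim + self._d_dim,
                          cfg.hidden_units, rng)

    def trainable_params(self):
        return self.private.params() + self.head.params()

    def all_params(self):
        return self.shared.params() + self.private.params() + self.head.params()

    def forward_logits(self, batch, train=False):
        common = self.shared.forward(batch, train=False)  # frozen: inference mode
        priv = self.private.forward(batch, train=train)
        parts = [common, priv]
        if self._d_dim:
            parts.append(np.asarray(batch["D"], np.float32)[:, None])
        return self.head.forward(np.concatenate(parts, axis=1), train=train)

    def backward_logits(self, dz):
        dfeat = self.head.backward(dz)
        lo = self.shared.out_dim
        if self.private.blocks:
            self.private.backward(dfeat[:, lo: lo + self.private.out_dim])

    def predict(self, bundles, batch_size: int = 256) -> np.ndarray:
        arrays = bundles.arrays if hasattr(bundles, "arrays") else bundles
        n = len(next(iter(arrays.values())))
        out = np.empty(n, dtype=np.float64)
        for at in range(0, n, batch_size):
            batch = {k: v[at: at + batch_size] for k, v in arrays.items()}
            out[at: at + batch_size] = _sigmoid(self.forward_logits(batch, train=False))
        return np.clip(out, 1e-12, 1 - 1e-12)

    def state_dict(self):
        out = self.shared.state_dict(prefix="shared.")
        out.update(self.private.state_dict(prefix="private."))
        out.update(self.head.state_dict(prefix="head."))
        return out

    def load_state_dict(self, state):
        self.shared.load_state_dict(state, prefix="shared.")
        self.private.load_state_dict(state, prefix="private.")
        self.head.load_state_dict(state, prefix="head.")

    def describe(self) -> dict:
        return {
            "shared": self.shared.describe(),
            "private": self.private.describe(),
            "classifier_hidden": self.cfg.hidden_units,
            "classifier_input": self.head.in_dim,
        }


def load_model(directory: str | Path) -> InteractionNet:
    return InteractionNet.load(directory)
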