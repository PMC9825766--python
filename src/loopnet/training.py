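"""Training regimes for the interaction classifier.

Three paradigms are supported:

* **Base** — one network per tissue, trained only on that tissue's labeled
  interactions (70/15/15 train/validation/test split).
* **Multi-task** ("shared knowledge transfer") — a shared feature extractor
  is pretrained on labeled interactions pooled from source tissues
  (85/15 split), then frozen; a private extractor of identical architecture
  is trained on the target tissue, and the tissue-specific classifier
  consumes the concatenated [common || private] fused features.
* **Transfer** — the network is initialized from the pretrained shared
  extractor and the whole network (extractor and classifier) is fine-tuned
  on the target tissue.

All regimes optimize binary cross-entropy with Adam, initial learning rate
1e-4 decayed exponentially per epoch, at most 200 epochs, stopping early
when validation loss has not decreased for five consecutive epochs; the
best-validation weights are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import BundleSet
from .interactions import DatasetSplit, split_dataset
from .nn.model import InteractionNet, ModelConfig, MultiTaskNet
from .nn.optim import Adam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    lr_decay: float = 0.96
    max_epochs: int = 200
    patience: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < self.patience:
            raise ValueError("max_epochs must be >= patience")


@dataclass(frozen=True)
class ParadigmSpec:
    """What to train: the paradigm, the target tissue and, for the shared
    paradigms, how the pretraining tissue set is chosen."""

    mode: str = "base"  # base | multitask | transfer
    target: str = ""
    pretrain_mode: str = "all-others"  # all-others | group:<name> | top-k
    top_k: int = 5

    def __post_init__(self):
        if self.mode not in ("base", "multitask", "transfer"):
            raise ValueError(f"unknown paradigm mode {self.mode!r}")


@dataclass
class TrainingLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_epoch: int = -1


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy computed from logits, with its gradient."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / z.size).astype(np.float32)


def _eval_loss(net, bundles: BundleSet, batch_size: int) -> float:
    z_all = []
    arrays = bundles.arrays
    n = len(bundles)
    for at in range(0, n, batch_size):
        batch = {k: v[at: at + batch_size] for k, v in arrays.items()}
        z_all.append(net.forward_logits(batch, train=False))
    loss, _ = bce_with_logits(np.concatenate(z_all), bundles.labels)
    return loss


def fit(net, train_set: BundleSet, val_set: BundleSet, cfg: TrainConfig) -> TrainingLog:
    """Mini-batch training with per-epoch exponential learning-rate decay and
    patience-based early stopping on validation loss."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.trainable_params(), lr=cfg.learning_rate)
    log = TrainingLog()
    best_state = None
    bad = 0
    arrays = train_set.arrays
    y = train_set.labels
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate * (cfg.lr_decay ** epoch)
        opt.set_lr(lr)
        log.learning_rates.append(lr)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for at in range(0, n, cfg.batch_size):
            idx = perm[at: at + cfg.batch_size]
            batch = {k: v[idx] for k, v in arrays.items()}
            opt.zero_grad()
            z = net.forward_logits(batch, train=True)
            loss, dz = bce_with_logits(z, y[idx])
            net.backward_logits(dz)
            opt.step()
            epoch_loss += loss * idx.size
        log.train_losses.append(epoch_loss / n)
        val_loss = _eval_loss(net, val_set, cfg.batch_size)
        log.val_losses.append(val_loss)
        if val_loss < log.best_val_loss:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                log.stopped_epoch = epoch
                break
    if log.stopped_epoch < 0:
        log.stopped_epoch = len(log.val_losses) - 1
    if best_state is not None:
        net.load_state_dict(best_state)
    return log


# ---------------------------------------------------------------------------
# paradigms


def train_base(
    bundles: BundleSet,
    split: DatasetSplit,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[InteractionNet, TrainingLog]:
    """Single-tissue training on the split's train/validation parts."""
    net = InteractionNet(model_cfg)
    log = fit(net, bundles.subset(split.train), bundles.subset(split.validation), train_cfg)
    return net, log


def pretrain_shared(
    sources: Mapping[str, BundleSet],
    target: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    fractions: Sequence[float] = (0.85, 0.15),
) -> tuple[InteractionNet, TrainingLog]:
    """Pretrain the shared feature extractor on interactions pooled from all
    source tissues (the target tissue must not be in the pool). The attached
    classifier head is a throwaway used only to drive pretraining."""
    if not sources:
        raise ValueError("at least one source tissue is required")
    if target in sources:
        raise ValueError(f"target tissue {target!r} must be excluded from the pretraining pool")
    pooled = BundleSet.concat(list(sources.values()))
    split = split_dataset(len(pooled), fractions=fractions, seed=train_cfg.seed)
    net = InteractionNet(model_cfg)
    log = fit(net, pooled.subset(split.train), pooled.subset(split.validation), train_cfg)
    return net, log


def train_multitask(
    bundles: BundleSet,
    split: DatasetSplit,
    shared: InteractionNet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[MultiTaskNet, TrainingLog]:
    """Shared/private training: the pretrained shared extractor stays frozen,
    a fresh private extractor and classifier are trained on the target."""
    net = MultiTaskNet(model_cfg, shared)
    log = fit(net, bundles.subset(split.train), bundles.subset(split.validation), train_cfg)
    return net, log


def train_transfer(
    bundles: BundleSet,
    split: DatasetSplit,
    shared: InteractionNet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[InteractionNet, TrainingLog]:
    """Fine-tune the whole network (pretrained extractor + fresh classifier)
    on the target tissue."""
    net = InteractionNet(model_cfg)
    net.extractor.load_state_dict(shared.extractor.state_dict())
    log = fit(net, bundles.subset(split.train), bundles.subset(split.validation), train_cfg)
    return net, log


def select_pretraining_tissues(
    target: str,
    tissues: Sequence[str],
    mode: str = "all-others",
    groups: Mapping[str, Sequence[str]] | None = None,
    similarity=None,
    k: int = 5,
) -> list[str]:
    """Choose the pretraining tissue set for a target tissue.

    Modes: ``all-others`` (every tissue but the target), ``group:<name>``
    (a predefined group minus the target), or ``top-k`` (the k tissues most
    similar to the target per the similarity matrix, ties broken by tissue
    id).
    """
    if target not in tissues:
        raise ValueError(f"unknown target tissue {target!r}")
    if mode == "all-others":
        return [t for t in tissues if t != target]
    if mode.startswith("group:"):
        name = mode.split(":", 1)[1]
        if not groups or name not in groups:
            raise ValueError(f"unknown tissue group {name!r}")
        return [t for t in groups[name] if t != target]
    if mode == "top-k":
        if similarity is None:
            raise ValueError("top-k mode requires a similarity matrix")
        from .similarity import top_k_similar

        return top_k_similar(similarity, target, k=k)
    raise ValueError(f"unknown pretraining mode {mode!r}")
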