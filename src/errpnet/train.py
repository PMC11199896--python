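"""Pretraining and fine-tuning of the ErrP network.

Pretraining runs stratified K-fold cross-validation (K = 5): each fold's
training partition is balanced with SVM-SMOTE (the validation partition is
never oversampled — oversampling happens inside each CV iteration precisely
so synthetic minority samples cannot leak into validation), then trained
with SGD (momentum 0.9), a cosine learning-rate decay from 1e-4, batch 32,
200 epochs, and label-smoothed cross-entropy (eps = 0.1).  The fold model
with the best validation accuracy (ties broken by lower final validation
loss) is the transfer checkpoint.

Fine-tuning continues training all weights (no freezing) on one target
subject's data with Adam at 1e-5 — ten times below the pretraining rate —
under the same cosine decay for 100 epochs, with no internal validation
split.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .imbalance import OversampleConfig, oversample_epochs
from .io_store import EpochSet
from .model import ErrPNet, ModelConfig, build
from .nn import SGD, Adam, Tensor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one phase.

    Use :meth:`pretrain_defaults` / :meth:`finetune_defaults` for the two
    phases' canonical settings.
    """

    phase: str = "pretrain"
    optimizer: str = "sgd"
    lr_init: float = 1e-4
    lr_min: float = 0.0
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    label_smoothing_eps: float = 0.1
    k_folds: int = 5
    oversample: bool = True
    oversample_config: OversampleConfig = field(default_factory=OversampleConfig)
    seed: int = 0

    def __post_init__(self):
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError("phase must be 'pretrain' or 'finetune'")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    @classmethod
    def pretrain_defaults(cls, **overrides) -> "TrainConfig":
        base = dict(phase="pretrain", optimizer="sgd", lr_init=1e-4, epochs=200)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def finetune_defaults(cls, **overrides) -> "TrainConfig":
        base = dict(phase="finetune", optimizer="adam", lr_init=1e-5, epochs=100)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainConfig":
        raw = dict(raw)
        if "oversample_config" in raw and isinstance(raw["oversample_config"], dict):
            raw["oversample_config"] = OversampleConfig(**raw["oversample_config"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown train config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class FoldResult:
    network: ErrPNet
    train_indices: np.ndarray  # original (pre-oversampling) row indices
    val_indices: np.ndarray
    history: list[dict]  # per epoch: lr, train_loss, val_accuracy, val_auc, val_loss
    val_accuracy: float
    val_auc: float
    val_loss: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    best_fold: int

    @property
    def best_network(self) -> ErrPNet:
        return self.folds[self.best_fold].network


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0):
    """Shuffled, stratified K-fold splits: list of (train_idx, val_idx).

    Folds are disjoint, cover every index, and hold per-fold class
    proportions within one sample of the global proportions.
    """
    labels = np.asarray(labels).reshape(-1)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members, got counts {counts.tolist()}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in splitter.split(np.zeros_like(labels), labels)]


def cosine_lr(t: int, config: TrainConfig) -> float:
    """Cosine decay: eta(t) = lr_min + (lr_init - lr_min)(1 + cos(pi t/T))/2."""
    if not 0 <= t <= config.epochs:
        raise ValueError(f"epoch index {t} outside [0, {config.epochs}]")
    if config.epochs == 0:
        return config.lr_init
    cos = math.cos(math.pi * t / config.epochs)
    return config.lr_min + 0.5 * (config.lr_init - config.lr_min) * (1.0 + cos)


def smoothed_cross_entropy(probabilities: np.ndarray, labels: np.ndarray,
                           eps: float = 0.1) -> float:
    """Label-smoothed cross-entropy on probability rows.

    Targets are ``(1 - eps) * onehot + eps / n_classes``; the loss is the
    batch mean of ``-sum(target * log p)``.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels).astype(int).reshape(-1)
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    if p.ndim != 2 or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to one")
    n, c = p.shape
    target = np.full((n, c), eps / c)
    target[np.arange(n), labels] += 1.0 - eps
    return float(-(target * np.log(np.clip(p, 1e-300, None))).sum(axis=1).mean())


def _smoothed_ce_loss(logits: Tensor, labels: np.ndarray, eps: float) -> Tensor:
    """Differentiable label-smoothed CE on logits (log-softmax path)."""
    n, c = logits.shape
    target = np.full((n, c), eps / c)
    target[np.arange(n), np.asarray(labels, dtype=int)] += 1.0 - eps
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(target)).sum(axis=1).mean()


def _train_network(
    net: ErrPNet,
    train_data: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    val_data: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> list[dict]:
    """Mini-batch training loop shared by pretraining and fine-tuning."""
    from .evaluate import compute_metrics  # local import: avoids a cycle

    params = list(net.parameters())
    if config.optimizer == "sgd":
        opt = SGD(params, lr=config.lr_init, momentum=config.momentum)
    else:
        opt = Adam(params, lr=config.lr_init)
    n = len(train_labels)
    x_all = np.asarray(train_data, dtype=np.float64)[:, None, :, :]
    history: list[dict] = []
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(epoch, config)
        net.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = net.forward_logits(Tensor(x_all[idx]), rng=rng)
            loss = _smoothed_ce_loss(logits, train_labels[idx], config.label_smoothing_eps)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            scores = net.predict_proba(val_data)
            cell = compute_metrics(scores[:, 1], val_labels)
            record.update(val_accuracy=cell.accuracy, val_auc=cell.auc,
                          val_loss=smoothed_cross_entropy(scores, val_labels,
                                                          config.label_smoothing_eps))
        history.append(record)
    return history


def pretrain(
    source: EpochSet,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig | None = None,
) -> CVResult:
    """Stratified K-fold pretraining with per-fold oversampling.

    Each fold trains a freshly initialized network on the SVM-SMOTE-balanced
    training partition and validates on the untouched validation partition.
    Returns all folds plus the index of the best one (highest validation
    accuracy; ties broken by lower final validation loss).
    """
    config = train_config or TrainConfig.pretrain_defaults()
    source.validate_canonical()
    folds: list[FoldResult] = []
    splits = stratified_kfold(source.labels, config.k_folds, config.seed)
    for fold_id, (tr_idx, va_idx) in enumerate(splits):
        assert np.intersect1d(tr_idx, va_idx).size == 0
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(fold_id,)))
        data_tr = source.data[tr_idx].astype(np.float64)
        labels_tr = source.labels[tr_idx].astype(np.int64)
        if config.oversample:
            os_cfg = dataclasses.replace(config.oversample_config, seed=config.seed + fold_id)
            data_tr, labels_tr = oversample_epochs(data_tr, labels_tr, os_cfg)
        net = build(model_config, seed=config.seed + fold_id)
        history = _train_network(net, data_tr, labels_tr, config, rng,
                                 val_data=source.data[va_idx].astype(np.float64),
                                 val_labels=source.labels[va_idx].astype(np.int64))
        last = history[-1] if history else {"val_accuracy": 0.0, "val_auc": float("nan"),
                                            "val_loss": float("inf")}
        folds.append(FoldResult(net, tr_idx.copy(), va_idx.copy(), history,
                                last.get("val_accuracy", 0.0),
                                last.get("val_auc", float("nan")),
                                last.get("val_loss", float("inf"))))
        logger.info("fold %d: val accuracy %.2f%%", fold_id, folds[-1].val_accuracy)
    best = max(range(len(folds)),
               key=lambda i: (folds[i].val_accuracy, -folds[i].val_loss))
    return CVResult(folds, best)


def finetune(
    network: ErrPNet,
    target: EpochSet,
    train_config: TrainConfig | None = None,
) -> ErrPNet:
    """Low-rate continued training of a pretrained network on target data.

    All weights are updated; the input network is left untouched (a clone is
    trained and returned).  Zero epochs returns an identical clone.
    """
    config = train_config or TrainConfig.finetune_defaults()
    target.validate_canonical()
    net = network.clone()
    if config.epochs == 0:
        return net
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xF1,)))
    data = target.data.astype(np.float64)
    labels = target.labels.astype(np.int64)
    if config.oversample and len(np.unique(labels)) == 2 and np.bincount(labels).min() > config.oversample_config.k_neighbors:
        os_cfg = dataclasses.replace(config.oversample_config, seed=config.seed)
        data, labels = oversample_epochs(data, labels, os_cfg)
    _train_network(net, data, labels, config, rng)
    return net
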