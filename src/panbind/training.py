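"""Dual-loss training: SGD with momentum, LR halving and early stopping.

The total loss is the unweighted sum of a regression loss (mean squared
error on logIC50) and a classification loss (binary cross entropy on the
binding probability). Optimization is stochastic gradient descent with
momentum 0.8 from an initial learning rate of 1e-3; the rate is halved
after every 5 epochs without validation improvement (floored at 1e-5) and
training stops after 15 epochs without improvement. The parameters of the
best-validation epoch are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data import Dataset
from .errors import DatasetSizeError, NetworkShapeError
from .network import Network, encode_dataset

__all__ = [
    "mse_loss", "bce_loss", "total_loss",
    "TrainingConfig", "LRSchedule", "EpochRecord", "TrainingLog", "train",
]

#: Probability clamp inside the cross entropy (its log is undefined at 0/1).
BCE_EPS = 1e-7


def mse_loss(pred_log_ic50, true_log_ic50) -> float:
    """Mean squared error between predicted and measured logIC50."""
    pred = np.asarray(pred_log_ic50, dtype=np.float64)
    true = np.asarray(true_log_ic50, dtype=np.float64)
    if pred.shape != true.shape:
        raise NetworkShapeError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return float(np.mean((true - pred) ** 2))


def bce_loss(true_p, pred_p, eps: float = BCE_EPS) -> float:
    """Binary cross entropy; predictions are clamped to [eps, 1-eps]."""
    true = np.asarray(true_p, dtype=np.float64)
    pred = np.asarray(pred_p, dtype=np.float64)
    if pred.shape != true.shape:
        raise NetworkShapeError(f"shape mismatch: {pred.shape} vs {true.shape}")
    pred = np.clip(pred, eps, 1.0 - eps)
    return float(np.mean(-true * np.log(pred) - (1.0 - true) * np.log(1.0 - pred)))


def total_loss(loss_regression: float, loss_classification: float) -> float:
    """The overall loss: plain sum of the two task losses, no weighting."""
    return float(loss_regression) + float(loss_classification)


@dataclass
class TrainingConfig:
    """Schedule constants; every field can be overridden from a YAML file."""

    learning_rate: float = 1e-3
    momentum: float = 0.8
    lr_floor: float = 1e-5
    halve_patience: int = 5       # stagnant epochs between LR halvings
    stop_patience: int = 15       # stagnant epochs before early stop
    batch_size: int = 64
    max_epochs: int = 500
    improvement_tol: float = 1e-6

    @staticmethod
    def from_yaml(path) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return TrainingConfig(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class LRSchedule:
    """Plateau schedule: halve the rate every ``halve_patience`` epochs
    without validation improvement (never below ``lr_floor``); signal a
    stop after ``stop_patience`` stagnant epochs."""

    def __init__(self, config: TrainingConfig) -> None:
        self.config = config
        self.lr = config.learning_rate
        self.stagnant = 0
        self.best = float("inf")

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True to stop."""
        if val_loss < self.best - self.config.improvement_tol:
            self.best = val_loss
            self.stagnant = 0
            return False
        self.stagnant += 1
        if self.stagnant >= self.config.stop_patience:
            return True
        if self.stagnant % self.config.halve_patience == 0:
            self.lr = max(self.lr / 2.0, self.config.lr_floor)
        return False

    @property
    def improved(self) -> bool:
        return self.stagnant == 0


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_total: float
    train_regression: float
    train_classification: float
    val_total: float
    val_regression: float
    val_classification: float
    learning_rate: float


@dataclass
class TrainingLog:
    records: list[EpochRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _labels(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    logs, bins = [], []
    for s in dataset.samples:
        if s.log_ic50 is None:
            raise DatasetSizeError(
                f"training requires ic50-labelled samples; {s.allele}/{s.peptide} "
                f"has type {s.measurement_type}")
        logs.append(s.log_ic50)
        bins.append(s.binary_label)
    return (np.asarray(logs, dtype=np.float32), np.asarray(bins, dtype=np.float32))


def _epoch_losses(network: Network, peptides, bank, rows, y_log, y_bin,
                  batch_size: int) -> tuple[float, float]:
    """Inference-mode losses over a full dataset (weighted by batch size)."""
    n = len(y_log)
    sum_r = sum_c = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        out = network.forward_batch_grouped(peptides[sl], bank, rows[sl], train=False)
        b = sl.stop - sl.start
        sum_r += mse_loss(out["log_ic50"], y_log[sl]) * b
        sum_c += bce_loss(y_bin[sl], out["prob"]) * b
    return sum_r / n, sum_c / n


def train(network: Network, train_set: Dataset, val_set: Dataset,
          config: TrainingConfig | None = None, seed: int = 0,
          ) -> tuple[Network, TrainingLog]:
    """Train in place; returns the network holding the best-validation
    parameters, plus the per-epoch log.

    Mini-batches are reshuffled each epoch from ``seed``; the whole run is
    deterministic given (network seed, data, seed). With
    ``config.max_epochs == 0`` the network is returned untrained (useful as
    a null baseline).
    """
    from .nn import SGD  # local import to keep module load cheap

    config = config or TrainingConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise DatasetSizeError("training and validation sets must be non-empty")

    p_tr, bank_tr, rows_tr = encode_dataset(train_set)
    p_va, bank_va, rows_va = encode_dataset(val_set)
    ylog_tr, ybin_tr = _labels(train_set)
    ylog_va, ybin_va = _labels(val_set)

    opt = SGD(list(network.iter_layers()), lr=config.learning_rate,
              momentum=config.momentum)
    schedule = LRSchedule(config)
    rng = np.random.default_rng(seed)
    log = TrainingLog()

    best_state = network.state_dict()
    n = len(train_set)

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        sum_r = sum_c = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            out = network.forward_batch_grouped(p_tr[idx], bank_tr, rows_tr[idx], train=True)
            b = len(idx)
            loss_r = mse_loss(out["log_ic50"], ylog_tr[idx])
            loss_c = bce_loss(ybin_tr[idx], out["prob"])
            sum_r += loss_r * b
            sum_c += loss_c * b
            # d(MSE)/d(pred) and d(BCE)/d(logit) for the sigmoid head
            g_log = (2.0 / b) * (out["log_ic50"] - ylog_tr[idx])
            g_logit = (out["prob"] - ybin_tr[idx]) / b
            network.backward_batch_grouped(g_log, g_logit)
            opt.step()

        val_r, val_c = _epoch_losses(network, p_va, bank_va, rows_va,
                                     ylog_va, ybin_va, 512)
        val_total = total_loss(val_r, val_c)
        log.records.append(EpochRecord(
            epoch=epoch,
            train_total=total_loss(sum_r / n, sum_c / n),
            train_regression=sum_r / n,
            train_classification=sum_c / n,
            val_total=val_total,
            val_regression=val_r,
            val_classification=val_c,
            learning_rate=opt.lr,
        ))

        stop = schedule.update(val_total)
        if schedule.improved:
            best_state = network.state_dict()
        opt.lr = schedule.lr
        if stop:
            break

    network.load_state_dict(best_state)
    return network, log
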