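"""Metrics and evaluation protocols.

AUC (Mann–Whitney: probability a random binder outscores a random
non-binder, ties at half credit) and Spearman's rank correlation are the
two reported metrics, computed separately for the affinity output and the
probability output. Protocols: random k-fold cross-validation,
leave-one-allele-out (LOAO) cross-validation for generalization to unseen
alleles, benchmark-table scoring with per-measurement-type rules, and the
dual-output consistency analysis (do the two heads indicate the same
binding state, and how tightly are they correlated?).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data import (
    Dataset,
    IC50_THRESHOLD,
    T_HALF_THRESHOLD,
    train_val_split,
    loao_folds,
)
from .errors import (
    CoverageError,
    DatasetSizeError,
    FoldError,
    UndefinedMetricError,
)
from .network import Network, NetworkConfig, PredictionRow, build_network, predict
from .training import TrainingConfig, train

__all__ = [
    "auc", "srcc", "score_direction", "ConsistencyReport", "consistency_report",
    "EvalReport", "run_cv", "run_loao", "evaluate_benchmark",
]


def auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the Mann–Whitney probability that a random positive outscores a
    random negative, with ties counted 1/2. Raises
    :class:`UndefinedMetricError` when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise UndefinedMetricError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def srcc(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of mean ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise UndefinedMetricError("SRCC needs two equal-length vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("SRCC undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def score_direction(rows: list[PredictionRow]) -> tuple[np.ndarray, np.ndarray]:
    """Orient the two outputs so that higher score = stronger binder.

    The affinity head predicts logIC50, where *lower* means stronger
    binding, so its ranking score is the negated prediction; the
    probability head is used as-is. (AUC is rank-based, so any strictly
    monotone transform of either score leaves it unchanged.)
    """
    affinity = np.array([-r.log_ic50_pred for r in rows])
    prob = np.array([r.binding_prob for r in rows])
    return affinity, prob


def _true_state(sample) -> int:
    """Measured binding state of a sample, per its measurement type."""
    if sample.measurement_type == "ic50":
        return int(sample.measurement_value <= IC50_THRESHOLD)
    if sample.measurement_type == "t_half":
        return int(sample.measurement_value < T_HALF_THRESHOLD)
    return int(sample.binary_label)


@dataclass(frozen=True)
class ConsistencyReport:
    """Agreement between the two heads, and each head's accuracy.

    A prediction pair is *consistent* when the predicted IC50 and the
    predicted probability indicate the same binding state (IC50 <= 500 nM
    vs probability >= 0.5). ``pearson_r`` and the fitted line describe the
    relation between predicted logIC50 (x) and predicted probability (y);
    for a well-trained model the correlation is strongly negative.
    """

    total: int
    consistent: int
    correct_ic50: int
    correct_binary: int
    pearson_r: float
    slope: float
    intercept: float

    @property
    def consistent_fraction(self) -> float:
        return self.consistent / self.total

    @property
    def correct_ic50_fraction(self) -> float:
        return self.correct_ic50 / self.total

    @property
    def correct_binary_fraction(self) -> float:
        return self.correct_binary / self.total


def consistency_report(rows: list[PredictionRow]) -> ConsistencyReport:
    if not rows:
        raise DatasetSizeError("consistency analysis needs at least one prediction")
    consistent = correct_ic50 = correct_binary = 0
    for r in rows:
        state_ic50 = r.ic50_pred <= IC50_THRESHOLD
        state_prob = r.binding_prob >= 0.5
        truth = bool(_true_state(r.sample))
        consistent += state_ic50 == state_prob
        correct_ic50 += state_ic50 == truth
        correct_binary += state_prob == truth
    x = np.array([r.log_ic50_pred for r in rows])
    y = np.array([r.binding_prob for r in rows])
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        pearson_r = float(stats.pearsonr(x, y).statistic)
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    else:
        pearson_r = slope = float("nan")
        intercept = float(np.mean(y))
    return ConsistencyReport(len(rows), consistent, correct_ic50, correct_binary,
                             pearson_r, slope, intercept)


@dataclass
class EvalReport:
    """Per-group metric table: one row per group (all / locus / allele),
    with AUC and SRCC for both the affinity and the probability output."""

    table: pd.DataFrame

    def row(self, group: str) -> pd.Series:
        return self.table.set_index("group").loc[group]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _locus(allele: str) -> str:
    # "HLA-A*02:01" -> "HLA-A"
    return allele.split("*")[0]


def _metric_row(group: str, rows: list[PredictionRow]) -> dict:
    labels = np.array([_true_state(r.sample) for r in rows])
    aff_scores, prob_scores = score_direction(rows)
    true_strength = np.array([
        -np.log(max(r.sample.measurement_value, 1.0))
        if r.sample.measurement_type == "ic50" else float(r.sample.binary_label)
        for r in rows
    ])

    def _safe(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return float("nan")

    return {
        "group": group,
        "n": len(rows),
        "auc_affinity": _safe(auc, aff_scores, labels),
        "srcc_affinity": _safe(srcc, aff_scores, true_strength),
        "auc_prob": _safe(auc, prob_scores, labels),
        "srcc_prob": _safe(srcc, prob_scores, true_strength),
    }


def report_from_predictions(rows: list[PredictionRow]) -> EvalReport:
    """Group pooled predictions into all / per-locus / per-allele rows."""
    if not rows:
        raise DatasetSizeError("no predictions to evaluate")
    records = [_metric_row("all", rows)]
    by_locus: dict[str, list[PredictionRow]] = {}
    by_allele: dict[str, list[PredictionRow]] = {}
    for r in rows:
        by_locus.setdefault(_locus(r.sample.allele), []).append(r)
        by_allele.setdefault(r.sample.allele, []).append(r)
    for locus in sorted(by_locus):
        records.append(_metric_row(locus, by_locus[locus]))
    for allele in sorted(by_allele):
        records.append(_metric_row(allele, by_allele[allele]))
    return EvalReport(pd.DataFrame.from_records(records))


def run_cv(dataset: Dataset, network_config: NetworkConfig,
           training_config: TrainingConfig | None = None, k: int = 5,
           seed: int = 0) -> tuple[EvalReport, list[PredictionRow]]:
    """Random k-fold cross-validation: train on k-1 folds, predict the
    held-out fold, pool all held-out predictions, report per-group metrics.

    Each fold trains a freshly built network (seed offset by the fold
    index) with an internal 4:1 train/validation split for the schedule.
    """
    if k < 2:
        raise FoldError(f"k-fold cross-validation needs k >= 2, got {k}")
    n = len(dataset)
    if n < k:
        raise DatasetSizeError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(k), -(-n // k))[:n]
    rng.shuffle(fold_of)

    pooled: list[PredictionRow] = []
    for fold in range(k):
        test_idx = np.flatnonzero(fold_of == fold)
        train_idx = np.flatnonzero(fold_of != fold)
        net = build_network(replace(network_config, seed=network_config.seed + fold))
        cfg = training_config or TrainingConfig()
        if cfg.max_epochs > 0:
            tr, va = train_val_split(dataset.subset(train_idx), seed=seed + fold)
            net, _ = train(net, tr, va, cfg, seed=seed + fold)
        pooled.extend(predict(net, dataset.subset(test_idx)))
    return report_from_predictions(pooled), pooled


def run_loao(dataset: Dataset, network_config: NetworkConfig,
             training_config: TrainingConfig | None = None,
             alleles: list[str] | None = None, seed: int = 0,
             ) -> tuple[EvalReport, list[PredictionRow]]:
    """Leave-one-allele-out cross-validation.

    For each held-out allele, a fresh network is trained on every other
    allele's samples and scored on the held-out allele, measuring
    generalization to HLA sequences never seen in training. ``alleles``
    restricts which folds are run (all by default).
    """
    folds = loao_folds(dataset)
    if alleles is not None:
        wanted = set(alleles)
        folds = [f for f in folds if f[0] in wanted]
        if not folds:
            raise FoldError("none of the requested alleles are in the dataset")
    pooled: list[PredictionRow] = []
    for i, (allele, train_part, test_part) in enumerate(folds):
        net = build_network(replace(network_config, seed=network_config.seed + i))
        cfg = training_config or TrainingConfig()
        if cfg.max_epochs > 0:
            tr, va = train_val_split(train_part, seed=seed + i)
            net, _ = train(net, tr, va, cfg, seed=seed + i)
        pooled.extend(predict(net, test_part))
    return report_from_predictions(pooled), pooled


def evaluate_benchmark(network: Network, benchmark: Dataset) -> pd.DataFrame:
    """Score a parsed benchmark table, one row per (allele, measurement type).

    Scoring rules by measurement type: ic50 rows get AUC (500 nM
    binarization) and SRCC; binary rows get AUC only; t1/2 rows get AUC
    (120 min binarization) and SRCC against negated minutes so that larger
    = stronger binding matches the affinity orientation. Datasets where a
    metric is undefined (single class, constant values) report NaN and the
    run continues.
    """
    known = [s for s in benchmark.samples if s.allele in benchmark.allele_index]
    if not known:
        raise CoverageError("benchmark shares no alleles with the allele index")
    rows = predict(network, benchmark)
    groups: dict[tuple[str, str], list[PredictionRow]] = {}
    for r in rows:
        groups.setdefault((r.sample.allele, r.sample.measurement_type), []).append(r)

    records = []
    for (allele, mtype), grp in sorted(groups.items()):
        # duplicate peptides within one benchmark dataset are not scored twice
        seen: set[str] = set()
        uniq = []
        for r in grp:
            if r.sample.peptide not in seen:
                seen.add(r.sample.peptide)
                uniq.append(r)
        labels = np.array([_true_state(r.sample) for r in uniq])
        aff_scores, prob_scores = score_direction(uniq)
        rec = {"allele": allele, "measurement_type": mtype, "n": len(uniq),
               "auc_affinity": float("nan"), "srcc_affinity": float("nan"),
               "auc_prob": float("nan"), "srcc_prob": float("nan")}

        def _safe(fn, *args):
            try:
                return fn(*args)
            except UndefinedMetricError:
                return float("nan")

        rec["auc_affinity"] = _safe(auc, aff_scores, labels)
        rec["auc_prob"] = _safe(auc, prob_scores, labels)
        if mtype == "ic50":
            strength = -np.log([max(r.sample.measurement_value, 1.0) for r in uniq])
            rec["srcc_affinity"] = _safe(srcc, aff_scores, strength)
            rec["srcc_prob"] = _safe(srcc, prob_scores, strength)
        elif mtype == "t_half":
            strength = -np.array([r.sample.measurement_value for r in uniq])
            rec["srcc_affinity"] = _safe(srcc, aff_scores, strength)
            rec["srcc_prob"] = _safe(srcc, prob_scores, strength)
        records.append(rec)
    return pd.DataFrame.from_records(records)
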