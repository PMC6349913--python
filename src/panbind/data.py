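"""Affinity-table parsing, label derivation, redundancy filtering and splits.

Measured binding affinities are IC50 values in nM spanning [0, 80000];
training regresses on logIC50 = ln(IC50) to keep the label range numerically
tame, and classifies with the standard 500 nM threshold (IC50 <= 500 nM is a
binder). Dissociation half-life (t1/2) measurements are binarized at 120
minutes. Peptide redundancy is removed by greedy identity clustering at a
configurable threshold (default 0.7), keeping the most-sampled peptide of
each cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import PEPTIDE_LENGTH, is_residue
from .errors import (
    DatasetSizeError,
    DomainError,
    EmptyDatasetError,
    FoldError,
    TableFormatError,
)

__all__ = [
    "BindingSample",
    "Dataset",
    "ParseReport",
    "parse_affinity_table",
    "log_transform_ic50",
    "inverse_transform",
    "binarize_ic50",
    "binarize_t_half",
    "redundancy_filter",
    "train_val_split",
    "loao_folds",
]

#: Upper clamp of the IC50 scale in nM.
IC50_MAX = 80000.0
#: Binder/non-binder threshold in nM.
IC50_THRESHOLD = 500.0
#: t1/2 binding threshold in minutes (strictly below = binder).
T_HALF_THRESHOLD = 120.0

MEASUREMENT_TYPES = ("ic50", "binary", "t_half")
_TYPE_ALIASES = {"ic50": "ic50", "binary": "binary", "t1/2": "t_half", "t_half": "t_half"}

#: Default column names of the tab-separated affinity table.
DEFAULT_COLUMNS = {
    "allele": "allele",
    "peptide": "peptide",
    "measurement_type": "measurement_type",
    "measurement_value": "measurement_value",
}


def log_transform_ic50(ic50: float) -> float:
    """ln(IC50), with IC50 clamped to >= 1 nM so the log stays finite.

    500 nM maps to ln 500 = 6.2146, the class boundary in log space.
    """
    if ic50 < 0:
        raise DomainError(f"IC50 must be non-negative, got {ic50}")
    return math.log(max(float(ic50), 1.0))


def inverse_transform(log_ic50: float) -> float:
    """exp(logIC50) back to nM, clamped to the measured range [0, 80000]."""
    return float(min(math.exp(float(log_ic50)), IC50_MAX))


def binarize_ic50(ic50: float) -> int:
    """1 iff IC50 <= 500 nM (binder), else 0."""
    if ic50 < 0:
        raise DomainError(f"IC50 must be non-negative, got {ic50}")
    return int(ic50 <= IC50_THRESHOLD)


def binarize_t_half(minutes: float) -> int:
    """1 iff dissociation half-life is strictly below 120 minutes."""
    if minutes < 0:
        raise DomainError(f"t1/2 must be non-negative, got {minutes}")
    return int(minutes < T_HALF_THRESHOLD)


@dataclass(frozen=True)
class BindingSample:
    """One peptide–allele measurement with its derived training labels.

    ``log_ic50`` is present only for ic50-type measurements; ``binary_label``
    is derived from the measurement via the 500 nM / 120 min rules (binary
    measurements carry their own 0/1 value).
    """

    allele: str
    peptide: str
    measurement_type: str
    measurement_value: float
    log_ic50: float | None = None
    binary_label: int = 0

    @staticmethod
    def from_measurement(allele: str, peptide: str, mtype: str, value: float) -> "BindingSample":
        mtype = _TYPE_ALIASES[mtype]
        if mtype == "ic50":
            value = min(max(float(value), 0.0), IC50_MAX)
            return BindingSample(allele, peptide, mtype, value,
                                 log_ic50=log_transform_ic50(value),
                                 binary_label=binarize_ic50(value))
        if mtype == "t_half":
            return BindingSample(allele, peptide, mtype, float(value),
                                 binary_label=binarize_t_half(float(value)))
        return BindingSample(allele, peptide, mtype, float(value),
                             binary_label=int(float(value) > 0.5))


@dataclass
class ParseReport:
    """Row-drop accounting produced by :func:`parse_affinity_table`."""

    total_rows: int = 0
    kept: int = 0
    dropped_length: int = 0
    dropped_allele: int = 0
    dropped_value: int = 0
    dropped_duplicate: int = 0

    def to_text(self) -> str:
        lines = [f"rows\t{self.total_rows}", f"kept\t{self.kept}"]
        for k in ("dropped_length", "dropped_allele", "dropped_value", "dropped_duplicate"):
            lines.append(f"{k}\t{getattr(self, k)}")
        return "\n".join(lines) + "\n"


@dataclass
class Dataset:
    """A list of binding samples plus the allele -> aligned-sequence index.

    Invariant: every sample's allele is present in ``allele_index`` and no
    two samples share (allele, peptide, measurement_type).
    """

    samples: list[BindingSample]
    allele_index: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def alleles(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.allele, None)
        return list(seen)

    def subset(self, indices) -> "Dataset":
        return Dataset([self.samples[i] for i in indices], self.allele_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": [s.allele for s in self.samples],
                "peptide": [s.peptide for s in self.samples],
                "measurement_type": [s.measurement_type for s in self.samples],
                "measurement_value": [s.measurement_value for s in self.samples],
                "log_ic50": [s.log_ic50 for s in self.samples],
                "binary_label": [s.binary_label for s in self.samples],
            }
        )


def _valid_peptide(p: str) -> bool:
    return len(p) == PEPTIDE_LENGTH and all(is_residue(c) for c in p)


def parse_affinity_table(path, allele_index: dict[str, str],
                         column_map: dict[str, str] | None = None,
                         ) -> tuple[Dataset, ParseReport]:
    """Parse a tab-separated affinity table into a :class:`Dataset`.

    Expected columns (renameable via ``column_map``, e.g. to accept the
    IEDB weekly-benchmark header dialect): allele, peptide,
    measurement_type (ic50 | binary | t1/2), measurement_value. Rows with
    non-9-mer peptides, alleles missing from ``allele_index`` or
    unparseable values are dropped and counted; duplicates on
    (allele, peptide, measurement_type) keep the first occurrence.
    Inequality-qualified values such as ``>20000`` are parsed as their
    numeric bound.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"cannot read affinity table {path}: {exc}") from exc
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise TableFormatError(f"affinity table missing required columns: {missing}")

    report = ParseReport(total_rows=len(df))
    samples: list[BindingSample] = []
    seen: set[tuple[str, str, str]] = set()
    # plain lists: mapped column names need not be python identifiers
    columns = zip(df[cols["allele"]], df[cols["peptide"]],
                  df[cols["measurement_type"]], df[cols["measurement_value"]])
    for allele, peptide, mtype_raw, raw_value in columns:
        allele = str(allele)
        peptide = str(peptide).upper()
        mtype_raw = str(mtype_raw).strip().lower()
        raw_value = str(raw_value).strip()
        if not _valid_peptide(peptide):
            report.dropped_length += 1
            continue
        if allele not in allele_index:
            report.dropped_allele += 1
            continue
        if mtype_raw not in _TYPE_ALIASES:
            report.dropped_value += 1
            continue
        try:
            value = float(raw_value.lstrip("<>="))
        except ValueError:
            report.dropped_value += 1
            continue
        if value < 0:
            report.dropped_value += 1
            continue
        key = (allele, peptide, _TYPE_ALIASES[mtype_raw])
        if key in seen:
            report.dropped_duplicate += 1
            continue
        seen.add(key)
        samples.append(BindingSample.from_measurement(allele, peptide, mtype_raw, value))
    report.kept = len(samples)
    if not samples:
        raise EmptyDatasetError(f"no usable samples parsed from {path}")
    return Dataset(samples, dict(allele_index)), report


def _identity9(a: str, b: str) -> int:
    """Ungapped positional identity count between two 9-mers."""
    return sum(x == y for x, y in zip(a, b))


def redundancy_filter(dataset: Dataset, identity_threshold: float = 0.7) -> Dataset:
    """Greedy peptide-identity clustering; keep each cluster's representative.

    Peptides are visited in descending order of sample count (ties broken
    lexicographically). A peptide joins the first existing cluster whose
    representative shares at least ``ceil(9 * threshold)`` identical
    positions with it, otherwise it founds its own cluster. Only samples of
    cluster representatives survive. Representatives are visited first, so
    the filter is idempotent.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise DomainError(f"identity threshold must lie in (0, 1], got {identity_threshold}")
    min_matches = math.ceil(PEPTIDE_LENGTH * identity_threshold)

    counts: dict[str, int] = {}
    for s in dataset.samples:
        counts[s.peptide] = counts.get(s.peptide, 0) + 1
    order = sorted(counts, key=lambda p: (-counts[p], p))

    representatives: list[str] = []
    kept: set[str] = set()
    for pep in order:
        for rep in representatives:
            if _identity9(pep, rep) >= min_matches:
                break
        else:
            representatives.append(pep)
            kept.add(pep)
    return Dataset([s for s in dataset.samples if s.peptide in kept], dataset.allele_index)


def train_val_split(dataset: Dataset, seed: int) -> tuple[Dataset, Dataset]:
    """Random 4:1 split into training and validation sets.

    Sizes are ceil(0.8 n) and the remainder; deterministic given ``seed``.
    """
    n = len(dataset)
    if n < 5:
        raise DatasetSizeError(f"need at least 5 samples for a 4:1 split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.ceil(0.8 * n)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def loao_folds(dataset: Dataset) -> list[tuple[str, Dataset, Dataset]]:
    """Leave-one-allele-out folds: one (allele, train, test) triple per allele.

    Each fold's test set holds exactly the samples of the held-out allele;
    the train set holds everything else.
    """
    alleles = dataset.alleles
    if len(alleles) < 2:
        raise FoldError("leave-one-allele-out needs at least 2 alleles")
    folds = []
    for allele in alleles:
        test_idx = [i for i, s in enumerate(dataset.samples) if s.allele == allele]
        train_idx = [i for i, s in enumerate(dataset.samples) if s.allele != allele]
        folds.append((allele, dataset.subset(train_idx), dataset.subset(test_idx)))
    return folds
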