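"""Cohort containers and I/O: omics matrices, survival tables, risk labels.

A cohort couples a patients x features matrix (mRNA, RPPA protein,
methylation beta values and/or clinical covariates) with progression-free
survival records.  Risk labels are derived per *time frame* ``(t, t+1)``:
progression at or before ``12*t`` months is high-risk, progression-free
survival at or beyond ``12*(t+1)`` months is low-risk, and everything in
between -- censoring before the low threshold, or an event inside the open
gap -- is indeterminate and excluded from training and evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskLabel",
    "SurvivalRecord",
    "TimeFrame",
    "OmicsMatrix",
    "Cohort",
    "read_cohort",
    "read_survival",
    "assign_risk_labels",
    "split_cohort",
    "equalize_labels",
    "write_labeled_cohort",
]

FEATURE_KINDS = ("mrna", "rppa", "methylation", "clinical")


class RiskLabel(str, Enum):
    """Three-valued risk class; ``indeterminate`` patients are never trained on."""

    HIGH = "high"
    LOW = "low"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's progression-free survival outcome.

    ``event`` is True when progression occurred at ``time_months``; False
    means the patient was censored at that time.
    """

    patient_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError(
                f"negative survival time for patient {self.patient_id!r}: "
                f"{self.time_months}"
            )


@dataclass(frozen=True)
class TimeFrame:
    """The labeling frame ``(t, t+1)`` in years.

    High-risk threshold is ``12*t`` months, low-risk threshold ``12*(t+1)``
    months; events strictly inside the open gap are indeterminate.
    """

    t: int

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"time frame requires t >= 1, got {self.t}")

    @property
    def high_threshold_months(self) -> float:
        return 12.0 * self.t

    @property
    def low_threshold_months(self) -> float:
        return 12.0 * (self.t + 1)

    @classmethod
    def parse(cls, text: str) -> "TimeFrame":
        """Parse ``"3-4"`` / ``"3,4"`` / ``"3"`` into a frame."""
        first = str(text).replace(",", "-").split("-")[0]
        return cls(t=int(first))

    def __str__(self) -> str:
        return f"{self.t}-{self.t + 1}"


@dataclass
class OmicsMatrix:
    """Patients x features value matrix with per-feature data kinds.

    ``values`` is indexed by patient id (rows) and feature id (columns);
    missing measurements are NaN, never zero-filled.
    """

    values: pd.DataFrame
    feature_kinds: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.feature_kinds is None:
            self.feature_kinds = pd.Series("mrna", index=cols)
        else:
            self.feature_kinds = self.feature_kinds.reindex(cols).fillna("mrna")
        unknown = set(self.feature_kinds.unique()) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return len(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values.columns)


@dataclass
class Cohort:
    """An omics matrix plus survival records and (optional) risk labels.

    ``labels`` maps patient id to a :class:`RiskLabel` for exactly one
    :class:`TimeFrame`; patients without an entry are unlabeled.
    """

    matrix: OmicsMatrix
    survival: list[SurvivalRecord] = field(default_factory=list)
    labels: dict[str, RiskLabel] = field(default_factory=dict)
    frame: TimeFrame | None = None

    def __post_init__(self) -> None:
        known = set(self.matrix.patient_ids)
        for rec in self.survival:
            if rec.patient_id not in known:
                raise ValueError(
                    f"survival record for patient {rec.patient_id!r} has no "
                    "row in the matrix"
                )
        for pid in self.labels:
            if pid not in known:
                raise ValueError(f"label for unknown patient {pid!r}")

    @property
    def survival_by_id(self) -> dict[str, SurvivalRecord]:
        return {rec.patient_id: rec for rec in self.survival}

    def labeled_ids(self, classes: Iterable[RiskLabel] = (RiskLabel.HIGH, RiskLabel.LOW)) -> list[str]:
        """Patient ids with a label in ``classes``, in matrix order."""
        wanted = set(classes)
        return [p for p in self.matrix.patient_ids if self.labels.get(p) in wanted]

    def label_counts(self) -> dict[RiskLabel, int]:
        counts = {lab: 0 for lab in RiskLabel}
        for lab in self.labels.values():
            counts[lab] += 1
        return counts

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        """Restrict to ``patient_ids`` (kept in matrix order)."""
        keep = set(patient_ids)
        order = [p for p in self.matrix.patient_ids if p in keep]
        missing = keep - set(order)
        if missing:
            raise KeyError(f"patients not in cohort: {sorted(missing)}")
        mat = OmicsMatrix(
            values=self.matrix.values.loc[order],
            feature_kinds=self.matrix.feature_kinds.copy(),
        )
        surv = [r for r in self.survival if r.patient_id in keep]
        labs = {p: l for p, l in self.labels.items() if p in keep}
        return Cohort(matrix=mat, survival=surv, labels=labs, frame=self.frame)

    def with_labels(self, labels: Mapping[str, RiskLabel], frame: TimeFrame) -> "Cohort":
        return replace(self, labels=dict(labels), frame=frame)


# ---------------------------------------------------------------------------
# I/O


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival table with columns patient_id, pfs_months, pfs_event.

    ``pfs_event`` uses 1 for progression and 0 for censoring.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"patient_id", "pfs_months", "pfs_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in survival table: {dups}")
    return [
        SurvivalRecord(str(r.patient_id), float(r.pfs_months), bool(int(r.pfs_event)))
        for r in df.itertuples(index=False)
    ]


def read_cohort(
    matrix_path: str | Path,
    survival_path: str | Path,
    orientation: str = "patients_in_rows",
    feature_kinds: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a delimited matrix plus survival table into a :class:`Cohort`.

    The matrix is transposed to patients x features when
    ``orientation == "features_in_rows"``.  Missing cells stay missing (NaN).
    """
    if orientation not in {"patients_in_rows", "features_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(matrix_path)
    if orientation == "features_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    kinds = None
    if feature_kinds is not None:
        kinds = pd.Series({str(k): v for k, v in feature_kinds.items()})
    matrix = OmicsMatrix(values=df.astype(float), feature_kinds=kinds)
    survival = read_survival(survival_path)
    return Cohort(matrix=matrix, survival=survival)


def write_labeled_cohort(cohort: Cohort, path: str | Path) -> None:
    """Export (patient_id, time, event, label) as TSV."""
    rows = []
    for rec in cohort.survival:
        lab = cohort.labels.get(rec.patient_id)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "time": rec.time_months,
                "event": int(rec.event),
                "label": lab.value if lab is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labeling and cohort manipulation


def assign_risk_labels(
    survival: Iterable[SurvivalRecord],
    frame: TimeFrame,
    strict_boundaries: bool = False,
    gap_events: str = "indeterminate",
) -> dict[str, RiskLabel]:
    """Map each survival record to high / low / indeterminate for ``frame``.

    High-risk: progression occurred at or before ``12*t`` months.  Low-risk:
    survival (event or censoring) reached ``12*(t+1)`` months.  Everything
    else is indeterminate: censoring before the low threshold without an
    event, or an event inside the open gap.  ``strict_boundaries`` switches
    the threshold comparisons to strict inequalities (tie handling at exact
    month multiples is a convention, not part of the rule).  ``gap_events``
    may be set to ``"high"`` to fold events inside the gap into the
    high-risk class instead of excluding them.
    """
    if gap_events not in {"indeterminate", "high"}:
        raise ValueError(f"gap_events must be 'indeterminate' or 'high', got {gap_events!r}")
    hi, lo = frame.high_threshold_months, frame.low_threshold_months
    out: dict[str, RiskLabel] = {}
    for rec in survival:
        t = rec.time_months
        if t < 0:
            raise ValueError(f"negative time for {rec.patient_id!r}")
        high = (t < hi) if strict_boundaries else (t <= hi)
        low = (t > lo) if strict_boundaries else (t >= lo)
        if rec.event and high:
            out[rec.patient_id] = RiskLabel.HIGH
        elif low:
            out[rec.patient_id] = RiskLabel.LOW
        elif rec.event and gap_events == "high":
            out[rec.patient_id] = RiskLabel.HIGH
        else:
            out[rec.patient_id] = RiskLabel.INDETERMINATE
    return out


def _piece_sizes(n: int) -> tuple[int, int, int]:
    """Split ``n`` into roughly (1/2, 1/4, 1/4) with each piece within 1 of target."""
    n_val = int(round(n * 0.25))
    n_test = int(round(n * 0.25))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_cohort(cohort: Cohort, seed: int) -> tuple[Cohort, Cohort, Cohort]:
    """Random train/validate/test partition (about 1/2, 1/4, 1/4) of the
    labeled patients, stratified by risk label.

    Deterministic given ``seed``.  A class with fewer than 4 members cannot
    populate all three pieces and is placed entirely in the training set
    (with a warning).
    """
    rng = np.random.default_rng(seed)
    strata: dict[RiskLabel, list[str]] = {RiskLabel.HIGH: [], RiskLabel.LOW: []}
    for pid in cohort.matrix.patient_ids:
        lab = cohort.labels.get(pid)
        if lab in strata:
            strata[lab].append(pid)
    total = sum(len(v) for v in strata.values())
    if total < 8:
        raise ValueError(f"need >= 8 labeled patients to split, have {total}")
    train_ids: list[str] = []
    val_ids: list[str] = []
    test_ids: list[str] = []
    for lab in (RiskLabel.HIGH, RiskLabel.LOW):
        ids = sorted(strata[lab])
        rng.shuffle(ids)
        if len(ids) < 4:
            if ids:
                warnings.warn(
                    f"risk class {lab.value!r} has only {len(ids)} members; "
                    "placing them all in the training set"
                )
            train_ids.extend(ids)
            continue
        n_train, n_val, n_test = _piece_sizes(len(ids))
        train_ids.extend(ids[:n_train])
        val_ids.extend(ids[n_train : n_train + n_val])
        test_ids.extend(ids[n_train + n_val :])
    return (
        cohort.subset(train_ids),
        cohort.subset(val_ids),
        cohort.subset(test_ids),
    )


def equalize_labels(cohort: Cohort, max_ratio: float, seed: int) -> Cohort:
    """Subsample the majority class so majority/minority <= ``max_ratio``.

    The minority class is never touched; an already-balanced cohort is
    returned unchanged (same patient set).
    """
    if max_ratio < 1:
        raise ValueError(f"max_ratio must be >= 1, got {max_ratio}")
    high = cohort.labeled_ids([RiskLabel.HIGH])
    low = cohort.labeled_ids([RiskLabel.LOW])
    if not high or not low:
        raise ValueError("equalize_labels requires both risk classes present")
    major, minor = (high, low) if len(high) >= len(low) else (low, high)
    cap = int(max_ratio * len(minor))
    if len(major) <= cap:
        return cohort
    rng = np.random.default_rng(seed)
    kept_major = list(rng.choice(sorted(major), size=cap, replace=False))
    keep = set(kept_major) | set(minor)
    keep |= {p for p, l in cohort.labels.items() if l == RiskLabel.INDETERMINATE}
    return cohort.subset([p for p in cohort.matrix.patient_ids if p in keep])
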