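"""Core domain containers shared across the pipeline.

The pipeline moves four kinds of objects between stages: the probe panel
(which probes are miRNA targets, negative controls, or internal-control
miRNAs), the signal matrix (probes x samples with a detection mask and an
explicit processing stage), the sample sheet (which serum draw belongs to
which patient and time point), and the per-patient clinical table.  The
fitted recurrence-predictive index lives in :class:`DiscriminantModel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "TimePoint",
    "Group",
    "ProbePanel",
    "SampleRecord",
    "SignalMatrix",
    "Stage",
    "DiscriminantModel",
    "ValidationError",
    "FormatError",
    "StageError",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an external file does not match its declared format."""


class StageError(RuntimeError):
    """Raised when an operation is applied at the wrong processing stage."""


class ProbeClass(str, enum.Enum):
    TARGET = "target"
    NEGATIVE_CONTROL = "negative_control"
    INTERNAL_CONTROL = "internal_control"


class TimePoint(str, enum.Enum):
    """Serum sampling time point relative to radical surgery.

    ``FINAL`` is the recurrence draw for relapsers and the last-observation
    draw for patients without recurrence.
    """

    PRE = "pre"
    POST = "post"
    FINAL = "final"


class Group(str, enum.Enum):
    RECURRENCE = "recurrence"
    NONRECURRENCE = "nonrecurrence"


class Stage(str, enum.Enum):
    """Processing stages of a signal matrix, in mandatory forward order."""

    RAW = "raw"
    BACKGROUND_CORRECTED = "background_corrected"
    QUANTILE_NORMALIZED = "quantile_normalized"
    CONTROL_SCALED = "control_scaled"
    LOG2 = "log2"


_STAGE_ORDER = {s: i for i, s in enumerate(Stage)}


@dataclass
class ProbePanel:
    """Annotation of every probe on the array.

    Parameters
    ----------
    table:
        DataFrame with columns ``probe_id``, ``probe_class`` and
        ``mirna_name``; ``mirna_name`` is empty for negative controls.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "probe_class", "mirna_name"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"probe panel missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dupes = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise ValidationError(f"duplicate probe ids: {list(dupes.head())}")
        cls = self.table["probe_class"].map(lambda c: ProbeClass(c))
        self.table = self.table.assign(probe_class=cls).reset_index(drop=True)
        ic = self.table["probe_class"] == ProbeClass.INTERNAL_CONTROL
        if (self.table.loc[ic, "mirna_name"] == "").any():
            raise ValidationError("internal-control probes must carry a miRNA name")

    def ids(self, probe_class: ProbeClass | None = None) -> list[str]:
        if probe_class is None:
            return list(self.table["probe_id"])
        mask = self.table["probe_class"] == probe_class
        return list(self.table.loc[mask, "probe_id"])

    @property
    def target_ids(self) -> list[str]:
        return self.ids(ProbeClass.TARGET)

    @property
    def negative_control_ids(self) -> list[str]:
        return self.ids(ProbeClass.NEGATIVE_CONTROL)

    @property
    def internal_control_ids(self) -> list[str]:
        return self.ids(ProbeClass.INTERNAL_CONTROL)

    @property
    def mirna_ids(self) -> list[str]:
        """Probes that measure a miRNA (targets plus internal controls)."""
        mask = self.table["probe_class"] != ProbeClass.NEGATIVE_CONTROL
        return list(self.table.loc[mask, "probe_id"])

    def name_of(self, probe_id: str) -> str:
        row = self.table.loc[self.table["probe_id"] == probe_id]
        if row.empty:
            raise KeyError(probe_id)
        return str(row["mirna_name"].iloc[0])


@dataclass(frozen=True)
class SampleRecord:
    """One array / serum draw: which patient, which time point."""

    sample_id: str
    patient_id: str
    time_point: TimePoint | None

    @staticmethod
    def validate(records: list["SampleRecord"]) -> None:
        seen: set[tuple[str, TimePoint | None]] = set()
        for r in records:
            key = (r.patient_id, r.time_point)
            if r.time_point is not None and key in seen:
                raise ValidationError(
                    f"duplicate (patient, time point) pair: {key}"
                )
            seen.add(key)


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "time_point": [
                r.time_point.value if r.time_point is not None else ""
                for r in records
            ],
        }
    )


def samples_from_frame(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in frame.iterrows():
        tp = str(row["time_point"])
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                time_point=TimePoint(tp) if tp else None,
            )
        )
    return records


COHORT_COLUMNS = [
    "patient_id",
    "group",
    "rfs_days",
    "rfs_event",
    "os_days",
    "os_event",
    "age",
    "sex",
    "disease_type",
    "stage",
    "differentiation",
    "lymph_metastasis",
    "cea",
    "ca19_9",
]


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the clinical-table invariants.

    Recurrence group membership must coincide with an observed RFS event,
    RFS cannot exceed OS, and all times must be strictly positive.
    """
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if (cohort["rfs_days"] <= 0).any() or (cohort["os_days"] <= 0).any():
        raise ValidationError("survival times must be strictly positive")
    if (cohort["rfs_days"] > cohort["os_days"] + 1e-9).any():
        raise ValidationError("rfs_days must not exceed os_days")
    is_rec = cohort["group"].astype(str) == Group.RECURRENCE.value
    if not (is_rec == cohort["rfs_event"].astype(bool)).all():
        raise ValidationError("group=recurrence must coincide with rfs_event=True")


@dataclass
class SignalMatrix:
    """Probes x samples intensity matrix with a detection mask and a stage.

    ``values`` and ``detected`` share index (probe ids) and columns (sample
    ids).  ``detected`` is all-True at the raw stage; after background
    correction an undetected cell holds the declared floor (0).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not (
            self.values.columns.equals(self.detected.columns)
        ):
            raise ValidationError("values and detected must share index/columns")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("intensities must be nonnegative")
        self.stage = Stage(self.stage)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def require_stage(self, stage: Stage) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage={stage.value!r}, matrix is at "
                f"{self.stage.value!r}"
            )

    def advance(self, values: pd.DataFrame, detected: pd.DataFrame,
                stage: Stage) -> "SignalMatrix":
        if _STAGE_ORDER[stage] <= _STAGE_ORDER[self.stage]:
            raise StageError(
                f"stage may only move forward ({self.stage.value} -> {stage.value})"
            )
        return SignalMatrix(values=values, detected=detected, stage=stage)


@dataclass
class DiscriminantModel:
    """A recurrence-predictive index: score = sum(c_i * x_i) + b.

    A sample is called *recurrence* when its score is greater than or equal
    to the cut-off ``cutoff`` (ties predict recurrence).
    """

    members: list[str]
    coefficients: list[float]
    intercept: float
    cutoff: float
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValidationError("a discriminant model needs at least one member")
        if len(self.members) != len(self.coefficients):
            raise ValidationError("one coefficient per member required")
        vals = list(self.coefficients) + [self.intercept, self.cutoff]
        if not np.all(np.isfinite(vals)):
            raise ValidationError("model parameters must be finite")

    def score(self, x) -> float | np.ndarray:
        """Index score for a member-expression vector (or matrix of rows)."""
        arr = np.asarray(x, dtype=float)
        if arr.shape[-1] != len(self.members):
            raise ValidationError(
                f"expected {len(self.members)} member values, got {arr.shape[-1]}"
            )
        return arr @ np.asarray(self.coefficients) + self.intercept

    def predict(self, x) -> np.ndarray:
        """Predicted group labels: recurrence iff score >= cutoff."""
        s = np.atleast_1d(self.score(x))
        return np.where(
            s >= self.cutoff, Group.RECURRENCE.value, Group.NONRECURRENCE.value
        )
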