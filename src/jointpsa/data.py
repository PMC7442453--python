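"""Domain types and cohort I/O.

A cohort couples two flat tables:

* a long-format table of repeated PSA measurements (one row per visit), and
* a one-row-per-subject table of baseline covariates and the recurrence
  outcome (event or right-censoring time in years since end of radiotherapy).

Raw PSA (ng/ml) is strongly right-skewed, so all modelling happens on a
transformed scale ``psa_star = transform(psa_raw)``.  The transform is
configurable (``log_shift`` — the default ``ln(PSA + 0.1)`` — ``sqrt`` or
``identity``) because different cohorts use different conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOSE_LEVELS",
    "STAGE_LEVELS",
    "GLEASON_LEVELS",
    "TransformSpec",
    "LongitudinalObs",
    "SubjectBaseline",
    "Cohort",
    "CohortValidationError",
    "transform_psa",
    "inverse_transform_psa",
    "read_cohort",
    "write_cohort",
]

#: Radiation-dose bands (Gy); reference level first.
DOSE_LEVELS = ("le50", "51-69", "ge70")
#: Tumour-stage grouping: localized (I-II) vs locally advanced (III-IV).
STAGE_LEVELS = ("1-2", "3-4")
#: Gleason-score bands; reference level first.
GLEASON_LEVELS = ("2-5", "6", "7", "8-10")

LONGITUDINAL_COLUMNS = ["subject_id", "time_years", "psa_ng_ml"]
SURVIVAL_COLUMNS = [
    "subject_id",
    "event_time_years",
    "event",
    "hormone_therapy",
    "dose_group",
    "stage_group",
    "gleason_group",
    "age_years",
]


class CohortValidationError(ValueError):
    """A cohort (or cohort file) violates a structural invariant.

    ``offending`` lists the subject ids (or column names) involved so the
    caller can report or repair the specific rows.
    """

    def __init__(self, message: str, offending: Sequence = ()):  # noqa: D107
        super().__init__(message)
        self.offending = list(offending)


@dataclass(frozen=True)
class TransformSpec:
    """Monotone transform applied to raw PSA before modelling.

    ``log_shift`` maps ``x -> ln(x + shift)``; the 0.1 ng/ml default offset
    keeps post-treatment values near the assay floor finite.
    """

    name: str = "log_shift"
    shift: float = 0.1
    #: plausibility range for raw PSA in ng/ml; values outside are rejected.
    psa_range: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self):
        if self.name not in ("log_shift", "sqrt", "identity"):
            raise ValueError(f"unknown transform {self.name!r}")


def transform_psa(psa_raw, spec: TransformSpec = TransformSpec()):
    """Map raw PSA (ng/ml) to the modelling scale.  Vectorized.

    Raises ``ValueError`` naming the offending value when the input lies
    outside the transform's domain or the plausibility range.
    """
    x = np.asarray(psa_raw, dtype=float)
    lo, hi = spec.psa_range
    bad = (x <= lo) | (x > hi)
    if np.any(bad):
        val = np.atleast_1d(x)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"psa_raw={val:g} outside plausibility range ({lo:g}, {hi:g}] ng/ml"
        )
    if spec.name == "log_shift":
        if np.any(x <= -spec.shift):
            val = np.atleast_1d(x)[np.atleast_1d(x <= -spec.shift)][0]
            raise ValueError(f"psa_raw={val:g} not > {-spec.shift:g} for log_shift")
        out = np.log(x + spec.shift)
    elif spec.name == "sqrt":
        if np.any(x < 0):
            val = np.atleast_1d(x)[np.atleast_1d(x < 0)][0]
            raise ValueError(f"psa_raw={val:g} negative; sqrt undefined")
        out = np.sqrt(x)
    else:  # identity
        out = x.copy()
    return out if out.ndim else float(out)


def inverse_transform_psa(psa_star, spec: TransformSpec = TransformSpec()):
    """Inverse of :func:`transform_psa` (exact to round-off)."""
    y = np.asarray(psa_star, dtype=float)
    if spec.name == "log_shift":
        out = np.exp(y) - spec.shift
    elif spec.name == "sqrt":
        out = y * y
    else:
        out = y.copy()
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LongitudinalObs:
    """One PSA measurement: visit time (years since end of RT) and value."""

    subject_id: str
    time: float
    psa_raw: float
    psa_star: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"observation time {self.time} < 0 for {self.subject_id}")


@dataclass(frozen=True)
class SubjectBaseline:
    """Baseline covariates and survival outcome for one subject.

    ``event`` is 1 for observed recurrence/metastasis, 0 for right-censoring
    at ``event_time`` (years since end of radiotherapy).
    """

    subject_id: str
    hormone_therapy: int
    dose_group: str
    stage_group: str
    gleason_group: str
    age: float
    event_time: float
    event: int

    def __post_init__(self):
        if self.dose_group not in DOSE_LEVELS:
            raise ValueError(f"dose_group {self.dose_group!r} not in {DOSE_LEVELS}")
        if self.stage_group not in STAGE_LEVELS:
            raise ValueError(f"stage_group {self.stage_group!r} not in {STAGE_LEVELS}")
        if self.gleason_group not in GLEASON_LEVELS:
            raise ValueError(
                f"gleason_group {self.gleason_group!r} not in {GLEASON_LEVELS}"
            )
        if self.hormone_therapy not in (0, 1):
            raise ValueError("hormone_therapy must be 0/1")
        if self.event not in (0, 1):
            raise ValueError("event must be 0/1")
        if not self.event_time > 0:
            raise ValueError(f"event_time {self.event_time} must be > 0")


@dataclass
class Cohort:
    """Validated container pairing subjects with their PSA series."""

    subjects: list[SubjectBaseline]
    observations: list[LongitudinalObs]
    transform: TransformSpec = field(default_factory=TransformSpec)

    def __post_init__(self):
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def subject(self, subject_id: str) -> SubjectBaseline:
        return self._by_id[subject_id]

    def observations_for(self, subject_id: str) -> list[LongitudinalObs]:
        return [o for o in self.observations if o.subject_id == subject_id]

    def validate(self) -> None:
        """Check the cross-table invariants; raise on the first violation."""
        if not self.subjects or not self.observations:
            raise CohortValidationError("cohort must contain subjects and observations")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}", dup)
        self._by_id = {s.subject_id: s for s in self.subjects}
        orphans = sorted({o.subject_id for o in self.observations} - set(ids))
        if orphans:
            raise CohortValidationError(
                f"observations reference unknown subjects: {orphans}", orphans
            )
        seen = {o.subject_id for o in self.observations}
        empty = sorted(set(ids) - seen)
        if empty:
            raise CohortValidationError(f"subjects with no observations: {empty}", empty)
        late = sorted(
            {
                o.subject_id
                for o in self.observations
                if o.time > self._by_id[o.subject_id].event_time + 1e-12
            }
        )
        if late:
            raise CohortValidationError(
                f"observations after event/censor time for subjects: {late}", late
            )

    # -- frame views ---------------------------------------------------
    def longitudinal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [o.subject_id for o in self.observations],
                "time_years": [o.time for o in self.observations],
                "psa_ng_ml": [o.psa_raw for o in self.observations],
            }
        )

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "event_time_years": [s.event_time for s in self.subjects],
                "event": [s.event for s in self.subjects],
                "hormone_therapy": [s.hormone_therapy for s in self.subjects],
                "dose_group": [s.dose_group for s in self.subjects],
                "stage_group": [s.stage_group for s in self.subjects],
                "gleason_group": [s.gleason_group for s in self.subjects],
                "age_years": [s.age for s in self.subjects],
            }
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}", missing)


def read_cohort(
    longitudinal_path,
    survival_path,
    spec: TransformSpec = TransformSpec(),
) -> Cohort:
    """Read and validate the two cohort CSVs.

    The transform is applied to every raw PSA value on ingest; all
    structural invariants (known category levels, no orphan observations,
    no visits after the event time, no missing values) are enforced and
    reported with the offending subject ids.
    """
    long_df = pd.read_csv(longitudinal_path, float_precision="round_trip")
    surv_df = pd.read_csv(survival_path, float_precision="round_trip")
    _require_columns(long_df, LONGITUDINAL_COLUMNS, longitudinal_path)
    _require_columns(surv_df, SURVIVAL_COLUMNS, survival_path)
    for df, path in ((long_df, longitudinal_path), (surv_df, survival_path)):
        if df.isna().any().any():
            cols = list(df.columns[df.isna().any()])
            raise CohortValidationError(f"{path}: missing values in {cols}", cols)

    subjects = []
    for row in surv_df.itertuples(index=False):
        subjects.append(
            SubjectBaseline(
                subject_id=str(row.subject_id),
                hormone_therapy=int(row.hormone_therapy),
                dose_group=str(row.dose_group),
                stage_group=str(row.stage_group),
                gleason_group=str(row.gleason_group),
                age=float(row.age_years),
                event_time=float(row.event_time_years),
                event=int(row.event),
            )
        )
    psa_star = transform_psa(long_df["psa_ng_ml"].to_numpy(float), spec)
    observations = [
        LongitudinalObs(
            subject_id=str(sid), time=float(t), psa_raw=float(raw), psa_star=float(star)
        )
        for sid, t, raw, star in zip(
            long_df["subject_id"], long_df["time_years"], long_df["psa_ng_ml"], psa_star
        )
    ]
    return Cohort(subjects=subjects, observations=observations, transform=spec)


def write_cohort(cohort: Cohort, out_dir) -> tuple[Path, Path]:
    """Write ``longitudinal.csv`` and ``survival.csv`` under ``out_dir``.

    Floats are written with 17 significant digits so that
    ``read_cohort(write_cohort(c))`` round-trips to <= 1e-12 relative.
    """
    cohort.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_path = out / "longitudinal.csv"
    surv_path = out / "survival.csv"
    cohort.longitudinal_frame().to_csv(long_path, index=False, float_format="%.17g")
    cohort.survival_frame().to_csv(surv_path, index=False, float_format="%.17g")
    return long_path, surv_path
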