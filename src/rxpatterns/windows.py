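"""Pre-diagnosis period windowing and patient x medication indicator matrices.

All time windows are measured backwards from each patient's diagnosis date
in exact year fractions (365.25-day years) and are half-open
``[lower, upper)`` so the four default 5-year windows partition the 20-year
observation span with no gap or overlap at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import YEAR_DAYS, EmptyMatrixError, InvalidSpecError


@dataclass(frozen=True)
class PeriodWindow:
    """One window of ``[lower_years, upper_years)`` years before diagnosis."""

    index: int
    lower_years: float
    upper_years: float

    def __post_init__(self):
        if not (0 <= self.lower_years < self.upper_years):
            raise InvalidSpecError(
                f"window {self.index}: require 0 <= lower < upper, "
                f"got [{self.lower_years}, {self.upper_years})"
            )

    def contains(self, years_before: float) -> bool:
        return self.lower_years <= years_before < self.upper_years


#: The study design: four contiguous 5-year windows over the 20 years before diagnosis.
DEFAULT_WINDOWS: tuple[PeriodWindow, ...] = (
    PeriodWindow(1, 0.0, 5.0),
    PeriodWindow(2, 5.0, 10.0),
    PeriodWindow(3, 10.0, 15.0),
    PeriodWindow(4, 15.0, 20.0),
)


def windows_from_pairs(pairs) -> tuple[PeriodWindow, ...]:
    """Build ordered, contiguity-checked windows from (lower, upper) pairs."""
    wins = tuple(PeriodWindow(i + 1, float(lo), float(hi)) for i, (lo, hi) in enumerate(pairs))
    for a, b in zip(wins, wins[1:]):
        if not np.isclose(a.upper_years, b.lower_years):
            raise InvalidSpecError("windows must be ordered and contiguous")
    return wins


@dataclass
class PeriodMatrix:
    """Patients x medication-codes matrix for one window.

    Row/column identity is preserved: ``patient_ids[i]`` owns row i and
    ``medication_codes[j]`` owns column j.  Patients with no in-window
    medication event are excluded from the rows but the period cohort size
    (= number of rows in binary mode) is kept for prevalence denominators.
    """

    window: PeriodWindow
    patient_ids: list = field(default_factory=list)
    medication_codes: list = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    coding: str = "binary"

    @property
    def cohort_size(self) -> int:
        return len(self.patient_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.medication_codes)


def years_before(event_date, diagnosis_date) -> float:
    """Exact year fraction between an event and the diagnosis date."""
    return (pd.Timestamp(diagnosis_date) - pd.Timestamp(event_date)).days / YEAR_DAYS


def assign_period(event_date, diagnosis_date, windows=DEFAULT_WINDOWS) -> int | None:
    """Map one event to its period index, or None if outside every window.

    Events after the diagnosis date (negative offset) fall outside all
    windows and return None; callers count them as discarded rather than
    raising.
    """
    try:
        delta = years_before(event_date, diagnosis_date)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed date pair ({event_date!r}, {diagnosis_date!r})") from exc
    for w in windows:
        if w.contains(delta):
            return w.index
    return None


def assign_periods(
    events: pd.DataFrame, patients: pd.DataFrame, windows=DEFAULT_WINDOWS
) -> tuple[pd.DataFrame, int]:
    """Vectorised period assignment for a long event table.

    Returns the events restricted to the observation span with a ``period``
    column, plus the count of events discarded for falling after the
    diagnosis date.
    """
    merged = events.merge(
        patients[["patient_id", "diagnosis_date"]], on="patient_id", how="left", validate="m:1"
    )
    if merged["diagnosis_date"].isna().any():
        bad = merged.loc[merged["diagnosis_date"].isna(), "patient_id"].iloc[0]
        raise ValueError(f"event for unknown patient {bad!r}")
    delta = (
        pd.to_datetime(merged["diagnosis_date"]) - pd.to_datetime(merged["event_date"])
    ).dt.days / YEAR_DAYS
    n_after = int((delta < 0).sum())
    period = pd.Series(pd.NA, index=merged.index, dtype="Int64")
    for w in windows:
        period[(delta >= w.lower_years) & (delta < w.upper_years)] = w.index
    out = merged.drop(columns="diagnosis_date").assign(period=period)
    return out[out["period"].notna()].copy(), n_after


def build_matrix(
    med_events: pd.DataFrame,
    patients: pd.DataFrame,
    window: PeriodWindow,
    coding: str = "binary",
) -> PeriodMatrix:
    """Build the in-window patient x medication matrix.

    Binary mode records presence (>=1 event of the code in the window);
    count mode records event counts.  Column order is lexicographic and
    row order follows sorted patient ids, so the construction is
    deterministic for a given event table.
    """
    if coding not in ("binary", "count"):
        raise InvalidSpecError(f"unknown coding {coding!r}")
    merged = med_events.merge(
        patients[["patient_id", "diagnosis_date"]], on="patient_id", how="inner", validate="m:1"
    )
    delta = (
        pd.to_datetime(merged["diagnosis_date"]) - pd.to_datetime(merged["event_date"])
    ).dt.days / YEAR_DAYS
    inwin = merged[(delta >= window.lower_years) & (delta < window.upper_years)]
    if inwin.empty:
        raise EmptyMatrixError(
            f"no medication events fall in period {window.index} "
            f"[{window.lower_years}, {window.upper_years}); widen the window or check inputs"
        )
    table = pd.crosstab(inwin["patient_id"], inwin["medication_code"])
    table = table.sort_index(axis=0).sort_index(axis=1)
    values = table.to_numpy()
    if coding == "binary":
        values = (values > 0).astype(np.int8)
    return PeriodMatrix(
        window=window,
        patient_ids=list(table.index),
        medication_codes=list(table.columns),
        values=values,
        coding=coding,
    )


def polypharmacy_flags(
    matrix: PeriodMatrix, min_meds: int = 3, denominator: int | None = None
) -> tuple[pd.Series, float]:
    """Flag patients on >= min_meds distinct medications; return prevalence %.

    The denominator defaults to the period cohort (rows of the matrix); pass
    the full study cohort size to express prevalence over all patients.
    """
    if min_meds < 1:
        raise InvalidSpecError(f"min_meds must be >= 1, got {min_meds}")
    distinct = (matrix.values > 0).sum(axis=1)
    flags = pd.Series(distinct >= min_meds, index=matrix.patient_ids)
    denom = matrix.cohort_size if denominator is None else int(denominator)
    if denom <= 0:
        raise InvalidSpecError("denominator must be positive")
    return flags, 100.0 * int(flags.sum()) / denom


def apply_min_support_filter(
    matrix: PeriodMatrix, min_patients: int
) -> tuple[PeriodMatrix, list]:
    """Drop medication columns prescribed to fewer than min_patients patients.

    Returns the reduced matrix and the list of dropped codes (for the run
    log).  Rows are kept even if they become all-zero, so membership
    denominators are unaffected.
    """
    support = (matrix.values > 0).sum(axis=0)
    keep = support >= min_patients
    if not keep.any():
        raise EmptyMatrixError(
            f"min_patients={min_patients} removes every medication column; lower the threshold"
        )
    dropped = [c for c, k in zip(matrix.medication_codes, keep) if not k]
    reduced = PeriodMatrix(
        window=matrix.window,
        patient_ids=list(matrix.patient_ids),
        medication_codes=[c for c, k in zip(matrix.medication_codes, keep) if k],
        values=matrix.values[:, keep],
        coding=matrix.coding,
    )
    return reduced, dropped


def truncate_codes(med_events: pd.DataFrame, prefix_length: int | None) -> pd.DataFrame:
    """Optionally coarsen medication codes to a fixed-length prefix."""
    if prefix_length is None:
        return med_events
    out = med_events.copy()
    out["medication_code"] = out["medication_code"].str[: int(prefix_length)]
    return out
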