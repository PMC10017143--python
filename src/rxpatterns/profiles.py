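"""Descriptive surfaces for identified clusters: disease prevalence,
demographic composition, and yearly visit-count series.

These reproduce the standard reporting tables of a cluster study: merge
cluster memberships with the diagnosis table on the patient identifier,
rank diagnosis codes within each cluster, stratify members by gender and
age band at diagnosis, and aggregate event counts by whole years before
the index date.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assignment import ClusterAssignment
from .utils import YEAR_DAYS, round_half_up
from .windows import PeriodWindow

#: Closed age bands at diagnosis; the open-ended last band catches the oldest old.
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = ((0, 65), (65, 75), (75, 86), (86, np.inf))


def link_diagnoses(
    assignment: ClusterAssignment,
    dx_events: pd.DataFrame,
    patients: pd.DataFrame,
    window: PeriodWindow,
) -> pd.DataFrame:
    """Presence-coded (factor, patient, diagnosis_code) rows for in-window
    diagnoses of cluster members."""
    merged = dx_events.merge(
        patients[["patient_id", "diagnosis_date"]], on="patient_id", how="inner", validate="m:1"
    )
    delta = (
        pd.to_datetime(merged["diagnosis_date"]) - pd.to_datetime(merged["event_date"])
    ).dt.days / YEAR_DAYS
    inwin = merged[(delta >= window.lower_years) & (delta < window.upper_years)]
    pairs = inwin[["patient_id", "diagnosis_code"]].drop_duplicates()
    frames = []
    for f, members in sorted(assignment.members.items()):
        sub = pairs[pairs["patient_id"].isin(members)]
        frames.append(sub.assign(factor=f))
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["patient_id", "diagnosis_code", "factor"])
    )
    return out[["factor", "patient_id", "diagnosis_code"]].sort_values(
        ["factor", "patient_id", "diagnosis_code"]
    ).reset_index(drop=True)


def disease_prevalence(
    linked: pd.DataFrame,
    cluster_sizes: dict[int, int],
    top_k: int = 8,
    decimals: int = 2,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Top-k diagnosis codes per cluster with member counts and percentages."""
    rows = []
    for f in sorted(cluster_sizes):
        size = cluster_sizes[f]
        if size == 0:
            warnings.warn(f"factor {f} has no members; skipped", stacklevel=2)
            continue
        counts = (
            linked[linked["factor"] == f]
            .groupby("diagnosis_code")["patient_id"]
            .nunique()
            .sort_values(ascending=False, kind="stable")
        )
        for code, n in counts.head(top_k).items():
            rows.append(
                {
                    "factor": f,
                    "diagnosis_code": code,
                    "diagnosis_label": (labels or {}).get(code, ""),
                    "n_members_with_code": int(n),
                    "cluster_size": size,
                    "prevalence_pct": round_half_up(100.0 * n / size, decimals),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "factor", "diagnosis_code", "diagnosis_label",
            "n_members_with_code", "cluster_size", "prevalence_pct",
        ],
    )


def completed_years(dob, reference) -> np.ndarray:
    """Age in completed years at a reference date (calendar-exact)."""
    dob = pd.to_datetime(pd.Series(dob)).dt.tz_localize(None)
    ref = pd.to_datetime(pd.Series(reference)).dt.tz_localize(None)
    years = ref.dt.year - dob.dt.year
    before_birthday = (ref.dt.month < dob.dt.month) | (
        (ref.dt.month == dob.dt.month) & (ref.dt.day < dob.dt.day)
    )
    return (years - before_birthday.astype(int)).to_numpy()


def demographic_composition(
    assignment: ClusterAssignment,
    patients: pd.DataFrame,
    age_bands: tuple = DEFAULT_AGE_BANDS,
    reference: str = "diagnosis_date",
    decimals: int = 2,
) -> pd.DataFrame:
    """Gender and age-band composition of each cluster (percent of cluster)."""
    required = {"gender", "date_of_birth", reference}
    missing_cols = required - set(patients.columns)
    if missing_cols:
        raise ValueError(f"patients table lacks columns {sorted(missing_cols)}")
    pat = patients.set_index("patient_id")
    if pat[["gender", "date_of_birth", reference]].isna().any().any():
        bad = pat.index[pat[["gender", "date_of_birth", reference]].isna().any(axis=1)][0]
        raise ValueError(f"patient {bad!r} is missing a demographic field")
    rows = []
    for f, members in sorted(assignment.members.items()):
        if not members:
            continue
        sub = pat.loc[sorted(members)]
        size = len(sub)
        for g, n in sub["gender"].value_counts().sort_index().items():
            rows.append(
                {
                    "factor": f, "stratum_type": "gender", "stratum": g,
                    "count": int(n), "pct_of_cluster": round_half_up(100.0 * n / size, decimals),
                }
            )
        age = completed_years(sub["date_of_birth"], sub[reference])
        for lo, hi in age_bands:
            n = int(((age >= lo) & (age < hi)).sum())
            label = f"{int(lo)}-{int(hi)}" if np.isfinite(hi) else f"{int(lo)}+"
            rows.append(
                {
                    "factor": f, "stratum_type": "age_band", "stratum": label,
                    "count": n, "pct_of_cluster": round_half_up(100.0 * n / size, decimals),
                }
            )
    return pd.DataFrame(rows, columns=["factor", "stratum_type", "stratum", "count", "pct_of_cluster"])


def yearly_visit_counts(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    category_map: dict[str, str],
    code_column: str,
    max_years: float = 20.0,
) -> pd.DataFrame:
    """Event counts per (whole years before diagnosis, category), tidy form.

    Codes absent from the category map are bucketed as "other" with a
    warning; a "total" category row is emitted per year offset.
    """
    merged = events.merge(
        patients[["patient_id", "diagnosis_date"]], on="patient_id", how="inner", validate="m:1"
    )
    delta = (
        pd.to_datetime(merged["diagnosis_date"]) - pd.to_datetime(merged["event_date"])
    ).dt.days / YEAR_DAYS
    merged = merged[(delta >= 0) & (delta < max_years)].copy()
    if merged.empty:
        return pd.DataFrame(columns=["years_before", "category", "n_events"])
    merged["years_before"] = np.floor(delta[merged.index]).astype(int)
    unmapped = sorted(set(merged[code_column]) - set(category_map))
    if unmapped:
        warnings.warn(f"codes {unmapped[:10]} not in category_map; bucketed as 'other'", stacklevel=2)
    merged["category"] = merged[code_column].map(category_map).fillna("other")
    counts = (
        merged.groupby(["years_before", "category"], as_index=False)
        .size()
        .rename(columns={"size": "n_events"})
    )
    totals = (
        merged.groupby("years_before", as_index=False)
        .size()
        .rename(columns={"size": "n_events"})
        .assign(category="total")
    )
    out = pd.concat([counts, totals[["years_before", "category", "n_events"]]], ignore_index=True)
    return out.sort_values(["years_before", "category"]).reset_index(drop=True)
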