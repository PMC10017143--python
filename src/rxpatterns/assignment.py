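"""From fitted factors to polypharmacy clusters.

A factor's medication set is its salient items (|loading| strictly over the
threshold, default 0.30).  A patient belongs to the cluster if at least
``min_drugs`` (default 3) distinct salient medications were prescribed to
them in the window — so clusters may overlap and need not exhaust the
cohort, matching how published cluster percentages fail to sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factor import FactorModel
from .utils import InvalidSpecError, VocabularyMismatchError, round_half_up
from .windows import PeriodMatrix


@dataclass
class SalientSet:
    factor_index: int
    medication_codes: list  # sorted by descending |loading|
    loadings: list
    threshold: float = 0.30


@dataclass
class ClusterAssignment:
    period_index: int
    members: dict[int, set]  # factor index -> patient-id set
    min_drugs: int
    cohort_size: int
    salient_sets: list[SalientSet] = field(default_factory=list)

    def sizes(self) -> dict[int, int]:
        return {f: len(m) for f, m in self.members.items()}


def salient_items(model: FactorModel, threshold: float = 0.30) -> list[SalientSet]:
    """Per-factor medication sets with |loading| strictly above the threshold."""
    if threshold < 0:
        raise InvalidSpecError(f"salience threshold must be >= 0, got {threshold}")
    out = []
    for k in range(model.n_factors):
        lam = model.loadings[:, k]
        idx = np.where(np.abs(lam) > threshold)[0]
        idx = idx[np.argsort(-np.abs(lam[idx]), kind="stable")]
        out.append(
            SalientSet(
                factor_index=k + 1,
                medication_codes=[model.columns[j] for j in idx],
                loadings=[float(lam[j]) for j in idx],
                threshold=threshold,
            )
        )
    if all(len(s.medication_codes) == 0 for s in out):
        warnings.warn(
            f"no loading exceeds {threshold}; all salient sets are empty", stacklevel=2
        )
    return out


def assign_members(
    matrix: PeriodMatrix, sets: list[SalientSet], min_drugs: int = 3
) -> ClusterAssignment:
    """Rule-based cluster membership from a period matrix and salient sets."""
    if min_drugs < 1:
        raise InvalidSpecError(f"min_drugs must be >= 1, got {min_drugs}")
    col_of = {c: j for j, c in enumerate(matrix.medication_codes)}
    present = matrix.values > 0
    ids = np.asarray(matrix.patient_ids, dtype=object)
    members: dict[int, set] = {}
    for s in sets:
        unknown = [c for c in s.medication_codes if c not in col_of]
        if unknown:
            raise VocabularyMismatchError(
                f"factor {s.factor_index}: codes {unknown} not in matrix vocabulary"
            )
        if s.medication_codes:
            cols = [col_of[c] for c in s.medication_codes]
            hits = present[:, cols].sum(axis=1)
            members[s.factor_index] = set(ids[hits >= min_drugs])
        else:
            members[s.factor_index] = set()
    return ClusterAssignment(
        period_index=matrix.window.index,
        members=members,
        min_drugs=min_drugs,
        cohort_size=matrix.cohort_size,
        salient_sets=list(sets),
    )


def cluster_prevalence(
    assignment: ClusterAssignment, denominator: int | None = None, decimals: int = 2
) -> pd.DataFrame:
    """Per-factor member counts and prevalence percentages (half-up rounded).

    The denominator defaults to the period cohort size, which is how the
    printed count/percentage pairs are constructed; pass another count (e.g.
    the full study cohort) to change the base.
    """
    denom = assignment.cohort_size if denominator is None else int(denominator)
    if denom <= 0:
        raise InvalidSpecError(f"denominator must be positive, got {denom}")
    rows = [
        {
            "period": assignment.period_index,
            "factor": f,
            "n_members": len(m),
            "denominator": denom,
            "prevalence_pct": round_half_up(100.0 * len(m) / denom, decimals),
        }
        for f, m in sorted(assignment.members.items())
    ]
    return pd.DataFrame(rows)
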