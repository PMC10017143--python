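"""Horn's parallel analysis for choosing the number of factors.

Reference eigenvalues come from column-wise permutation of the observed
matrix (which preserves each medication's marginal prevalence — important
for sparse binary indicators, where Gaussian reference data would misstate
the null eigenvalue spectrum).  The suggested factor count is the number of
leading observed eigenvalues exceeding their reference percentile, counted
from the first index and stopping at the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import InvalidSpecError, child_rng
from .windows import PeriodMatrix


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_factors_suggested: int
    n_sims: int
    percentile: float
    seed: int


def _corr_eigenvalues(values: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(values, rowvar=False)
    return np.sort(np.linalg.eigvalsh(corr))[::-1]


def parallel_analysis(
    matrix: PeriodMatrix | np.ndarray,
    n_sims: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> ParallelAnalysisResult:
    if n_sims < 1:
        raise InvalidSpecError(f"n_sims must be >= 1, got {n_sims}")
    values = matrix.values if isinstance(matrix, PeriodMatrix) else np.asarray(matrix)
    values = np.asarray(values, dtype=float)
    if np.any(values.std(axis=0) == 0):
        raise InvalidSpecError("zero-variance column; filter before parallel analysis")
    observed = _corr_eigenvalues(values)
    rng = child_rng(seed, 97)
    sims = np.empty((n_sims, values.shape[1]))
    for s in range(n_sims):
        sims[s] = _corr_eigenvalues(rng.permuted(values, axis=0))
    reference = np.percentile(sims, percentile, axis=0)
    above = observed > reference
    n_suggested = int(np.argmin(above)) if not above.all() else len(above)
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        reference_eigenvalues=reference,
        n_factors_suggested=n_suggested,
        n_sims=n_sims,
        percentile=percentile,
        seed=seed,
    )
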