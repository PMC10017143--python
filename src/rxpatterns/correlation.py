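"""Correlation estimation for binary prescription indicators.

Pearson (phi) correlation is the default input to factor extraction;
tetrachoric correlation — the ML correlation of a latent bivariate normal
inferred from each pair's 2x2 table — is available as the model-consistent
alternative for threshold-generated binary data.  Non-positive-semidefinite
estimates (common for pairwise tetrachorics) are repaired by eigenvalue
clipping and rescaling to unit diagonal, and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .utils import InvalidSpecError
from .windows import PeriodMatrix


@dataclass
class CorrelationModel:
    matrix: np.ndarray
    method: str
    n_obs: int
    columns: list
    smoothing_applied: bool = False

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def _check_input(values: np.ndarray, columns) -> None:
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InvalidSpecError("need >= 2 patients and >= 2 medications")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(columns, sd) if s == 0]
        raise InvalidSpecError(
            f"zero-variance column(s) {bad}; apply a minimum-support filter first"
        )


def smooth_psd(matrix: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((matrix + matrix.T) / 2.0)
    if vals.min() >= min_eig:
        return matrix, False
    fixed = (vecs * np.clip(vals, min_eig, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def tetrachoric_pair(a: float, b: float, c: float, d: float) -> float:
    """ML tetrachoric correlation from 2x2 counts.

    Cell layout: a = n(x=0,y=0), b = n(x=0,y=1), c = n(x=1,y=0),
    d = n(x=1,y=1).  Thresholds are fixed at the marginal-implied probit
    quantiles (two-step estimator); empty cells get a 0.5 continuity
    correction.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise InvalidSpecError("2x2 cell counts must be non-negative")
    if np.any(cells == 0):
        cells = cells + 0.5
    n = cells.sum()
    px = (cells[2] + cells[3]) / n  # P(x=1)
    py = (cells[1] + cells[3]) / n  # P(y=1)
    tx, ty = stats.norm.ppf(1 - px), stats.norm.ppf(1 - py)

    def negll(rho: float) -> float:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
        # P(x=1, y=1) = survival beyond both thresholds, via inclusion-exclusion
        p11 = 1 - stats.norm.cdf(tx) - stats.norm.cdf(ty) + bvn.cdf([tx, ty])
        p11 = min(max(p11, 1e-12), 1 - 1e-12)
        p10 = max((1 - stats.norm.cdf(tx)) - p11, 1e-12)
        p01 = max((1 - stats.norm.cdf(ty)) - p11, 1e-12)
        p00 = max(1.0 - p11 - p10 - p01, 1e-12)
        return -(
            cells[0] * np.log(p00)
            + cells[1] * np.log(p01)
            + cells[2] * np.log(p10)
            + cells[3] * np.log(p11)
        )

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def tetrachoric_matrix(values: np.ndarray) -> np.ndarray:
    x = (values > 0).astype(int)
    p = x.shape[1]
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = x[:, i], x[:, j]
            d = int(np.sum(xi & xj))
            c = int(np.sum(xi) - d)
            b = int(np.sum(xj) - d)
            a = x.shape[0] - b - c - d
            out[i, j] = out[j, i] = tetrachoric_pair(a, b, c, d)
    return out


def correlation(matrix: PeriodMatrix | np.ndarray, method: str = "pearson", columns=None) -> CorrelationModel:
    """Estimate the medication-indicator correlation matrix for EFA."""
    if isinstance(matrix, PeriodMatrix):
        values, columns = matrix.values, matrix.medication_codes
    else:
        values = np.asarray(matrix)
        columns = list(columns) if columns is not None else list(range(values.shape[1]))
    values = np.asarray(values, dtype=float)
    _check_input(values, columns)
    if method == "pearson":
        corr = np.corrcoef(values, rowvar=False)
    elif method == "tetrachoric":
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise InvalidSpecError("tetrachoric correlation requires binary input")
        corr = tetrachoric_matrix(values)
    else:
        raise InvalidSpecError(f"unknown correlation method {method!r}")
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr, smoothed = smooth_psd(corr)
    return CorrelationModel(
        matrix=corr,
        method=method,
        n_obs=values.shape[0],
        columns=list(columns),
        smoothing_applied=smoothed,
    )
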