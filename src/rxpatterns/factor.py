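"""Factor extraction, rotation, fit indices and factor scores.

Extraction follows the classical two-stage scheme: the uniquenesses are
optimised numerically and, given uniquenesses, the loadings have a closed
form from an eigendecomposition.  Two discrepancy functions are available:

* ``minres`` (default) minimises the sum of squared off-diagonal residuals
  of R - Lambda Lambda' — robust for non-normal indicator data;
* ``ml`` minimises the Wishart maximum-likelihood discrepancy
  F = ln|Sigma| - ln|R| + tr(R Sigma^-1) - p.

Rotation is gradient-projection (varimax for orthogonal, oblimin gamma=0
for oblique) via statsmodels; factors are then ordered by explained
variance and sign-fixed so each column's largest-|loading| entry is
positive.  The model chi-square uses the Bartlett correction
(n - 1 - (2p+5)/6 - 2F/3) times the ML discrepancy evaluated at the
solution, from which RMSEA and the Tucker-Lewis index follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .correlation import CorrelationModel
from .utils import ConvergenceError, InvalidSpecError
from .windows import PeriodMatrix

_PSI_BOUNDS = (0.005, 1.0)


@dataclass
class FactorModel:
    loadings: np.ndarray               # p x F pattern matrix
    factor_correlations: np.ndarray    # F x F (identity for orthogonal rotations)
    uniquenesses: np.ndarray           # length p
    rotation: str
    method: str
    n_factors: int
    columns: list
    corr: CorrelationModel
    explained_variance: pd.DataFrame = field(default=None, repr=False)
    chi_square: float = np.nan
    dof: int = 0
    f_min: float = np.nan

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    def implied_correlation(self) -> np.ndarray:
        sigma = self.loadings @ self.factor_correlations @ self.loadings.T
        return sigma + np.diag(self.uniquenesses)

    def residuals(self) -> np.ndarray:
        return self.corr.matrix - self.implied_correlation()

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=self.columns,
            columns=[f"F{k + 1}" for k in range(self.n_factors)],
        )


@dataclass
class FitIndices:
    rmsr: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    tli: float
    chi_square: float
    dof: int
    good_fit: bool  # RMSEA <= 0.05 convention

    @property
    def tli_x100(self) -> float:
        return 100.0 * self.tli


def _loadings_given_psi(corr: np.ndarray, psi: np.ndarray, n_factors: int, method: str) -> np.ndarray:
    if method == "minres":
        reduced = corr.copy()
        np.fill_diagonal(reduced, 1.0 - psi)
        vals, vecs = np.linalg.eigh(reduced)
        idx = np.argsort(vals)[::-1][:n_factors]
        return vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    # ML: eigen-structure of the uniqueness-scaled matrix
    s = 1.0 / np.sqrt(psi)
    scaled = corr * np.outer(s, s)
    vals, vecs = np.linalg.eigh(scaled)
    idx = np.argsort(vals)[::-1][:n_factors]
    lam = vecs[:, idx] * np.sqrt(np.clip(vals[idx] - 1.0, 0.0, None))
    return lam / s[:, None]


def _minres_objective(psi: np.ndarray, corr: np.ndarray, n_factors: int) -> float:
    lam = _loadings_given_psi(corr, psi, n_factors, "minres")
    resid = corr - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid**2))


def _ml_objective(psi: np.ndarray, corr: np.ndarray, n_factors: int) -> float:
    # Joreskog's concentrated ML criterion: sum over trailing eigenvalues
    s = 1.0 / np.sqrt(psi)
    scaled = corr * np.outer(s, s)
    vals = np.sort(np.linalg.eigvalsh(scaled))[::-1]
    tail = np.clip(vals[n_factors:], 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def ml_discrepancy(corr: np.ndarray, sigma: np.ndarray) -> float:
    """Wishart ML discrepancy between a sample and model correlation matrix."""
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(corr)
    if sign_s <= 0 or sign_r <= 0:
        return np.nan
    p = corr.shape[0]
    return float(logdet_s - logdet_r + np.trace(corr @ np.linalg.inv(sigma)) - p)


def _order_and_sign(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-(lam**2).sum(axis=0), kind="stable")
    lam, phi = lam[:, order], phi[np.ix_(order, order)]
    flips = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(lam.shape[1])])
    flips[flips == 0] = 1.0
    return lam * flips, phi * np.outer(flips, flips)


def extract(
    corr: CorrelationModel,
    n_factors: int,
    method: str = "minres",
    rotation: str = "oblimin",
    max_iter: int = 1000,
) -> FactorModel:
    """Fit a common-factor model to a correlation matrix.

    Raises ConvergenceError (carrying the last objective value) if the
    uniqueness optimisation does not converge.
    """
    R = corr.matrix
    p = R.shape[0]
    if not 1 <= n_factors <= p // 2:
        raise InvalidSpecError(f"n_factors must lie in [1, p/2], got {n_factors} for p={p}")
    dof = ((p - n_factors) ** 2 - (p + n_factors)) // 2
    ledermann = (2 * p + 1 - np.sqrt(8 * p + 1)) / 2
    if n_factors > ledermann:
        warnings.warn(
            f"n_factors={n_factors} exceeds the Ledermann bound {ledermann:.1f}", stacklevel=2
        )
    if method not in ("minres", "ml"):
        raise InvalidSpecError(f"unknown extraction method {method!r}")
    objective = _minres_objective if method == "minres" else _ml_objective
    # start uniquenesses at 1 - squared multiple correlation
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, *_PSI_BOUNDS)
    res = optimize.minimize(
        objective,
        psi0,
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[_PSI_BOUNDS] * p,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(
            f"{method} uniqueness optimisation failed: {res.message}", last_objective=res.fun
        )
    psi = np.asarray(res.x)
    lam = _loadings_given_psi(R, psi, n_factors, method)

    phi = np.eye(n_factors)
    if n_factors > 1 and rotation != "none":
        if rotation == "varimax":
            lam, _ = rotate_factors(lam, "varimax")
        elif rotation == "oblimin":
            lam, T = rotate_factors(lam, "oblimin", 0.0, "oblique")
            phi = T.T @ T
        else:
            raise InvalidSpecError(f"unknown rotation {rotation!r}")
    lam, phi = _order_and_sign(lam, phi)

    communality = np.diag(lam @ phi @ lam.T)
    uniq = np.clip(1.0 - communality, 0.0, None)
    # explained variance on the total-variance scale (and common-variance share)
    ss = (lam**2).sum(axis=0)
    ss_total = ss.sum() if ss.sum() > 0 else np.nan
    ev = pd.DataFrame(
        {
            "ss_loadings": ss,
            "proportion_total": ss / p,
            "cumulative_total": np.cumsum(ss) / p,
            "proportion_common": ss / ss_total,
            "cumulative_common": np.cumsum(ss) / ss_total,
        },
        index=[f"F{k + 1}" for k in range(n_factors)],
    )
    sigma = lam @ phi @ lam.T + np.diag(uniq)
    f_min = ml_discrepancy(R, sigma)
    n = corr.n_obs
    correction = n - 1 - (2 * p + 5) / 6 - 2 * n_factors / 3
    chi2 = correction * f_min if np.isfinite(f_min) else np.nan
    return FactorModel(
        loadings=lam,
        factor_correlations=phi,
        uniquenesses=uniq,
        rotation=rotation if n_factors > 1 else "none",
        method=method,
        n_factors=n_factors,
        columns=list(corr.columns),
        corr=corr,
        explained_variance=ev,
        chi_square=float(chi2),
        dof=int(dof),
        f_min=f_min,
    )


def _rmsea_ci(chi2: float, dof: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square for the RMSEA confidence interval."""
    alpha = (1.0 - level) / 2.0

    def bound(prob: float) -> float:
        # find noncentrality ncp with P(X2_{dof,ncp} <= chi2) = prob
        if stats.ncx2.cdf(chi2, dof, 0.0) < prob:
            return 0.0
        hi = max(chi2 * 2, 10.0)
        while stats.ncx2.cdf(chi2, dof, hi) > prob:
            hi *= 2
        ncp = optimize.brentq(lambda l: stats.ncx2.cdf(chi2, dof, l) - prob, 0.0, hi)
        return float(np.sqrt(ncp / (dof * (n - 1))))

    return bound(1.0 - alpha), bound(alpha)


def fit_indices(model: FactorModel, corr: CorrelationModel | None = None, n_obs: int | None = None) -> FitIndices:
    """RMSR, RMSEA (with 90% CI) and Tucker-Lewis index for a fitted model."""
    corr = corr or model.corr
    n = n_obs or corr.n_obs
    R = corr.matrix
    p = R.shape[0]
    dof = model.dof
    if dof <= 0:
        raise InvalidSpecError("model has no degrees of freedom (saturated); fewer factors needed")
    resid = model.residuals()
    off = ~np.eye(p, dtype=bool)
    rmsr = float(np.sqrt(np.mean(resid[off] ** 2)))
    chi2 = model.chi_square
    rmsea = float(np.sqrt(max((chi2 - dof) / (dof * (n - 1)), 0.0)))
    ci = _rmsea_ci(chi2, dof, n) if np.isfinite(chi2) else (np.nan, np.nan)
    # independence baseline
    sign, logdet = np.linalg.slogdet(R)
    f0 = -logdet if sign > 0 else np.nan
    chi2_0 = (n - 1 - (2 * p + 5) / 6) * f0
    dof_0 = p * (p - 1) // 2
    denom = chi2_0 / dof_0 - 1.0
    tli = (chi2_0 / dof_0 - chi2 / dof) / denom if denom != 0 else np.nan
    return FitIndices(
        rmsr=rmsr,
        rmsea=rmsea,
        rmsea_ci90=ci,
        tli=float(tli),
        chi_square=float(chi2),
        dof=int(dof),
        good_fit=bool(rmsea <= 0.05),
    )


def factor_scores(
    model: FactorModel, matrix: PeriodMatrix | np.ndarray, method: str = "regression"
) -> np.ndarray:
    """Per-patient factor scores by the regression (Thurstone) method.

    W = R^-1 Lambda Phi applied to column-standardised data; under the
    Gaussian factor model this is the posterior mean of the factors, which
    coincides with the maximum a posteriori estimate.
    """
    if method != "regression":
        raise InvalidSpecError(f"unknown scoring method {method!r}")
    values = matrix.values if isinstance(matrix, PeriodMatrix) else np.asarray(matrix)
    values = np.asarray(values, dtype=float)
    if values.shape[1] != len(model.columns):
        raise InvalidSpecError("matrix columns do not match the fitted medication set")
    mu, sd = values.mean(axis=0), values.std(axis=0)
    if np.any(sd == 0):
        raise InvalidSpecError("zero-variance column in scoring data")
    z = (values - mu) / sd
    R = model.corr.matrix
    target = model.loadings @ model.factor_correlations
    try:
        weights = np.linalg.solve(R, target)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; using ridge-regularised solve", stacklevel=2)
        weights = np.linalg.solve(R + 1e-8 * np.eye(R.shape[0]), target)
    return z @ weights


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-congruence matrix phi(a_i, b_j) between two loading matrices."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    return (a.T @ b) / np.outer(na, nb)


def match_columns(estimated: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy |congruence| matching of estimated factors to target factors;
    returns the permuted, sign-aligned estimate and the per-target congruence."""
    cong = tucker_congruence(target, estimated)
    Ft, Fe = cong.shape
    used, perm, sign = set(), np.zeros(Ft, dtype=int), np.ones(Ft)
    for i in np.argsort(-np.abs(cong).max(axis=1)):
        order = np.argsort(-np.abs(cong[i]))
        j = next(j for j in order if j not in used)
        used.add(j)
        perm[i], sign[i] = j, np.sign(cong[i, j]) or 1.0
    matched = estimated[:, perm] * sign
    return matched, np.abs(cong[np.arange(Ft), perm])
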