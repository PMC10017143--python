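"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the tetrachoric
oracle is a brute-force likelihood grid search, the membership oracle is an
explicit loop over (patient, factor) pairs, and the EFA oracle is R's
stats::factanal run through Rscript.
"""

from __future__ import annotations

import json
import os
import subprocess
import tempfile

import numpy as np
from scipy import stats

_FACTANAL_R = r"""
args <- commandArgs(trailingOnly=TRUE)
R <- as.matrix(read.csv(args[1], header=FALSE))
dimnames(R) <- NULL
f <- factanal(covmat=R, factors=as.integer(args[2]), n.obs=as.integer(args[3]), rotation="none")
out <- list(loadings=unclass(f$loadings), uniquenesses=f$uniquenesses,
            statistic=as.numeric(f$STATISTIC), dof=as.numeric(f$dof))
cat(jsonlite::toJSON(out, digits=12))
"""


def factanal_reference(corr: np.ndarray, n_factors: int, n_obs: int) -> dict:
    """Unrotated ML factor solution from R's factanal (loadings, chi-square, dof)."""
    with tempfile.TemporaryDirectory() as d:
        rpath = os.path.join(d, "R.csv")
        np.savetxt(rpath, corr, delimiter=",")
        script = os.path.join(d, "factanal.R")
        with open(script, "w") as fh:
            fh.write(_FACTANAL_R)
        res = subprocess.run(
            ["Rscript", "--vanilla", script, rpath, str(n_factors), str(n_obs)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = json.loads(res.stdout)
    p = corr.shape[0]
    loadings = np.asarray(out["loadings"], dtype=float).reshape(p, n_factors)
    return {
        "loadings": loadings,
        "uniquenesses": np.asarray(out["uniquenesses"], dtype=float),
        "chi_square": float(np.atleast_1d(out["statistic"])[0]),
        "dof": int(np.atleast_1d(out["dof"])[0]),
    }


def tetrachoric_grid_oracle(a: int, b: int, c: int, d: int, n_grid: int = 1999) -> float:
    """Brute-force ML: evaluate the 2x2 log-likelihood on a dense rho grid."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    n = cells.sum()
    px = (cells[2] + cells[3]) / n
    py = (cells[1] + cells[3]) / n
    tx, ty = stats.norm.ppf(1 - px), stats.norm.ppf(1 - py)
    sx, sy = 1 - stats.norm.cdf(tx), 1 - stats.norm.cdf(ty)
    best_ll, best_rho = -np.inf, 0.0
    for rho in np.linspace(-0.998, 0.998, n_grid):
        bvn = stats.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]])
        p11 = sx + sy - 1 + bvn.cdf([tx, ty])
        p10, p01 = sx - p11, sy - p11
        p00 = 1.0 - p11 - p10 - p01
        ps = np.clip([p00, p01, p10, p11], 1e-12, None)
        ll = float(cells @ np.log(ps))
        if ll > best_ll:
            best_ll, best_rho = ll, rho
    return best_rho


def membership_bruteforce(values: np.ndarray, codes: list, sets: dict, min_drugs: int) -> dict:
    """Explicit per-(patient, factor) membership loop: patient i belongs to
    factor f iff at least min_drugs of f's codes have a positive cell."""
    col = {c: j for j, c in enumerate(codes)}
    out = {}
    for f, med_codes in sets.items():
        members = set()
        for i in range(values.shape[0]):
            hits = sum(1 for c in med_codes if values[i, col[c]] > 0)
            if hits >= min_drugs:
                members.add(i)
        out[f] = members
    return out
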