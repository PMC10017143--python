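"""Small shared helpers: half-up rounding, seeding, error types."""

from __future__ import annotations

import decimal

import numpy as np

YEAR_DAYS = 365.25  # calendar-year length used for all year-fraction arithmetic


class InvalidSpecError(ValueError):
    """A simulation or run specification violates its invariants."""


class EmptyMatrixError(ValueError):
    """An operation produced or received a matrix with no rows or columns."""


class VocabularyMismatchError(KeyError):
    """A medication code is not present in the matrix vocabulary."""


class ConvergenceError(RuntimeError):
    """Iterative fitting failed to converge; carries the last objective value."""

    def __init__(self, message: str, last_objective: float | None = None):
        super().__init__(message)
        self.last_objective = last_objective


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    numpy/python round half-to-even, which disagrees with published
    percentage tables on exact .5 ties (e.g. 69.695 -> 69.70 not 69.69).
    """
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent generator from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return np.random.default_rng(ss)
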