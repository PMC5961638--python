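"""Spline bases for the log excess hazard.

Two families are used.  Time since diagnosis enters through quadratic
B-splines (default interior knots at 1 and 5 years on the analysis window
[0, 10]); these model the log baseline hazard and, with the first column
dropped, the time-dependent coefficient functions.  Covariates (age at
diagnosis, year of diagnosis, deprivation index) enter through quadratic
truncated-power splines with a single knot, giving columns
``[x, x^2, (x - knot)_+^2]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BSplineBasis", "TruncatedQuadraticBasis"]


@dataclass(frozen=True)
class BSplineBasis:
    """Quadratic B-spline basis on a closed interval.

    ``dim = degree + len(interior_knots) + 1``; rows of :meth:`eval` sum to
    one (partition of unity).  Evaluation outside the boundary raises.
    """

    interior_knots: tuple[float, ...] = (1.0, 5.0)
    boundary: tuple[float, float] = (0.0, 10.0)
    degree: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        ks = tuple(float(k) for k in self.interior_knots)
        if not all(a < b for a, b in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ks and not (lo < ks[0] and ks[-1] < hi):
            raise ValueError("interior knots must lie strictly inside the boundary")
        object.__setattr__(self, "interior_knots", ks)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def dim(self) -> int:
        return self.degree + len(self.interior_knots) + 1

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [np.full(self.degree + 1, lo), self.interior_knots, np.full(self.degree + 1, hi)]
        )

    def eval(self, t) -> np.ndarray:
        """Basis matrix of shape (n, dim) by the Cox-de Boor recursion."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.boundary
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(f"time value outside the spline boundary [{lo}, {hi}]")
        t = np.clip(t, lo, hi)
        return BSpline.design_matrix(t, self.knot_vector, self.degree).toarray()

    def td(self, t) -> np.ndarray:
        """Time-dependent-effect basis: the B-spline basis without its first column.

        The first basis function is the only one non-zero at the left
        boundary, so dropping it anchors a time-dependent coefficient
        function at 0 for t = 0 and keeps it identifiable against the
        time-constant main effect.
        """
        return self.eval(t)[:, 1:]


@dataclass(frozen=True)
class TruncatedQuadraticBasis:
    """Quadratic truncated-power basis with one knot: columns [x, x^2, (x-knot)_+^2]."""

    knot: float = 0.0

    def eval(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.column_stack([x, x**2, np.clip(x - self.knot, 0.0, None) ** 2])
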