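"""Shared cubic spline basis on pseudotime-quantile knots.

Every gene and every lineage uses the same K basis functions b_k(t): the
cardinal natural cubic spline basis on K knots placed at quantiles of the
pooled assigned pseudotimes (b_k is the natural cubic spline interpolating
the k-th unit vector at the knots). Consequences used downstream:

* K knots give exactly K basis functions, so each lineage smoother carries
  K coefficients;
* partition of unity holds exactly (the natural spline through all-ones is
  the constant 1), so the basis spans constants and each lineage smoother
  carries its own level without a separate intercept;
* the smoother has continuous first and second derivatives at the knots.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SplineBasis", "place_knots", "build_basis"]


class SplineBasis:
    """Evaluable cardinal natural-cubic basis on a fixed knot vector.

    Parameters
    ----------
    knots : increasing 1-d array of pseudotimes (boundary knots at the pooled
        min/max pseudotime).
    """

    degree = 3

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knot vector must be strictly increasing")
        self.knots = knots
        self._spline = CubicSpline(knots, np.eye(knots.size), axis=0, bc_type="natural")

    @property
    def K(self) -> int:
        return self.knots.size

    @property
    def t_min(self) -> float:
        return float(self.knots[0])

    @property
    def t_max(self) -> float:
        return float(self.knots[-1])

    def design(self, t, clamp: bool = True) -> np.ndarray:
        """Evaluate the K basis functions at pseudotimes ``t`` -> (|t|, K).

        Values outside [min knot, max knot] are clamped to the boundary with
        a warning.
        """
        t = np.asarray(t, dtype=float).ravel()
        if t.size == 0:
            raise ValueError("empty pseudotime vector")
        if clamp:
            if np.any(t < self.t_min) or np.any(t > self.t_max):
                warnings.warn(
                    "pseudotimes outside the training range were clamped to the boundary",
                    stacklevel=2,
                )
            t = np.clip(t, self.t_min, self.t_max)
        B = self._spline(t)
        return np.atleast_2d(B)

    def curvature_penalty(self) -> np.ndarray:
        """K x K curvature matrix O with O_jk = integral of b_j'' b_k'' dt.

        The second derivative of a cubic spline is piecewise linear, so the
        integral over each knot interval is exact. The null space of O holds
        constant and linear functions, so a curvature-penalized fit shrinks
        toward a straight line on the log scale.
        """
        gamma = self._spline.derivative(2)(self.knots)  # (K knots, K basis)
        h = np.diff(self.knots)
        omega = np.zeros((self.K, self.K))
        for j in range(self.K - 1):
            a, b = gamma[j], gamma[j + 1]
            omega += (h[j] / 6.0) * (
                2.0 * np.outer(a, a) + np.outer(a, b) + np.outer(b, a) + 2.0 * np.outer(b, b)
            )
        return (omega + omega.T) / 2.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"SplineBasis(K={self.K}, range=({self.t_min:.3g}, {self.t_max:.3g}))"


def place_knots(pseudotimes, Z, K: int = 6) -> np.ndarray:
    """Place K knots at quantiles of the pooled assigned pseudotimes.

    The pool consists of T[i, l] for every cell i assigned to lineage l
    (Z[i, l] == 1); knots sit at the 0, 1/(K-1), ..., 1 quantiles, so the
    first and last knots equal the pooled min and max (K = 3 gives the
    minimum, median and maximum). Duplicate quantile values are collapsed
    with a warning.
    """
    if K < 3:
        raise ValueError("K must be at least 3")
    T = np.asarray(pseudotimes, dtype=float)
    Z = np.asarray(Z)
    if T.shape != Z.shape:
        raise ValueError("pseudotimes and Z must have the same shape")
    pooled = T[Z.astype(bool)]
    if np.unique(pooled).size < K:
        raise ValueError(
            f"only {np.unique(pooled).size} distinct pseudotime values for {K} knots; "
            "choose a smaller K"
        )
    knots = np.quantile(pooled, np.linspace(0.0, 1.0, K))
    uniq = np.unique(knots)
    if uniq.size < K:
        warnings.warn(
            f"{K - uniq.size} duplicate quantile knot(s) collapsed; "
            f"effective K = {uniq.size}",
            stacklevel=2,
        )
    return uniq


def build_basis(t, basis: SplineBasis) -> np.ndarray:
    """Design matrix (|t| x K) of the basis evaluated at pseudotimes ``t``."""
    return basis.design(t)
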