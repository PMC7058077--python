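"""Observation-level weights for zero-inflated counts.

Full-length single-cell protocols produce excess zeros (dropouts) that a
plain NB model cannot absorb. Each gene is modelled as a two-component
mixture: with probability pi_g the count is a structural zero, otherwise it
is NB with mean mu_gi = exp(b0_g + offset_gi) and gene dispersion phi_g. The
EM posterior probability that an observation comes from the NB component is
the weight handed to the NB-GAM fit; weights are exactly 1 for all nonzero
counts.

The offset can be the usual cell-level size factor (intercept-only mean) or,
better, the fitted log-mean of a first-pass unweighted NB-GAM: with dynamic
genes an intercept-only NB soaks the mean variation into the dispersion and
then explains dropout zeros as NB zeros, underestimating pi. A uniform
dropout rate scales the first-pass mean by roughly (1 - pi) everywhere, so
the free intercept b0_g absorbs that bias while the shape stays informative.
:func:`estimate_zinb_weights` runs this two-pass scheme.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from . import nbglm
from .data import TrajectoryData, compute_offsets

__all__ = ["ZINBWeights", "estimate_zinb_weights"]


class ZINBWeights(BaseEstimator):
    """Gene-wise ZINB EM for observation weights.

    Parameters
    ----------
    max_iter : int, default 50
    tol : float, default 1e-4
        Convergence threshold on the change of pi_g and b0_g.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : (G, n) posterior NB-component probabilities in [0, 1].
    pi_ : (G,) estimated zero-inflation proportions.
    converged_ : (G,) bool; genes whose EM failed fall back to weights 1.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-4):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, counts, offsets=None):
        """Run the EM.

        ``offsets`` may be a length-n vector (cell size factors) or a (G, n)
        matrix of per-observation log-means (e.g. fitted values of a
        first-pass NB-GAM); in both cases the NB mean is
        exp(b0_g + offset_gi) with a free per-gene intercept.
        """
        Y = np.asarray(counts, dtype=float)
        if Y.ndim != 2:
            raise ValueError("counts must be genes x cells")
        G, n = Y.shape
        if offsets is None:
            offsets = compute_offsets(Y)
        offsets = np.asarray(offsets, dtype=float)
        off = offsets if offsets.ndim == 2 else np.broadcast_to(offsets[None, :], (G, n))
        N = np.exp(off - off.max(axis=1, keepdims=True))  # scaled, overflow-safe

        is_zero = Y == 0
        pi = np.clip(0.5 * is_zero.mean(axis=1), 1e-4, 0.95)
        b0 = np.log(
            np.maximum(Y.mean(axis=1), 1e-8) / np.maximum(N.mean(axis=1), 1e-12)
        )
        w = np.ones_like(Y)
        mu = np.clip(np.exp(b0[:, None]) * N, 1e-10, 1e12)
        phi = nbglm.moment_phi(Y, mu)
        converged = np.zeros(G, dtype=bool)

        for _ in range(self.max_iter):
            mu = np.clip(np.exp(b0[:, None]) * N, 1e-10, 1e12)
            r = 1.0 / np.clip(phi, 1e-6, 1e4)[:, None]
            p0 = np.exp(r * np.log(r / (r + mu)))  # NB probability of a zero
            post = ((1.0 - pi)[:, None] * p0) / (
                pi[:, None] + (1.0 - pi)[:, None] * p0
            )
            w = np.where(is_zero, post, 1.0)
            pi_new = np.clip(1.0 - w.mean(axis=1), 0.0, 0.999)
            b0_new = np.log(
                np.maximum((w * Y).sum(axis=1), 1e-12)
                / np.maximum((w * N).sum(axis=1), 1e-12)
            )
            phi = nbglm.update_phi_golden(
                Y, np.clip(np.exp(b0_new[:, None]) * N, 1e-10, 1e12), obs_w=w, iters=25
            )
            delta = np.abs(pi_new - pi) + np.abs(b0_new - b0)
            pi, b0 = pi_new, b0_new
            converged |= delta < self.tol
            if converged.all():
                break

        bad = ~np.isfinite(w).all(axis=1) | ~np.isfinite(pi) | ~converged
        if (~np.isfinite(w).all(axis=1) | ~np.isfinite(pi)).any() or not converged.all():
            n_bad = int(bad.sum())
            if n_bad:
                warnings.warn(
                    f"ZINB EM did not converge for {n_bad} gene(s); falling back "
                    "to unweighted NB for them",
                    stacklevel=2,
                )
            w[bad] = 1.0
            pi[bad] = 0.0
            converged[bad] = False

        self.weights_ = w
        self.pi_ = pi
        self.b0_ = b0
        self.phi_ = phi
        self.converged_ = converged
        return self


def estimate_zinb_weights(
    counts,
    data: TrajectoryData | None = None,
    offsets=None,
    use_fitted_means: bool = True,
    n_knots: int = 6,
    seed: int = 0,
):
    """Observation weights in [0, 1] for a genes x cells count matrix.

    With ``use_fitted_means`` (default) a first-pass unweighted NB-GAM is
    fitted on ``data`` and its fitted log-means serve as the EM offsets, so
    dynamic expression is not mistaken for overdispersion; otherwise (or
    when ``data`` is None) cell-level size-factor offsets are used.
    """
    counts = np.asarray(counts)
    if offsets is None:
        if data is not None and data.offsets is not None:
            offsets = data.offsets
        else:
            offsets = compute_offsets(counts, method="ratio")
    if use_fitted_means and data is not None:
        from .model import NBSplineGAM

        first = NBSplineGAM(n_knots=n_knots, use_obs_weights=False, seed=seed).fit(data)
        eta = first.beta_ @ first.design_.T + np.asarray(offsets)[None, :]
        ok = first.converged_ & np.isfinite(eta).all(axis=1)
        em_off = np.broadcast_to(
            np.asarray(offsets, dtype=float)[None, :], counts.shape
        ).copy()
        em_off[ok] = eta[ok]
        return ZINBWeights().fit(counts, offsets=em_off).weights_
    return ZINBWeights().fit(counts, offsets=offsets).weights_
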