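"""Per-gene negative binomial GAMs along trajectory lineages.

The model for gene g and cell i is

    Y_gi ~ NB(mu_gi, phi_g),   log mu_gi = sum_l s_gl(T_li) Z_li + U_i a_g + offset_i

with each lineage smoother s_gl(t) = sum_k b_k(t) beta_glk on a shared
K-dimensional cubic spline basis. Coefficients are shrunk by a smoothness
penalty lambda_g * beta' S beta on the spline coefficients only, with S the
lineage-block curvature matrix by default (integrated squared second
derivative; a diagonal ridge indicator is available as an option); lambda_g
is selected per gene by generalized cross-validation on a log-spaced grid,
and phi_g by profile likelihood. The coefficient covariance used for Wald tests is the
penalized form (X'WX + lambda S)^{-1}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nbglm
from .basis import SplineBasis, place_knots
from .data import LineageAssignment, TrajectoryData, assign_lineages, compute_offsets

__all__ = [
    "GeneFit",
    "FitReport",
    "NBSplineGAM",
    "fit_all",
    "fit_gene",
    "evaluate_k",
    "predict_smoother",
]

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 20)


@dataclass
class GeneFit:
    """Estimated NB-GAM for a single gene."""

    beta: np.ndarray          # (L*K + p,)
    Sigma: np.ndarray         # (L*K + p, L*K + p)
    phi: float
    lam: float
    edf: float
    loglik: float
    aic: float
    converged: bool
    basis: SplineBasis
    n_lineages: int
    lineage_ranges: np.ndarray  # (L, 2) observed pseudotime range per lineage


@dataclass
class FitReport:
    """Summary of a full-dataset fit (serializable to JSON)."""

    n_genes: int
    n_non_converged: int
    non_converged_ids: list
    knots: list
    settings: dict = field(default_factory=dict)

    @property
    def fraction_non_converged(self) -> float:
        return self.n_non_converged / max(self.n_genes, 1)

    def to_json(self, path=None) -> str:
        payload = {
            "n_genes": self.n_genes,
            "n_non_converged": self.n_non_converged,
            "fraction_non_converged": self.fraction_non_converged,
            "non_converged_ids": [str(g) for g in self.non_converged_ids],
            "knots": [float(k) for k in self.knots],
            "settings": self.settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_design(data: TrajectoryData, assignment: LineageAssignment, basis: SplineBasis):
    """Block design matrix: lineage-specific spline blocks plus covariates.

    Row i carries the basis evaluated at T_li in the block of the lineage the
    cell is assigned to, zeros elsewhere, followed by the covariates U_i.
    """
    Z = assignment.Z
    n, L = Z.shape
    K = basis.K
    p = data.n_covariates
    X = np.zeros((n, L * K + p))
    ranges = np.zeros((L, 2))
    for l in range(L):
        idx = Z[:, l] == 1
        if not idx.any():
            raise ValueError(f"no cells assigned to lineage {l}")
        t = data.pseudotimes[idx, l]
        ranges[l] = (t.min(), t.max())
        X[idx, l * K : (l + 1) * K] = basis.design(t)
    if p:
        X[:, L * K :] = data.covariates
    return X, ranges


def build_penalty(basis: SplineBasis, n_lineages: int, n_covariates: int,
                  kind: str = "curvature") -> np.ndarray:
    """Penalty matrix S on the stacked coefficients (covariates unpenalized).

    ``curvature`` places the basis curvature matrix in each lineage block, so
    large lambda shrinks each smoother toward a straight line; ``ridge``
    places the identity (shrinks spline coefficients toward zero).
    """
    K = basis.K
    d = n_lineages * K + n_covariates
    S = np.zeros((d, d))
    if kind == "curvature":
        block = basis.curvature_penalty()
    elif kind == "ridge":
        block = np.eye(K)
    else:
        raise ValueError(f"unknown penalty kind {kind!r}")
    for l in range(n_lineages):
        S[l * K : (l + 1) * K, l * K : (l + 1) * K] = block
    return S


class NBSplineGAM(BaseEstimator):
    """Negative binomial spline GAM fitted independently per gene.

    Parameters
    ----------
    n_knots : int, default 6
        Number of spline knots K (= coefficients per lineage), placed at
        quantiles of the pooled assigned pseudotimes.
    lambda_grid : array-like or None
        Log-spaced candidate smoothing parameters for GCV; default 20 points
        spanning 1e-4..1e4.
    lambda_smooth : float or None
        If given, skip GCV and fix the smoothing parameter (0 = unpenalized).
    use_obs_weights : bool, default True
        Use ``data.obs_weights`` when present.
    max_outer : int, default 50
        Maximum coefficient/dispersion alternation steps.
    tol : float, default 1e-6
        Relative change of the penalized objective declaring convergence.
    penalty : {"curvature", "ridge"}, default "curvature"
        Smoothness penalty: curvature of each lineage smoother, or a plain
        ridge on the spline coefficients.
    offset_method : {"ratio", "libsize"}, default "ratio"
        How offsets are estimated when ``data.offsets`` is absent:
        median-of-ratios size factors (robust to composition shifts when
        many genes are differential) or plain log library size.
    seed : int, default 0
        Seed for the stochastic cell-to-lineage assignment.

    Attributes (after :meth:`fit`)
    ------------------------------
    beta_, Sigma_, phi_, lambda_, edf_, loglik_, aic_ : per-gene arrays
    converged_ : (G,) bool
    basis_, knots_, assignment_, design_, lineage_ranges_, report_
    """

    def __init__(
        self,
        n_knots: int = 6,
        lambda_grid=None,
        lambda_smooth=None,
        use_obs_weights: bool = True,
        max_outer: int = 50,
        tol: float = 1e-6,
        penalty: str = "curvature",
        offset_method: str = "ratio",
        seed: int = 0,
    ):
        self.n_knots = n_knots
        self.lambda_grid = lambda_grid
        self.lambda_smooth = lambda_smooth
        self.use_obs_weights = use_obs_weights
        self.max_outer = max_outer
        self.tol = tol
        self.penalty = penalty
        self.offset_method = offset_method
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, data: TrajectoryData, obs_weights=None, assignment=None):
        if not isinstance(data, TrajectoryData):
            raise TypeError("fit expects a TrajectoryData (see validate_trajectory_data)")
        if assignment is None:
            assignment = assign_lineages(data.lineage_weights, seed=self.seed)
        offsets = data.offsets
        if offsets is None:
            offsets = compute_offsets(data.counts, method=self.offset_method)
        if obs_weights is None and self.use_obs_weights:
            obs_weights = data.obs_weights
        if obs_weights is not None:
            obs_weights = np.asarray(obs_weights, dtype=float)
            if np.allclose(obs_weights, 1.0):
                obs_weights = None  # identical to the unweighted fit

        knots = place_knots(data.pseudotimes, assignment.Z, K=self.n_knots)
        basis = SplineBasis(knots)
        X, ranges = build_design(data, assignment, basis)
        S = build_penalty(basis, assignment.n_lineages, data.n_covariates, kind=self.penalty)

        out = _fit_matrix(
            X,
            data.counts,
            offsets,
            S,
            lambda_grid=(
                DEFAULT_LAMBDA_GRID if self.lambda_grid is None else np.asarray(self.lambda_grid, float)
            ),
            lambda_fixed=self.lambda_smooth,
            obs_w=obs_weights,
            max_outer=self.max_outer,
            tol=self.tol,
        )

        self.assignment_ = assignment
        self.offsets_ = offsets
        self.obs_weights_ = obs_weights
        self.basis_ = basis
        self.knots_ = knots
        self.design_ = X
        self.penalty_matrix_ = S
        self.lineage_ranges_ = ranges
        self.n_lineages_ = assignment.n_lineages
        self.gene_ids_ = data.gene_ids
        self.data_ = data
        for key, val in out.items():
            setattr(self, key + "_", val)
        bad = np.flatnonzero(~self.converged_)
        self.report_ = FitReport(
            n_genes=data.n_genes,
            n_non_converged=bad.size,
            non_converged_ids=list(data.gene_ids[bad]),
            knots=list(knots),
            settings={
                "n_knots": int(self.n_knots),
                "lambda_smooth": self.lambda_smooth,
                "seed": int(self.seed),
                "obs_weights": obs_weights is not None,
            },
        )
        return self

    # ---------------------------------------------------------- accessors
    def _check_fitted(self):
        if not hasattr(self, "beta_"):
            raise AttributeError("model is not fitted; call fit first")

    def gene_fit(self, gene) -> GeneFit:
        """Per-gene :class:`GeneFit` view (gene index or gene id)."""
        self._check_fitted()
        g = self._gene_index(gene)
        return GeneFit(
            beta=self.beta_[g],
            Sigma=self.Sigma_[g],
            phi=float(self.phi_[g]),
            lam=float(self.lambda_[g]),
            edf=float(self.edf_[g]),
            loglik=float(self.loglik_[g]),
            aic=float(self.aic_[g]),
            converged=bool(self.converged_[g]),
            basis=self.basis_,
            n_lineages=self.n_lineages_,
            lineage_ranges=self.lineage_ranges_,
        )

    def _gene_index(self, gene) -> int:
        if isinstance(gene, (int, np.integer)):
            return int(gene)
        hits = np.flatnonzero(self.gene_ids_ == gene)
        if hits.size != 1:
            raise KeyError(f"gene id {gene!r} not found")
        return int(hits[0])

    def predict_smoother(self, gene, lineage: int, t, counts_scale: bool = False):
        """Fitted lineage smoother s_gl(t) on the log-mean scale.

        Covariates are held at zero; with ``counts_scale`` the prediction is
        exponentiated (reference offset 0). Raises for non-converged genes.
        """
        self._check_fitted()
        g = self._gene_index(gene)
        if not self.converged_[g]:
            raise ValueError(f"gene {gene!r} did not converge; prediction is NA")
        K = self.basis_.K
        B = self.basis_.design(t)
        vals = B @ self.beta_[g, lineage * K : (lineage + 1) * K]
        return np.exp(vals) if counts_scale else vals


# ------------------------------------------------------------------ driver
def _fit_matrix(
    X,
    Y,
    offset,
    S,
    lambda_grid,
    lambda_fixed=None,
    obs_w=None,
    max_outer=50,
    tol=1e-6,
    phi_iters=40,
):
    """Fit every row of Y on the shared design X; returns dict of per-gene arrays."""
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    d = X.shape[1]
    xx = (X[:, :, None] * X[:, None, :]).reshape(n, d * d)
    ok = Y.sum(axis=1) > 0

    beta = np.full((G, d), np.nan)
    Sigma = np.full((G, d, d), np.nan)
    phi = np.full(G, np.nan)
    lam = np.full(G, np.nan)
    edf = np.full(G, np.nan)
    loglik = np.full(G, np.nan)
    aic = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)

    if ok.any():
        Yk = Y[ok]
        wk = obs_w[ok] if obs_w is not None else None
        Gk = Yk.shape[0]

        # --- initialization: moderate dispersion, mild penalty
        phi_k = np.full(Gk, 0.5)
        lam_init = 1.0 if lambda_fixed is None else float(lambda_fixed)
        res = nbglm.irls_nb(X, Yk, offset, phi_k, lam_init, S, wk, max_iter=30, xx=xx)
        phi_k = nbglm.moment_phi(Yk, res.mu, wk)

        # --- smoothing parameter by GCV on the grid (warm-started sweep)
        if lambda_fixed is None:
            best_gcv = np.full(Gk, np.inf)
            lam_k = np.full(Gk, lambda_grid[0])
            warm = res.beta
            beta_at_best = warm.copy()
            for lg in lambda_grid:
                res_l = nbglm.irls_nb(
                    X, Yk, offset, phi_k, lg, S, wk, beta0=warm, max_iter=50, xx=xx
                )
                warm = res_l.beta
                edf_l = nbglm.effective_df(res_l.xtwx, lg, S)
                score = nbglm.gcv_score(n, res_l.deviance, edf_l)
                score = np.where(res_l.failed, np.inf, score)
                better = score < best_gcv
                best_gcv = np.where(better, score, best_gcv)
                lam_k = np.where(better, lg, lam_k)
                beta_at_best[better] = res_l.beta[better]
        else:
            lam_k = np.full(Gk, float(lambda_fixed))
            beta_at_best = res.beta

        # --- alternate coefficients and dispersion at the selected penalty
        beta_k = beta_at_best
        pen_obj = np.full(Gk, np.inf)
        conv_k = np.zeros(Gk, dtype=bool)
        failed_k = np.zeros(Gk, dtype=bool)
        mono_bad = np.zeros(Gk, dtype=bool)
        last = None
        for _ in range(max_outer):
            res_a = nbglm.irls_nb(
                X, Yk, offset, phi_k, lam_k, S, wk, beta0=beta_k, max_iter=50, xx=xx
            )
            beta_k = res_a.beta
            failed_k |= res_a.failed
            phi_k = nbglm.update_phi_golden(Yk, res_a.mu, wk, iters=phi_iters)
            ll = nbglm.nb_loglik(Yk, res_a.mu, phi_k, wk)
            new_obj = -2.0 * ll + res_a.penalty
            # the alternation must not increase the penalized objective
            mono_bad |= new_obj > pen_obj + 1e-8 * (np.abs(pen_obj) + 1.0)
            rel = np.abs(pen_obj - new_obj) / (np.abs(new_obj) + 0.1)
            conv_k |= np.isfinite(new_obj) & (rel < tol)
            pen_obj = new_obj
            last = res_a
            if (conv_k | failed_k).all():
                break

        conv_k &= ~(failed_k | mono_bad)
        A = last.xtwx + lam_k[:, None, None] * S[None, :, :]
        try:
            Sig_k = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            A[:, np.arange(d), np.arange(d)] += 1e-8
            Sig_k = np.linalg.inv(A)
        Sig_k = (Sig_k + np.swapaxes(Sig_k, 1, 2)) / 2.0
        edf_k = nbglm.effective_df(last.xtwx, lam_k, S)
        ll_k = nbglm.nb_loglik(Yk, last.mu, phi_k, wk)
        aic_k = -2.0 * ll_k + 2.0 * (edf_k + 1.0)

        beta[ok] = beta_k
        Sigma[ok] = Sig_k
        phi[ok] = phi_k
        lam[ok] = lam_k
        edf[ok] = edf_k
        loglik[ok] = ll_k
        aic[ok] = aic_k
        conv = np.zeros(G, dtype=bool)
        conv[ok] = conv_k
        converged = conv

    # scrub non-converged genes so nothing downstream uses fabricated values
    bad = ~converged
    for arr in (phi, lam, edf, loglik, aic):
        arr[bad & ~np.isfinite(arr)] = np.nan

    return {
        "beta": beta,
        "Sigma": Sigma,
        "phi": phi,
        "lambda": lam,
        "edf": edf,
        "loglik": loglik,
        "aic": aic,
        "converged": converged,
    }


# ------------------------------------------------------------- thin wrappers
def fit_all(data: TrajectoryData, K: int = 6, **kwargs) -> NBSplineGAM:
    """Fit the NB-GAM to every gene; returns the fitted :class:`NBSplineGAM`."""
    return NBSplineGAM(n_knots=K, **kwargs).fit(data)


def fit_gene(
    y,
    data: TrajectoryData,
    Z=None,
    basis: SplineBasis | None = None,
    lambda_grid=None,
    obs_weights_row=None,
    lambda_smooth=None,
    penalty: str = "curvature",
    seed: int = 0,
) -> GeneFit:
    """Fit a single gene's NB-GAM and return its :class:`GeneFit`."""
    y = np.asarray(y, dtype=float).ravel()
    assignment = (
        LineageAssignment(Z=np.asarray(Z), seed=seed)
        if Z is not None
        else assign_lineages(data.lineage_weights, seed=seed)
    )
    if basis is None:
        basis = SplineBasis(place_knots(data.pseudotimes, assignment.Z, K=6))
    offsets = data.offsets if data.offsets is not None else compute_offsets(data.counts)
    X, ranges = build_design(data, assignment, basis)
    S = build_penalty(basis, assignment.n_lineages, data.n_covariates, kind=penalty)
    wrow = None if obs_weights_row is None else np.asarray(obs_weights_row, float)[None, :]
    out = _fit_matrix(
        X,
        y[None, :],
        offsets,
        S,
        lambda_grid=(
            DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
        ),
        lambda_fixed=lambda_smooth,
        obs_w=wrow,
    )
    return GeneFit(
        beta=out["beta"][0],
        Sigma=out["Sigma"][0],
        phi=float(out["phi"][0]),
        lam=float(out["lambda"][0]),
        edf=float(out["edf"][0]),
        loglik=float(out["loglik"][0]),
        aic=float(out["aic"][0]),
        converged=bool(out["converged"][0]),
        basis=basis,
        n_lineages=assignment.n_lineages,
        lineage_ranges=ranges,
    )


def evaluate_k(data: TrajectoryData, k_grid, n_genes_subsample: int = 100, seed: int = 0, **kwargs):
    """AIC over a grid of knot numbers on a random gene subsample.

    Returns a dict with the genes x |k_grid| AIC matrix, the per-K mean AIC
    (over genes with finite AIC across the whole grid), the per-gene
    AIC relative to its own minimum, and the mean-AIC-optimal K.
    """
    k_grid = list(k_grid)
    if len(k_grid) == 0:
        raise ValueError("k_grid must not be empty")
    if any(int(k) < 3 for k in k_grid):
        raise ValueError("all K in k_grid must be >= 3")
    rng = np.random.default_rng([int(seed), 0xEA1C])
    G = data.n_genes
    size = min(n_genes_subsample, G)
    genes = np.sort(rng.choice(G, size=size, replace=False))

    sub = TrajectoryData(
        counts=data.counts[genes],
        pseudotimes=data.pseudotimes,
        lineage_weights=data.lineage_weights,
        covariates=data.covariates,
        offsets=data.offsets,
        obs_weights=None if data.obs_weights is None else data.obs_weights[genes],
        gene_ids=data.gene_ids[genes],
        cell_ids=data.cell_ids,
        all_zero_genes=np.flatnonzero(data.counts[genes].sum(axis=1) == 0),
    )
    aic = np.full((size, len(k_grid)), np.nan)
    for j, k in enumerate(k_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NBSplineGAM(n_knots=int(k), seed=seed, **kwargs).fit(sub)
        aic[:, j] = model.aic_
    usable = np.isfinite(aic).all(axis=1)
    mean_aic = np.nanmean(aic[usable], axis=0) if usable.any() else np.full(len(k_grid), np.nan)
    rel = aic - np.nanmin(aic, axis=1, keepdims=True)
    best_k = int(k_grid[int(np.nanargmin(mean_aic))]) if np.isfinite(mean_aic).any() else None
    return {
        "genes": genes,
        "k_grid": np.asarray(k_grid, dtype=int),
        "aic": aic,
        "mean_aic": mean_aic,
        "relative_aic": rel,
        "best_k": best_k,
    }


def predict_smoother(fit: GeneFit, lineage: int, t, counts_scale: bool = False):
    """Evaluate a :class:`GeneFit` lineage smoother on the log-mean scale."""
    if not fit.converged:
        raise ValueError("fit did not converge; prediction is NA")
    K = fit.basis.K
    B = fit.basis.design(t)
    vals = B @ fit.beta[lineage * K : (lineage + 1) * K]
    return np.exp(vals) if counts_scale else vals
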