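"""Wald tests on spline-coefficient contrasts.

All differential-expression tests share one mechanism: a contrast matrix C
on the stacked coefficient vector beta_g = (beta_g11..beta_gLK, alpha_g) and
the Wald statistic

    W_g = (C' beta_g)' (C' Sigma_g C)^+ (C' beta_g)

where the pseudo-inverse is rank-truncated through an eigendecomposition of
C' Sigma C (eigenvalues below eig_tol relative to the largest are treated as
zero), and the chi-squared degrees of freedom equal the retained rank. The
default eig_tol of 1e-2 discards contrast directions whose variance is below
1% of the leading one: for grid-based contrasts those directions are almost
deterministic functions of the fitted smoothers, so they are dominated by
smoothing and range-estimation bias rather than sampling noise, and keeping
them wrecks the chi-squared calibration of the test. The
five tests differ only in C:

* association  - consecutive coefficient differences within a lineage
                 (is the smoother flat?);
* startVsEnd   - smoother difference between lineage end and start
                 (or any two user-given points);
* diffEnd      - pairwise differences between lineage endpoints;
* pattern      - pairwise differences on M equally spaced pseudotimes per
                 lineage (length-normalized grids);
* earlyDE      - the pattern construction restricted to the window between
                 two knots (localizes divergence around a branching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_EIG_TOL = 1e-2

__all__ = [
    "ContrastMatrix",
    "wald_test",
    "wald_test_batch",
    "association_test",
    "start_vs_end_test",
    "diff_end_test",
    "pattern_test",
    "early_de_test",
    "adjust_bh",
    "fisher_combine",
    "transient_score",
]


@dataclass
class ContrastMatrix:
    """A named contrast matrix on the stacked coefficient vector."""

    C: np.ndarray
    name: str
    labels: list = field(default_factory=list)
    eig_tol: float = DEFAULT_EIG_TOL


# ------------------------------------------------------------------- Wald
def wald_test(beta, Sigma, C, eig_tol: float = DEFAULT_EIG_TOL):
    """Rank-aware Wald test of H0: C' beta = 0 for a single gene.

    Returns ``(stat, df, p)``; NA (nan, 0, nan) when beta is non-finite or
    every contrast direction is degenerate.
    """
    beta = np.asarray(beta, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not np.all(np.isfinite(beta)):
        return np.nan, 0, np.nan
    ctb = C.T @ beta
    V = C.T @ Sigma @ C
    V = (V + V.T) / 2.0
    evals, evecs = np.linalg.eigh(V)
    keep = evals > eig_tol * max(evals.max(), 0.0)
    df = int(keep.sum())
    if df == 0:
        warnings.warn("all contrast directions are degenerate; returning NA", stacklevel=2)
        return np.nan, 0, np.nan
    proj = evecs.T @ ctb
    stat = float(np.sum(proj[keep] ** 2 / evals[keep]))
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def wald_test_batch(Beta, Sigmas, C, eig_tol: float = DEFAULT_EIG_TOL):
    """Vectorized rank-aware Wald tests across genes.

    Beta is (G, d), Sigmas is (G, d, d), C is (d, c); returns arrays
    ``(stats, dfs, ps)`` with NaN/0 rows for genes with non-finite beta.
    """
    Beta = np.asarray(Beta, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    G = Beta.shape[0]
    stats_ = np.full(G, np.nan)
    dfs = np.zeros(G, dtype=int)
    ps = np.full(G, np.nan)
    valid = np.isfinite(Beta).all(axis=1)
    if not valid.any():
        return stats_, dfs, ps
    Bv = Beta[valid]
    Sv = Sigmas[valid]
    ctb = Bv @ C                                   # (Gv, c)
    tmp = np.einsum("gij,jc->gic", Sv, C)
    V = np.einsum("ic,gik->gck", C, tmp)           # (Gv, c, c)
    V = (V + np.swapaxes(V, 1, 2)) / 2.0
    evals, evecs = np.linalg.eigh(V)
    vmax = np.maximum(evals.max(axis=1, keepdims=True), 0.0)
    keep = evals > eig_tol * vmax
    proj = np.einsum("gc,gce->ge", ctb, evecs)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(keep, proj**2 / evals, 0.0)
    st = contrib.sum(axis=1)
    df_v = keep.sum(axis=1)
    p_v = np.where(df_v > 0, sps.chi2.sf(st, np.maximum(df_v, 1)), np.nan)
    st = np.where(df_v > 0, st, np.nan)
    stats_[valid] = st
    dfs[valid] = df_v
    ps[valid] = p_v
    return stats_, dfs, ps


# ------------------------------------------------------- contrast builders
def _embed(model, lineage: int, vec: np.ndarray) -> np.ndarray:
    """Place a length-K vector in lineage ``lineage``'s coefficient block."""
    K = model.basis_.K
    d = model.beta_.shape[1]
    out = np.zeros(d)
    out[lineage * K : (lineage + 1) * K] = vec
    return out


def _assoc_block(model, lineage: int) -> np.ndarray:
    K = model.basis_.K
    cols = []
    for k in range(K - 1):
        e = np.zeros(K)
        e[k] = 1.0
        e[k + 1] = -1.0
        cols.append(_embed(model, lineage, e))
    return np.column_stack(cols)


def _point_contrast(model, lineage: int, t1: float, t0: float) -> np.ndarray:
    """Column encoding s_l(t1) - s_l(t0) for one lineage."""
    B = model.basis_.design(np.array([t0, t1]))
    return _embed(model, lineage, B[1] - B[0])


def _pair_grid_columns(model, l1: int, l2: int, grid1, grid2) -> np.ndarray:
    """Columns encoding s_l1(grid1[m]) - s_l2(grid2[m])."""
    B1 = model.basis_.design(np.asarray(grid1))
    B2 = model.basis_.design(np.asarray(grid2))
    cols = [
        _embed(model, l1, B1[m]) - _embed(model, l2, B2[m]) for m in range(len(grid1))
    ]
    return np.column_stack(cols)


def _result_frame(model, families, test_name, eig_tol=DEFAULT_EIG_TOL, lfc_fn=None) -> pd.DataFrame:
    """Run Wald tests for a list of (label, C) families and assemble a table.

    BH adjustment is applied across genes within each family; genes with
    failed fits get NA rows and do not enter the BH denominator.
    """
    frames = []
    Beta = np.where(model.converged_[:, None], model.beta_, np.nan)
    for label, C in families:
        st, df, p = wald_test_batch(Beta, model.Sigma_, C, eig_tol=eig_tol)
        lfc = lfc_fn(label, C, Beta) if lfc_fn is not None else np.full(len(st), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": model.gene_ids_,
                    "test": test_name,
                    "contrast": label,
                    "wald_stat": st,
                    "df": df,
                    "p_value": p,
                    "p_adj": adjust_bh(p),
                    "lfc": lfc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_multi_lineage(model, test):
    if model.n_lineages_ < 2:
        raise ValueError(
            f"{test} compares lineages and needs L >= 2; use the within-lineage "
            "tests (association, startVsEnd) for a single lineage"
        )


def _pairs(L):
    return [(l1, l2) for l1 in range(L) for l2 in range(l1 + 1, L)]


def association_test(model, mode: str = "lineage", eig_tol: float = DEFAULT_EIG_TOL) -> pd.DataFrame:
    """Within-lineage test that the smoother is flat (all coefficients equal).

    Per lineage the contrast has K-1 columns (consecutive coefficient
    differences); ``mode='global'`` stacks all L*(K-1) columns in one test.
    """
    if model.basis_.K < 2:
        raise ValueError("association test needs K >= 2")
    L = model.n_lineages_

    def lfc(label, C, Beta):
        # log-scale range of the smoother coefficients involved
        mask = np.abs(C).sum(axis=1) > 0
        sub = Beta[:, mask]
        return sub.max(axis=1) - sub.min(axis=1)

    if mode == "global":
        C = np.column_stack([_assoc_block(model, l) for l in range(L)])
        return _result_frame(model, [("global", C)], "association", eig_tol, lfc)
    families = [(f"lineage{l + 1}", _assoc_block(model, l)) for l in range(L)]
    return _result_frame(model, families, "association", eig_tol, lfc)


def start_vs_end_test(
    model, mode: str = "lineage", custom_points=None, eig_tol: float = DEFAULT_EIG_TOL
) -> pd.DataFrame:
    """Compare the smoother at the lineage end vs. start (progenitor state).

    ``custom_points`` may give one ``(t_start, t_end)`` pair per lineage to
    compare any two regions of the lineage.
    """
    L = model.n_lineages_
    points = []
    for l in range(L):
        lo, hi = model.lineage_ranges_[l]
        if custom_points is None:
            points.append((lo, hi))
        else:
            t0, t1 = custom_points[l]
            if not (lo <= t0 <= hi and lo <= t1 <= hi):
                raise ValueError(
                    f"custom points {t0, t1} outside lineage {l + 1} range [{lo}, {hi}]"
                )
            points.append((t0, t1))
    cols = [_point_contrast(model, l, t1=pt[1], t0=pt[0]) for l, pt in enumerate(points)]

    def lfc(label, C, Beta):
        return (Beta @ C).sum(axis=1) if C.shape[1] == 1 else np.abs(Beta @ C).mean(axis=1)

    if mode == "global":
        C = np.column_stack(cols)
        return _result_frame(model, [("global", C)], "startVsEnd", eig_tol, lfc)
    families = [(f"lineage{l + 1}", cols[l][:, None]) for l in range(L)]
    return _result_frame(model, families, "startVsEnd", eig_tol, lfc)


def diff_end_test(model, mode: str = "pairwise", eig_tol: float = DEFAULT_EIG_TOL) -> pd.DataFrame:
    """Compare smoother endpoints between lineages (L*(L-1)/2 pairwise columns)."""
    _check_multi_lineage(model, "diffEnd")
    L = model.n_lineages_
    cols = {}
    for l1, l2 in _pairs(L):
        c1 = _embed(model, l1, model.basis_.design([model.lineage_ranges_[l1, 1]])[0])
        c2 = _embed(model, l2, model.basis_.design([model.lineage_ranges_[l2, 1]])[0])
        cols[(l1, l2)] = c1 - c2

    def lfc(label, C, Beta):
        return (Beta @ C).sum(axis=1) if C.shape[1] == 1 else np.abs(Beta @ C).mean(axis=1)

    if mode == "global":
        C = np.column_stack(list(cols.values()))
        return _result_frame(model, [("global", C)], "diffEnd", eig_tol, lfc)
    families = [
        (f"lineage{l1 + 1}_vs_lineage{l2 + 1}", cols[(l1, l2)][:, None])
        for l1, l2 in _pairs(L)
    ]
    return _result_frame(model, families, "diffEnd", eig_tol, lfc)


def _grid_lfc(label, C, Beta):
    return np.abs(Beta @ C).mean(axis=1)


def pattern_test(model, M: int = 100, mode: str = "pairwise", eig_tol: float = DEFAULT_EIG_TOL) -> pd.DataFrame:
    """Compare expression patterns between lineages on length-normalized grids.

    For each lineage pair, M equally spaced pseudotimes between each
    lineage's own min and max are contrasted pointwise; the Wald statistic is
    rank-truncated (the M columns have rank at most the basis dimension).
    """
    _check_multi_lineage(model, "pattern")
    if M < 2:
        raise ValueError("M must be >= 2")
    L = model.n_lineages_
    fam = {}
    for l1, l2 in _pairs(L):
        g1 = np.linspace(*model.lineage_ranges_[l1], M)
        g2 = np.linspace(*model.lineage_ranges_[l2], M)
        fam[(l1, l2)] = _pair_grid_columns(model, l1, l2, g1, g2)
    if mode == "global":
        C = np.column_stack(list(fam.values()))
        return _result_frame(model, [("global", C)], "pattern", eig_tol, _grid_lfc)
    families = [
        (f"lineage{l1 + 1}_vs_lineage{l2 + 1}", fam[(l1, l2)]) for l1, l2 in _pairs(L)
    ]
    return _result_frame(model, families, "pattern", eig_tol, _grid_lfc)


def early_de_test(
    model, knots=(1, 2), M: int = 100, mode: str = "pairwise", eig_tol: float = DEFAULT_EIG_TOL
) -> pd.DataFrame:
    """Pattern comparison restricted to the window between two knots.

    ``knots`` are 1-based indices into the shared knot vector; the grid for
    each lineage spans the knot window clipped to that lineage's observed
    pseudotime range. Pairs where a lineage has no overlap with the window
    are skipped with a warning.
    """
    _check_multi_lineage(model, "earlyDE")
    k1, k2 = knots
    K = model.basis_.K
    if not (1 <= k1 < k2 <= K):
        raise ValueError(f"need 1 <= k1 < k2 <= {K}, got {knots}")
    t1 = model.knots_[k1 - 1]
    t2 = model.knots_[k2 - 1]
    L = model.n_lineages_
    grids = {}
    for l in range(L):
        lo, hi = model.lineage_ranges_[l]
        glo, ghi = max(t1, lo), min(t2, hi)
        grids[l] = np.linspace(glo, ghi, M) if glo < ghi else None
    fam = {}
    for l1, l2 in _pairs(L):
        if grids[l1] is None or grids[l2] is None:
            warnings.warn(
                f"lineage pair ({l1 + 1}, {l2 + 1}) has no overlap with the knot "
                "window; pair skipped",
                stacklevel=2,
            )
            continue
        fam[(l1, l2)] = _pair_grid_columns(model, l1, l2, grids[l1], grids[l2])
    if not fam:
        raise ValueError("no lineage pair overlaps the requested knot window")
    if mode == "global":
        C = np.column_stack(list(fam.values()))
        return _result_frame(model, [("global", C)], "earlyDE", eig_tol, _grid_lfc)
    families = [
        (f"lineage{l1 + 1}_vs_lineage{l2 + 1}", fam[(l1, l2)]) for l1, l2 in fam
    ]
    return _result_frame(model, families, "earlyDE", eig_tol, _grid_lfc)


# ----------------------------------------------------------- p-value tools
def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fisher_combine(p) -> float:
    """Fisher's method: -2 sum log p ~ chi-squared(2m) upper tail."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return np.nan
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, 2 * p.size))


def transient_score(stats_test1, stats_test2) -> np.ndarray:
    """Rank-based score for genes significant in test 1 but not test 2.

    score_g = rank(W1_g)^2 + (G - rank(W2_g))^2 with average ranks for ties;
    high scores rank genes expected to be DE under test 1 only. The score is
    a ranking device, not a significance measure.
    """
    s1 = np.asarray(stats_test1, dtype=float)
    s2 = np.asarray(stats_test2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("the two statistic vectors must have equal length")
    G = s1.size
    rk1 = sps.rankdata(s1, method="average", nan_policy="omit")
    rk2 = sps.rankdata(s2, method="average", nan_policy="omit")
    return rk1**2 + (G - rk2) ** 2
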