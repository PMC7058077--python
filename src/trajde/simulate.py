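"""Synthetic trajectory count data with known differential-expression truth.

The generator emulates the benchmark conditions of trajectory DE studies:
cells uniformly distributed along lineages, smooth log-scale mean functions
drawn from a small library of shapes (constant, linear, sigmoid, transient
bump; a sinusoid for cyclic topologies), NB counts with a common dispersion,
optional dropout zero inflation, and lineage weights of 1 after a branch
point and equal soft weights before it. Branch-point placement, effect-size
and mixture defaults are recorded in :class:`SimTruth` for reproducibility.

DE types for branching topologies (one randomly chosen lineage deviates):

* ``pattern``   - smooth divergence from the branch point to the end;
* ``endpoint``  - divergence confined to the late part of the lineage;
* ``transient`` - a bump after the branch that vanishes again by the end
  (endpoints agree, so endpoint-based tests are blind to it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrajectoryData, validate_trajectory_data

__all__ = ["SimTruth", "PerfCurve", "simulate_trajectory", "fdp_tpr_curve", "benchmark_run"]

TOPOLOGIES = ("single", "bifurcating", "multifurcating", "cyclic")

# gene-level DE mixture for branching topologies
DE_MIX = {"pattern": 0.5, "endpoint": 0.25, "transient": 0.25}
EFFECT_RANGE = (np.log(2.0), np.log(8.0))
BRANCH_FRAC = 0.4


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class SimTruth:
    """Ground truth of a simulated data set."""

    labels: np.ndarray            # per gene: null/dynamic/pattern/endpoint/transient
    de: np.ndarray                # bool, label != null
    within_dynamic: np.ndarray    # bool, non-constant along some lineage
    pair_de: np.ndarray           # (G, n_pairs) bool, between-lineage truth per pair
    pairs: list                   # lineage index pairs matching pair_de columns
    topology: str
    n_lineages: int
    t_total: float
    branch_frac: float
    prop_de: float
    phi: float
    pi_zero: float
    seed: int
    # generating parameters
    b0: np.ndarray
    base_type: np.ndarray         # 0 const, 1 linear, 2 sigmoid, 3 bump, 4 sine
    base_amp: np.ndarray
    base_center: np.ndarray
    de_lineage: np.ndarray        # deviating lineage index, -1 for none
    delta_type: np.ndarray        # 0 none, 1 pattern, 2 endpoint, 3 transient
    delta_amp: np.ndarray
    params: dict = field(default_factory=dict)

    def base_log_mean(self, gene: int, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        T = self.t_total
        typ = self.base_type[gene]
        a = self.base_amp[gene]
        c = self.base_center[gene]
        if typ == 0:
            f = np.zeros_like(t)
        elif typ == 1:
            f = a * (t / T - 0.5)
        elif typ == 2:
            f = a / (1.0 + np.exp(-(t - c) / (0.1 * T)))
        elif typ == 3:
            f = a * np.exp(-((t - c) ** 2) / (2.0 * (0.15 * T) ** 2))
        else:  # sine, cyclic
            f = 0.5 * a * np.sin(2.0 * np.pi * t / T + c)
        return self.b0[gene] + f

    def delta_log_mean(self, gene: int, t) -> np.ndarray:
        """Lineage-specific deviation added on the deviating lineage."""
        t = np.asarray(t, dtype=float)
        typ = self.delta_type[gene]
        if typ == 0:
            return np.zeros_like(t)
        tb = self.branch_frac * self.t_total
        x = np.clip((t - tb) / (self.t_total - tb), 0.0, 1.0)
        a = self.delta_amp[gene]
        if typ == 1:      # pattern: smooth divergence from the branch
            return a * _smoothstep(x)
        if typ == 2:      # endpoint: late ramp
            return a * _smoothstep((x - 0.7) / 0.3)
        # transient: bump vanishing at both ends of the branch segment
        return a * np.exp(-((x - 0.5) ** 2) / (2.0 * 0.15**2))

    def log_mean(self, gene: int, lineage: int, t) -> np.ndarray:
        """True log mean (offset-free) of ``gene`` on ``lineage`` at pseudotimes t."""
        base = self.base_log_mean(gene, t)
        if lineage == self.de_lineage[gene]:
            base = base + self.delta_log_mean(gene, t)
        return base


@dataclass
class PerfCurve:
    """FDP-TPR performance sweep along a gene ranking."""

    table: pd.DataFrame  # threshold, tp, fp, fn, fdp, tpr

    def tpr_at_fdp(self, max_fdp: float = 0.05) -> float:
        ok = self.table["fdp"] <= max_fdp
        return float(self.table.loc[ok, "tpr"].max()) if ok.any() else 0.0


def simulate_trajectory(
    topology: str = "bifurcating",
    n_cells: int = 500,
    n_genes: int = 5000,
    prop_de: float = 0.2,
    phi: float = 0.5,
    pi_zero: float = 0.0,
    seed: int = 0,
    t_total: float = 1.0,
    lib_sd: float = 0.3,
    dynamic_base_frac: float = 0.5,
):
    """Simulate a trajectory data set with known DE truth.

    Defaults follow the bifurcating benchmark design (500 cells, 5000 genes,
    20% DE). ``dynamic_base_frac`` is the fraction of genes in branching
    topologies that carry a lineage-shared dynamic profile (the rest are
    constant); set it to 0 for a constant-truth null. Returns
    ``(TrajectoryData, SimTruth)``.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose one of {TOPOLOGIES}")
    if not 0.0 <= prop_de <= 1.0:
        raise ValueError("prop_de must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 0x51E0])
    L = {"single": 1, "cyclic": 1, "bifurcating": 2, "multifurcating": 3}[topology]
    branching = L > 1
    tb = BRANCH_FRAC * t_total

    # ------------------------------------------------------------- cells
    t = rng.uniform(0.0, t_total, size=n_cells)
    if branching:
        lineage = np.where(t < tb, -1, rng.integers(0, L, size=n_cells))
        weights = np.zeros((n_cells, L))
        pre = lineage == -1
        weights[pre] = 1.0 / L
        for l in range(L):
            weights[lineage == l, l] = 1.0
        pseudotimes = np.tile(t[:, None], (1, L))
        # pre-branch cells behave identically on every lineage
        cell_lineage = np.where(pre, 0, lineage)
    else:
        weights = np.ones((n_cells, 1))
        pseudotimes = t[:, None]
        cell_lineage = np.zeros(n_cells, dtype=int)

    # ------------------------------------------------------------- genes
    n_de = int(round(prop_de * n_genes))
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[rng.choice(n_genes, size=n_de, replace=False)] = True

    b0 = np.clip(rng.normal(np.log(10.0), 0.8, size=n_genes), np.log(0.5), np.log(100.0))
    base_type = np.zeros(n_genes, dtype=int)
    base_amp = np.zeros(n_genes)
    base_center = rng.uniform(0.2 * t_total, 0.8 * t_total, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    amp = sign * np.exp(rng.uniform(*EFFECT_RANGE, size=n_genes))

    labels = np.array(["null"] * n_genes, dtype=object)
    de_lineage = np.full(n_genes, -1, dtype=int)
    delta_type = np.zeros(n_genes, dtype=int)
    delta_amp = np.zeros(n_genes)

    if branching:
        # every gene may carry its own (lineage-shared) dynamic base shape
        dynamic_base = rng.random(n_genes) < dynamic_base_frac
        base_type[dynamic_base] = rng.integers(1, 4, size=int(dynamic_base.sum()))
        base_amp[dynamic_base] = amp[dynamic_base]
        de_idx = np.flatnonzero(de_mask)
        kinds = rng.choice(
            list(DE_MIX.keys()), size=de_idx.size, p=list(DE_MIX.values())
        )
        labels[de_idx] = kinds
        code = {"pattern": 1, "endpoint": 2, "transient": 3}
        delta_type[de_idx] = [code[k] for k in kinds]
        de_lineage[de_idx] = rng.integers(0, L, size=de_idx.size)
        dsign = rng.choice([-1.0, 1.0], size=de_idx.size)
        delta_amp[de_idx] = dsign * np.exp(rng.uniform(*EFFECT_RANGE, size=de_idx.size))
    else:
        # within-lineage DE: dynamic shapes vs. constant nulls
        de_idx = np.flatnonzero(de_mask)
        labels[de_idx] = "dynamic"
        if topology == "cyclic":
            base_type[de_idx] = 4
            base_center[de_idx] = rng.uniform(0.0, 2.0 * np.pi, size=de_idx.size)
        else:
            base_type[de_idx] = rng.integers(1, 4, size=de_idx.size)
        base_amp[de_idx] = amp[de_idx]

    pairs = [(l1, l2) for l1 in range(L) for l2 in range(l1 + 1, L)]
    pair_de = np.zeros((n_genes, len(pairs)), dtype=bool)
    for j, (l1, l2) in enumerate(pairs):
        pair_de[:, j] = de_mask & ((de_lineage == l1) ^ (de_lineage == l2))

    truth = SimTruth(
        labels=labels,
        de=de_mask,
        within_dynamic=(base_type != 0) | (delta_type != 0),
        pair_de=pair_de,
        pairs=pairs,
        topology=topology,
        n_lineages=L,
        t_total=t_total,
        branch_frac=BRANCH_FRAC,
        prop_de=prop_de,
        phi=phi,
        pi_zero=pi_zero,
        seed=int(seed),
        b0=b0,
        base_type=base_type,
        base_amp=base_amp,
        base_center=base_center,
        de_lineage=de_lineage,
        delta_type=delta_type,
        delta_amp=delta_amp,
        params={"lib_sd": lib_sd, "effect_range": EFFECT_RANGE, "de_mix": DE_MIX},
    )

    # ------------------------------------------------------------- counts
    lib = np.exp(rng.normal(0.0, lib_sd, size=n_cells))
    log_mu = np.empty((n_genes, n_cells))
    for l in range(L):
        idx = np.flatnonzero(cell_lineage == l)
        if idx.size == 0:
            continue
        tl = t[idx]
        for g in range(n_genes):
            log_mu[g, idx] = truth.log_mean(g, l, tl)
    mu = np.exp(log_mu) * lib[None, :]
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    if pi_zero > 0:
        drop = rng.random(counts.shape) < pi_zero
        counts = np.where(drop, 0, counts)

    data = validate_trajectory_data(
        counts,
        pseudotimes,
        weights,
        gene_ids=np.array([f"gene{g}" for g in range(n_genes)], dtype=object),
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
    )
    return data, truth


def fdp_tpr_curve(scores_or_p, truth) -> PerfCurve:
    """Sweep a gene ranking and report FDP and TPR at every cutoff.

    ``scores_or_p`` ranks genes with smaller = more significant (p-values).
    NA-scored genes are excluded from the ranking and counted as
    non-discoveries. ``truth`` is a :class:`SimTruth` (uses its ``de``
    labels) or a boolean array.
    """
    p = np.asarray(scores_or_p, dtype=float).ravel()
    de = truth.de if isinstance(truth, SimTruth) else np.asarray(truth, dtype=bool).ravel()
    if p.shape != de.shape:
        raise ValueError(
            f"length mismatch: {p.size} scores for {de.size} truth labels"
        )
    ok = np.isfinite(p)
    n_pos = int(de.sum())
    order = np.flatnonzero(ok)[np.argsort(p[ok], kind="stable")]
    tp = np.cumsum(de[order])
    fp = np.cumsum(~de[order])
    fn = n_pos - tp
    fdp = fp / np.maximum(1, fp + tp)
    tpr = tp / max(1, n_pos) if n_pos else np.zeros_like(tp, dtype=float)
    table = pd.DataFrame(
        {
            "threshold": p[order],
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "fdp": fdp,
            "tpr": tpr,
        }
    )
    # prepend the zero-discovery cutoff (FDP = 0 by the max(1, .) guard)
    head = pd.DataFrame(
        {"threshold": [-np.inf], "tp": [0], "fp": [0], "fn": [n_pos], "fdp": [0.0], "tpr": [0.0]}
    )
    return PerfCurve(table=pd.concat([head, table], ignore_index=True))


def benchmark_run(settings: dict, methods, seed: int = 0):
    """End-to-end simulate -> fit -> test -> FDP/TPR curves.

    ``settings`` are keyword arguments for :func:`simulate_trajectory`;
    ``methods`` is a list of test names among association, startVsEnd,
    diffEnd, pattern, earlyDE (run as global tests). Returns a dict with the
    fitted model, truth, per-method curves and a summary table of TPR at
    FDP <= 0.05.
    """
    from . import testing
    from .model import NBSplineGAM

    data, truth = simulate_trajectory(seed=seed, **settings)
    model = NBSplineGAM(seed=seed).fit(data)
    runners = {
        "association": lambda: testing.association_test(model, mode="global"),
        "startVsEnd": lambda: testing.start_vs_end_test(model, mode="global"),
        "diffEnd": lambda: testing.diff_end_test(model, mode="global"),
        "pattern": lambda: testing.pattern_test(model, mode="global"),
        "earlyDE": lambda: testing.early_de_test(
            model, knots=(1, model.basis_.K), mode="global"
        ),
    }
    between = {"diffEnd", "pattern", "earlyDE"}
    curves = {}
    rows = []
    for name in methods:
        if name not in runners:
            raise ValueError(f"unknown test {name!r}")
        res = runners[name]()
        p = res["p_value"].to_numpy()
        labels = truth.de if name in between or truth.n_lineages == 1 else truth.within_dynamic
        curve = fdp_tpr_curve(p, labels)
        curves[name] = curve
        rows.append({"method": name, "tpr_at_fdp_0.05": curve.tpr_at_fdp(0.05)})
    return {
        "model": model,
        "truth": truth,
        "curves": curves,
        "summary": pd.DataFrame(rows),
    }
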