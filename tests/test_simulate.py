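import numpy as np
import pytest

import trajde
from trajde.simulate import fdp_tpr_curve, simulate_trajectory


class TestSimulator:
    def test_table_design_shapes(self):
        data, truth = simulate_trajectory(
            "bifurcating", n_cells=500, n_genes=1000, prop_de=0.2, seed=0
        )
        assert data.counts.shape == (1000, 500)
        assert data.n_lineages == 2
        assert truth.de.sum() == 200
        # cells before the branch share soft weights, later cells are hard
        tb = truth.branch_frac * truth.t_total
        pre = data.pseudotimes[:, 0] < tb
        assert np.allclose(data.lineage_weights[pre], 0.5)
        assert set(data.lineage_weights[~pre].ravel()) <= {0.0, 1.0}

    def test_no_de_when_prop_zero(self):
        _, truth = simulate_trajectory("bifurcating", n_cells=100, n_genes=50, prop_de=0.0, seed=1)
        assert truth.de.sum() == 0
        assert (truth.labels == "null").all()

    def test_null_genes_identical_across_lineages(self):
        _, truth = simulate_trajectory("bifurcating", n_cells=50, n_genes=40, prop_de=0.3, seed=2)
        t = np.linspace(0, 1, 20)
        for g in range(40):
            same = np.allclose(truth.log_mean(g, 0, t), truth.log_mean(g, 1, t))
            assert same == (not truth.de[g])

    def test_transient_de_vanishes_at_endpoint(self):
        _, truth = simulate_trajectory("bifurcating", n_cells=50, n_genes=200, prop_de=0.5, seed=3)
        trans = np.flatnonzero(truth.labels == "transient")
        assert trans.size > 0
        for g in trans[:10]:
            l = truth.de_lineage[g]
            other = 1 - l
            end_diff = truth.log_mean(g, l, [1.0])[0] - truth.log_mean(g, other, [1.0])[0]
            assert abs(end_diff) < 0.05
            mid = truth.branch_frac + 0.5 * (1 - truth.branch_frac)
            mid_diff = truth.log_mean(g, l, [mid])[0] - truth.log_mean(g, other, [mid])[0]
            assert abs(mid_diff) > abs(end_diff)

    def test_seed_reproducibility_bitwise(self):
        d1, _ = simulate_trajectory("multifurcating", n_cells=80, n_genes=30, seed=7)
        d2, _ = simulate_trajectory("multifurcating", n_cells=80, n_genes=30, seed=7)
        assert np.array_equal(d1.counts, d2.counts)
        d3, _ = simulate_trajectory("multifurcating", n_cells=80, n_genes=30, seed=8)
        assert not np.array_equal(d1.counts, d3.counts)

    def test_invalid_topology_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            simulate_trajectory("tree", n_cells=10, n_genes=5)

    def test_empirical_means_match_generating_functions(self):
        data, truth = simulate_trajectory(
            "single", n_cells=2000, n_genes=30, prop_de=0.5, seed=4, lib_sd=0.0
        )
        t = data.pseudotimes[:, 0]
        # bin cells along pseudotime and compare means where expression is high
        bins = np.digitize(t, np.linspace(0, 1, 6)[1:-1])
        errs = []
        for g in range(30):
            mu_true = np.exp(truth.log_mean(g, 0, t))
            for b in range(5):
                sel = bins == b
                if mu_true[sel].mean() >= 1:
                    errs.append(
                        abs(data.counts[g, sel].mean() - mu_true[sel].mean())
                        / mu_true[sel].mean()
                    )
        assert np.mean(errs) <= 0.10

    def test_zero_inflation_rate(self):
        pi = 0.3
        d_inf, truth = simulate_trajectory(
            "single", n_cells=400, n_genes=300, prop_de=0.0, pi_zero=pi, seed=5
        )
        d_ref, _ = simulate_trajectory(
            "single", n_cells=400, n_genes=300, prop_de=0.0, pi_zero=0.0, seed=5
        )
        excess = d_ref.counts.astype(bool).mean() - d_inf.counts.astype(bool).mean()
        # dropout hits nonzero draws at rate pi
        expected = pi * d_ref.counts.astype(bool).mean()
        assert abs(excess - expected) < 0.03


class TestBenchmarkRun:
    def test_end_to_end_curves_and_summary(self):
        res = trajde.benchmark_run(
            dict(topology="bifurcating", n_cells=200, n_genes=120, prop_de=0.3),
            ["pattern", "diffEnd"],
            seed=2,
        )
        assert set(res["curves"]) == {"pattern", "diffEnd"}
        assert res["summary"].shape == (2, 2)
        tprs = dict(zip(res["summary"]["method"], res["summary"]["tpr_at_fdp_0.05"]))
        # whole-pattern comparison sees transient DE that endpoints miss
        assert tprs["pattern"] >= tprs["diffEnd"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            trajde.benchmark_run(
                dict(topology="bifurcating", n_cells=50, n_genes=10), ["nope"], seed=0
            )


class TestPerfCurve:
    def test_direct_formula(self):
        # 8 true positives and 2 false positives at the top of the ranking
        truth = np.array([True] * 10 + [False] * 10)
        p = np.concatenate([np.linspace(0.001, 0.01, 8), [0.005, 0.006], np.linspace(0.5, 1, 10)])
        truth = np.array([True] * 8 + [False, False] + [True, True] + [False] * 8)
        curve = fdp_tpr_curve(p, truth)
        row = curve.table.iloc[10]  # after 10 discoveries
        assert row["tp"] == 8 and row["fp"] == 2
        assert row["fdp"] == pytest.approx(0.2)
        assert row["tpr"] == pytest.approx(0.8)

    def test_zero_discoveries_guard(self):
        curve = fdp_tpr_curve([np.nan, np.nan], [True, False])
        assert curve.table.iloc[0]["fdp"] == 0.0
        assert curve.table.iloc[0]["tpr"] == 0.0

    def test_matches_brute_force_confusion_matrices(self):
        rng = np.random.default_rng(6)
        G = 150
        p = rng.uniform(size=G)
        truth = rng.random(G) < 0.5
        curve = fdp_tpr_curve(p, truth).table.iloc[1:]  # skip the zero cutoff
        order = np.argsort(p, kind="stable")
        for i, (_, row) in enumerate(curve.iterrows()):
            called = order[: i + 1]
            tp = truth[called].sum()
            fp = (~truth[called]).sum()
            fn = truth.sum() - tp
            assert row["tp"] == tp and row["fp"] == fp and row["fn"] == fn
            assert row["fdp"] == pytest.approx(fp / max(1, fp + tp))
            assert row["tpr"] == pytest.approx(tp / (tp + fn))

    def test_tpr_nondecreasing_along_ranking(self):
        rng = np.random.default_rng(7)
        curve = fdp_tpr_curve(rng.uniform(size=100), rng.random(100) < 0.3)
        assert (np.diff(curve.table["tpr"]) >= 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fdp_tpr_curve([0.1, 0.2], [True])

    def test_na_scores_count_as_non_discoveries(self):
        p = np.array([0.01, np.nan, 0.02])
        truth = np.array([True, True, False])
        curve = fdp_tpr_curve(p, truth)
        assert curve.table["tpr"].max() == pytest.approx(0.5)
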