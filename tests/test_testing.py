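import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.linalg import pinvh
from statsmodels.stats.multitest import multipletests

import trajde
from trajde.testing import (
    adjust_bh,
    fisher_combine,
    transient_score,
    wald_test,
    wald_test_batch,
)


def _random_psd(dim, rng):
    A = rng.normal(size=(dim, dim))
    return A @ A.T + 0.1 * np.eye(dim)


def _oracle_wald(beta, Sigma, C, tol):
    """Brute-force generalized-inverse quadratic form, rank from eigenvalues."""
    V = C.T @ Sigma @ C
    evals = np.linalg.eigvalsh(V)
    df = int((evals > tol * evals.max()).sum())
    stat = float((C.T @ beta) @ pinvh(V, atol=tol * evals.max()) @ (C.T @ beta))
    return stat, df


class TestWald:
    def test_null_point_gives_zero_stat_unit_p(self):
        rng = np.random.default_rng(0)
        Sigma = _random_psd(4, rng)
        C = rng.normal(size=(4, 2))
        stat, df, p = wald_test(np.zeros(4), Sigma, C)
        assert stat == 0.0 and p == 1.0 and df == 2

    def test_scalar_closed_form(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=5)
        Sigma = _random_psd(5, rng)
        c = rng.normal(size=5)
        stat, df, p = wald_test(beta, Sigma, c)
        expected = (c @ beta) ** 2 / (c @ Sigma @ c)
        assert df == 1
        assert np.isclose(stat, expected, rtol=1e-12)
        assert np.isclose(p, sps.chi2.sf(expected, 1))

    @pytest.mark.parametrize("rank", [5, 3])
    def test_matches_pseudoinverse_oracle(self, rank):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=5)
        Sigma = _random_psd(5, rng)
        base = rng.normal(size=(5, rank))
        C = base if rank == 5 else np.column_stack([base, base @ rng.normal(size=(rank, 2))])
        stat, df, p = wald_test(beta, Sigma, C, eig_tol=1e-8)
        stat_o, df_o = _oracle_wald(beta, Sigma, C, 1e-8)
        assert df == df_o == rank
        assert np.isclose(stat, stat_o, atol=1e-10, rtol=1e-10)

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(3)
        G, d = 7, 6
        Beta = rng.normal(size=(G, d))
        Sig = np.array([_random_psd(d, rng) for _ in range(G)])
        C = rng.normal(size=(d, 3))
        st_b, df_b, p_b = wald_test_batch(Beta, Sig, C)
        for g in range(G):
            st_s, df_s, p_s = wald_test(Beta[g], Sig[g], C)
            assert np.isclose(st_b[g], st_s) and df_b[g] == df_s

    def test_nonfinite_beta_gives_na(self):
        rng = np.random.default_rng(4)
        Sigma = _random_psd(3, rng)
        stat, df, p = wald_test(np.array([1.0, np.nan, 0.0]), Sigma, np.eye(3))
        assert np.isnan(stat) and df == 0 and np.isnan(p)


class TestContrasts:
    def test_association_zero_stat_for_equal_coefficients(self, bif_model):
        model = bif_model
        beta = model.beta_.copy()
        g = int(np.flatnonzero(model.converged_)[0])
        K = model.basis_.K
        beta[g, :K] = 1.7  # equal within lineage 1
        from trajde.testing import _assoc_block

        C = _assoc_block(model, 0)
        stat, df, p = wald_test(beta[g], model.Sigma_[g], C)
        assert np.isclose(stat, 0.0, atol=1e-20)

    def test_diff_end_pair_count_three_lineages(self):
        data, _ = trajde.simulate_trajectory(
            "multifurcating", n_cells=200, n_genes=12, prop_de=0.0, seed=5
        )
        model = trajde.NBSplineGAM(seed=0).fit(data)
        res = trajde.diff_end_test(model, mode="pairwise")
        assert res["contrast"].nunique() == 3  # L(L-1)/2 for L=3

    def test_between_lineage_tests_require_two_lineages(self, flat_single):
        _, model = flat_single
        with pytest.raises(ValueError, match="within-lineage"):
            trajde.diff_end_test(model)

    def test_custom_points_outside_range_rejected(self, bif_model):
        with pytest.raises(ValueError, match="outside"):
            trajde.start_vs_end_test(
                bif_model, custom_points=[(0.0, 5.0)] * bif_model.n_lineages_
            )

    def test_equal_custom_points_give_zero_stat(self, bif_model):
        mid = [(0.5, 0.5)] * bif_model.n_lineages_
        res = trajde.start_vs_end_test(bif_model, custom_points=mid)
        ok = np.isfinite(res["wald_stat"])
        assert np.allclose(res.loc[ok, "wald_stat"], 0.0, atol=1e-16)

    def test_early_de_full_range_equals_pattern(self, bif_model):
        pt = trajde.pattern_test(bif_model)
        ed = trajde.early_de_test(bif_model, knots=(1, bif_model.basis_.K))
        assert np.allclose(
            pt["wald_stat"], ed["wald_stat"], atol=1e-10, equal_nan=True
        )

    def test_early_de_knot_order_validated(self, bif_model):
        with pytest.raises(ValueError, match="k1 < k2"):
            trajde.early_de_test(bif_model, knots=(3, 2))

    def test_pattern_df_bounded_by_basis_dimension(self, bif_model):
        res = trajde.pattern_test(bif_model, M=100)
        K = bif_model.basis_.K
        assert res["df"].max() <= 2 * K - 1

    def test_pattern_invariant_to_grid_column_order(self, bif_model):
        from trajde.testing import _pair_grid_columns

        g1 = np.linspace(*bif_model.lineage_ranges_[0], 40)
        g2 = np.linspace(*bif_model.lineage_ranges_[1], 40)
        C = _pair_grid_columns(bif_model, 0, 1, g1, g2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(C.shape[1])
        gene = int(np.flatnonzero(bif_model.converged_)[1])
        s1, d1, _ = wald_test(bif_model.beta_[gene], bif_model.Sigma_[gene], C)
        s2, d2, _ = wald_test(bif_model.beta_[gene], bif_model.Sigma_[gene], C[:, perm])
        assert np.isclose(s1, s2) and d1 == d2

    def test_failed_fits_get_na_rows(self, bif_sim):
        data, _ = bif_sim
        counts = data.counts.copy()
        counts[4] = 0
        d2 = trajde.validate_trajectory_data(counts, data.pseudotimes, data.lineage_weights)
        model = trajde.NBSplineGAM(seed=3).fit(d2)
        res = trajde.association_test(model, mode="global")
        assert np.isnan(res.loc[res.gene_id == d2.gene_ids[4], "p_value"]).all()


class TestPValueTools:
    def test_bh_hand_computed(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_trivial_cases(self):
        assert np.allclose(adjust_bh([1.0, 1.0]), 1.0)
        assert np.allclose(adjust_bh([0.2]), [0.2])

    def test_bh_nan_excluded_from_m(self):
        q = adjust_bh([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2, 3]], adjust_bh([0.01, 0.02, 0.03]))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_bh_matches_statsmodels(self, ps):
        assert np.allclose(adjust_bh(ps), multipletests(ps, method="fdr_bh")[1])

    def test_fisher_closed_form(self):
        x = -2 * 2 * np.log(0.05)
        assert np.isclose(fisher_combine([0.05, 0.05]), sps.chi2.sf(x, 4))
        assert np.isclose(fisher_combine([1.0, 1.0]), 1.0)
        assert np.isclose(fisher_combine([0.3]), 0.3)

    def test_fisher_rejects_zero(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    def test_transient_score_extremes(self):
        # G=10; rank 10 on test 1 and rank 1 on test 2 maximizes the score
        s1 = np.arange(10, dtype=float)
        s2 = np.arange(10, 0, -1, dtype=float)
        scores = transient_score(s1, s2)
        assert scores[-1] == 10**2 + (10 - 1) ** 2
        assert scores[0] == 1**2 + (10 - 10) ** 2

    def test_transient_score_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        s1, s2 = rng.normal(size=50), rng.normal(size=50)
        scores = transient_score(s1, s2)
        rk1 = sps.rankdata(s1)
        rk2 = sps.rankdata(s2)
        assert np.allclose(scores, rk1**2 + (50 - rk2) ** 2)
        assert np.argmax(scores) == np.argmax(rk1**2 + (50 - rk2) ** 2)
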