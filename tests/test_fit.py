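import numpy as np
import pytest
import statsmodels.api as sm

import trajde
from trajde.model import NBSplineGAM, evaluate_k, fit_gene


def _single_lineage_counts(G=20, n=300, seed=0, dynamic=True):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n)
    amp = rng.normal(0, 0.5, (G, 1)) if dynamic else np.zeros((G, 1))
    logmu = np.log(10) + rng.normal(0, 0.5, (G, 1)) + amp * np.sin(2 * np.pi * t)[None, :]
    counts = rng.poisson(rng.gamma(2.0, np.exp(logmu) * 0.5))
    data = trajde.validate_trajectory_data(counts, t[:, None], np.ones((n, 1)))
    return data


class TestFitGene:
    def test_unpenalized_fit_matches_nb_glm_irls(self):
        """With lambda=0 the GAM reduces to an ordinary NB-GLM on the basis."""
        data = _single_lineage_counts(G=10, n=400, seed=1)
        model = NBSplineGAM(n_knots=4, lambda_smooth=0.0, seed=0).fit(data)
        for g in range(data.n_genes):
            fam = sm.families.NegativeBinomial(alpha=max(model.phi_[g], 1e-6))
            ref = sm.GLM(
                data.counts[g], model.design_, family=fam, offset=model.offsets_
            ).fit(maxiter=200, tol=1e-10)
            rel = np.max(
                np.abs(ref.params - model.beta_[g]) / np.maximum(np.abs(ref.params), 1e-8)
            )
            assert rel < 1e-4

    def test_flat_genes_recover_flat_smoothers(self):
        """GCV smoothing keeps fitted curves of constant-truth genes nearly
        flat (median log-scale range below 0.2)."""
        rng = np.random.default_rng(5)
        n, G = 500, 12
        t = rng.uniform(0, 1, n)
        counts = rng.poisson(rng.gamma(2.0, np.exp(2.0) * 0.5, (G, n)))
        data = trajde.validate_trajectory_data(
            counts, t[:, None], np.ones((n, 1)), offsets=np.zeros(n)
        )
        grid = np.linspace(0.02, 0.98, 50)
        ranges = []
        for g in range(G):
            fit = fit_gene(counts[g], data)
            vals = trajde.predict_smoother(fit, 0, grid)
            ranges.append(vals.max() - vals.min())
        assert np.median(ranges) < 0.2

    def test_all_zero_gene_not_converged(self):
        data = _single_lineage_counts(G=3, n=100, seed=2)
        fit = fit_gene(np.zeros(100), data)
        assert not fit.converged
        assert np.isnan(fit.aic)
        with pytest.raises(ValueError, match="NA"):
            trajde.predict_smoother(fit, 0, [0.5])


class TestFitAll:
    def test_simulated_dataset_mostly_converges(self, bif_sim, bif_model):
        data, _ = bif_sim
        assert bif_model.beta_.shape[0] == data.n_genes
        assert bif_model.converged_.mean() >= 0.95

    def test_refit_is_bitwise_identical(self, bif_sim, bif_model):
        data, _ = bif_sim
        again = NBSplineGAM(seed=3).fit(data)
        assert np.array_equal(bif_model.beta_, again.beta_, equal_nan=True)
        assert np.array_equal(bif_model.phi_, again.phi_, equal_nan=True)

    def test_all_zero_genes_flagged_in_report(self, bif_sim):
        data, _ = bif_sim
        counts = data.counts.copy()
        counts[[2, 9, 33]] = 0
        d2 = trajde.validate_trajectory_data(counts, data.pseudotimes, data.lineage_weights)
        m = NBSplineGAM(seed=3).fit(d2)
        assert sorted(np.flatnonzero(~m.converged_)) == [2, 9, 33]
        assert m.report_.n_non_converged == 3

    def test_unit_obs_weights_reproduce_unweighted_fit(self, bif_sim, bif_model):
        data, _ = bif_sim
        ones = np.ones_like(data.counts, dtype=float)
        m = NBSplineGAM(seed=3).fit(data, obs_weights=ones)
        assert np.array_equal(bif_model.beta_, m.beta_, equal_nan=True)

    def test_smoother_curvature_shrinks_monotonically_in_lambda(self):
        data = _single_lineage_counts(G=5, n=250, seed=7)
        grid = np.linspace(0.05, 0.95, 80)
        curv_norm = []
        for lam in (0.0, 1.0, 100.0, 1e4, 1e6):
            m = NBSplineGAM(lambda_smooth=lam, seed=0).fit(data)
            vals = np.array(
                [m.predict_smoother(g, 0, grid) for g in range(data.n_genes)]
            )
            second = np.diff(vals, 2, axis=1)
            curv_norm.append(np.linalg.norm(second, axis=1))
        curv_norm = np.array(curv_norm)
        assert ((np.diff(curv_norm, axis=0) <= 1e-6).all(axis=0)).all()

    def test_dispersion_recovery(self):
        rng = np.random.default_rng(9)
        G, n, phi = 100, 500, 0.5
        t = rng.uniform(0, 1, n)
        mu = np.exp(rng.normal(np.log(15), 0.5, (G, 1))) * np.ones((1, n))
        counts = rng.poisson(rng.gamma(1 / phi, mu * phi))
        data = trajde.validate_trajectory_data(counts, t[:, None], np.ones((n, 1)))
        m = NBSplineGAM(seed=0).fit(data)
        assert 0.4 <= np.median(m.phi_) <= 0.6

    def test_sigma_is_symmetric_psd(self, bif_model):
        ok = bif_model.converged_
        Sig = bif_model.Sigma_[ok]
        assert np.allclose(Sig, np.swapaxes(Sig, 1, 2))
        evals = np.linalg.eigvalsh(Sig)
        assert evals.min() > -1e-10

    def test_predict_endpoints_match_start_vs_end_contrast(self, bif_model):
        sv = trajde.start_vs_end_test(bif_model)
        g = int(np.flatnonzero(bif_model.converged_)[3])
        for l in range(bif_model.n_lineages_):
            lo, hi = bif_model.lineage_ranges_[l]
            pred = (
                bif_model.predict_smoother(g, l, [hi])[0]
                - bif_model.predict_smoother(g, l, [lo])[0]
            )
            row = sv[
                (sv.gene_id == bif_model.gene_ids_[g])
                & (sv.contrast == f"lineage{l + 1}")
            ]
            assert np.isclose(float(row["lfc"].iloc[0]), pred)


class TestEvaluateK:
    def test_single_value_grid_returns_it(self):
        data = _single_lineage_counts(G=8, n=150, seed=3)
        res = evaluate_k(data, [5], n_genes_subsample=8, seed=0)
        assert res["best_k"] == 5

    def test_empty_grid_rejected(self):
        data = _single_lineage_counts(G=4, n=100, seed=3)
        with pytest.raises(ValueError, match="empty"):
            evaluate_k(data, [])

    def test_all_zero_gene_gets_nan_row(self):
        data = _single_lineage_counts(G=6, n=150, seed=4)
        counts = data.counts.copy()
        counts[2] = 0
        d2 = trajde.validate_trajectory_data(counts, data.pseudotimes, data.lineage_weights)
        res = evaluate_k(d2, [4, 5], n_genes_subsample=6, seed=0)
        row = np.flatnonzero(res["genes"] == 2)[0]
        assert np.isnan(res["aic"][row]).all()
        assert np.isfinite(res["mean_aic"]).all()
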