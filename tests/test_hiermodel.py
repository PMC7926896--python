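"""Hierarchical model: conditional correctness, determinism, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carpstress import hiermodel


def tiny_model_data():
    """2 genes x 2 animals (one per group), fully crossed."""
    y = np.array([0.3, -0.2, 1.1, 0.4])
    gene_idx = np.array([0, 0, 1, 1])
    animal_idx = np.array([0, 1, 0, 1])
    x_animal = np.array([0.0, 1.0])
    return hiermodel.ModelData(
        y, gene_idx, animal_idx, x_animal, ["g1", "g2"], ["a1", "a2"], "tiny"
    )


def model_simulated(rng, n_gene=26, n_animal=8, sa=1.0, sb=1.0, sg=0.3, s=0.5):
    x = np.array([0.0] * (n_animal // 2) + [1.0] * (n_animal - n_animal // 2))
    alpha = rng.normal(0, sa, n_gene)
    beta = rng.normal(0, sb, n_gene)
    gamma = rng.normal(0, sg, n_animal)
    gi = np.repeat(np.arange(n_gene), n_animal)
    ai = np.tile(np.arange(n_animal), n_gene)
    y = alpha[gi] + beta[gi] * x[ai] + gamma[ai] + rng.normal(0, s, n_gene * n_animal)
    data = hiermodel.ModelData(
        y, gi, ai, x,
        [f"g{j}" for j in range(n_gene)],
        [f"a{i}" for i in range(n_animal)],
        "sim",
    )
    return data, beta


class TestBuildModelData:
    def test_complete_design_208_observations(self, normalized):
        data = hiermodel.build_model_data(normalized, "tel")
        assert len(data.y) == 8 * 26
        assert data.n_gene == 26 and data.n_animal == 8
        assert data.x_animal.sum() == 4

    def test_missing_cell_drops_one_observation(self, normalized):
        sub = normalized.copy()
        drop = (
            (sub["region"] == "tel")
            & (sub["gene"] == "c-fos")
            & (sub["animal_id"] == sub["animal_id"].iloc[0])
        )
        data = hiermodel.build_model_data(sub[~drop], "tel")
        assert len(data.y) == 8 * 26 - 1

    def test_empty_region_rejected(self, normalized):
        with pytest.raises(ValueError, match="no observations"):
            hiermodel.build_model_data(normalized, "cortex")

    def test_single_group_rejected(self, normalized):
        only_ctrl = normalized[normalized["group"] == "control"]
        with pytest.raises(ValueError, match="single treatment group"):
            hiermodel.build_model_data(only_ctrl, "tel")


class TestConditionals:
    """Gibbs full conditionals vs an independent precision-matrix derivation.

    For fixed variances the coefficients theta = (alpha, beta, gamma) are
    jointly Gaussian given y: Q = X'X/s^2 + P, b = X'y/s^2; the full
    conditional of theta_m given the rest has variance 1/Q_mm and mean
    (b_m - sum_{k!=m} Q_mk theta_k)/Q_mm.
    """

    def test_match_closed_form_on_tiny_instance(self):
        data = tiny_model_data()
        s2, sa2, sb2, sg2 = 0.4, 1.3, 0.8, 0.6
        rng = np.random.default_rng(0)
        theta = rng.normal(size=6)  # alpha1, alpha2, beta1, beta2, gamma1, gamma2
        # design matrix columns in that order
        X = np.zeros((4, 6))
        for n in range(4):
            X[n, data.gene_idx[n]] = 1.0
            X[n, 2 + data.gene_idx[n]] = data.x_obs[n]
            X[n, 4 + data.animal_idx[n]] = 1.0
        P = np.diag([1 / sa2, 1 / sa2, 1 / sb2, 1 / sb2, 1 / sg2, 1 / sg2])
        Q = X.T @ X / s2 + P
        b = X.T @ data.y / s2

        alpha, beta, gamma = theta[:2], theta[2:4], theta[4:]
        # implementation-side conditional parameters per block
        resid_a = data.y - beta[data.gene_idx] * data.x_obs - gamma[data.animal_idx]
        mean_a, var_a = hiermodel.coefficient_conditional(
            np.bincount(data.gene_idx, weights=resid_a, minlength=2),
            np.bincount(data.gene_idx, minlength=2).astype(float),
            s2,
            sa2,
        )
        resid_b = data.y - alpha[data.gene_idx] - gamma[data.animal_idx]
        mean_b, var_b = hiermodel.coefficient_conditional(
            np.bincount(data.gene_idx, weights=data.x_obs * resid_b, minlength=2),
            np.bincount(data.gene_idx, weights=data.x_obs**2, minlength=2),
            s2,
            sb2,
        )
        resid_g = data.y - alpha[data.gene_idx] - beta[data.gene_idx] * data.x_obs
        mean_g, var_g = hiermodel.coefficient_conditional(
            np.bincount(data.animal_idx, weights=resid_g, minlength=2),
            np.bincount(data.animal_idx, minlength=2).astype(float),
            s2,
            sg2,
        )
        impl_mean = np.concatenate([mean_a, mean_b, mean_g])
        impl_var = np.concatenate([var_a, var_b, var_g])

        for m in range(6):
            var_m = 1.0 / Q[m, m]
            mean_m = (b[m] - Q[m].dot(theta) + Q[m, m] * theta[m]) * var_m
            assert impl_var[m] == pytest.approx(var_m, abs=1e-10)
            assert impl_mean[m] == pytest.approx(mean_m, abs=1e-10)

    def test_variance_conditional_is_inverse_gamma(self):
        """Draws of the variance update follow IG(a0 + k/2, b0 + ss/2)
        (scipy.stats.invgamma as the distributional oracle)."""
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1.5, size=40)
        prior = hiermodel.GibbsPrior(a0=0.001, b0=0.001)
        draws = np.array(
            [hiermodel._update_variance(rng, 1.0, values, prior) for _ in range(4000)]
        )
        shape = prior.a0 + len(values) / 2
        scale = prior.b0 + values @ values / 2
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert ks.pvalue > 0.01


class TestFit:
    def test_same_seed_identical_draws(self):
        data, _ = model_simulated(np.random.default_rng(3), n_gene=6, n_animal=4)
        f1 = hiermodel.fit_gibbs(data, chains=2, iters=300, warmup=100, seed=9)
        f2 = hiermodel.fit_gibbs(data, chains=2, iters=300, warmup=100, seed=9)
        for k in f1.draws:
            assert np.array_equal(f1.draws[k], f2.draws[k])

    def test_spike_prior_shrinks_beta_to_zero(self):
        """Forcing the beta variance prior toward zero collapses all group
        differences."""
        data, _ = model_simulated(np.random.default_rng(4))
        prior = hiermodel.GibbsPrior(a0=1e7, b0=1e-3)  # IG spike at ~1e-10
        fit = hiermodel.fit_gibbs(data, chains=2, iters=400, warmup=200, seed=2, prior=prior)
        assert np.abs(fit.summaries["point_estimate"]).max() < 1e-3

    def test_no_treatment_betas_reproduce_prior_balance(self):
        """With the treatment indicator removed (all x = 0) the group
        differences carry no likelihood weight: posterior means sit at ~0
        and the posterior probability of a positive effect near 1/2."""
        rng = np.random.default_rng(12)
        for rep in range(5):
            data, _ = model_simulated(rng, sb=0.0)
            data.x_animal[:] = 0.0
            fit = hiermodel.fit_gibbs(data, chains=2, iters=800, warmup=400, seed=50 + rep)
            p = fit.summaries["p_positive"]
            assert ((p > 0.3) & (p < 0.7)).all()

    def test_half_normal_prior_runs_and_agrees_roughly(self):
        data, _ = model_simulated(np.random.default_rng(5))
        fit_ig = hiermodel.fit_gibbs(data, chains=2, iters=800, warmup=400, seed=1)
        fit_hn = hiermodel.fit_gibbs(
            data, chains=2, iters=800, warmup=400, seed=1,
            prior=hiermodel.GibbsPrior(family="half_normal"),
        )
        assert np.allclose(
            fit_ig.summaries["point_estimate"],
            fit_hn.summaries["point_estimate"],
            atol=0.3,
        )

    def test_warmup_must_be_less_than_iters(self):
        data, _ = model_simulated(np.random.default_rng(6), n_gene=4, n_animal=4)
        with pytest.raises(ValueError):
            hiermodel.fit_gibbs(data, iters=100, warmup=100)


class TestPosteriorProb:
    def test_all_positive(self):
        assert hiermodel.posterior_prob_positive(np.ones(10)) == 1.0

    def test_symmetric_half(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        assert hiermodel.posterior_prob_positive(draws) == 0.5

    def test_sign_consistency_with_point_estimate(self, normalized):
        data = hiermodel.build_model_data(normalized, "opt")
        fit = hiermodel.fit_gibbs(data, chains=2, iters=1000, warmup=500, seed=7)
        s = fit.summaries
        strong_neg = s[s["point_estimate"] < -0.5]
        strong_pos = s[s["point_estimate"] > 0.5]
        assert (strong_neg["p_positive"] < 0.5).all()
        assert (strong_pos["p_positive"] > 0.5).all()


def _fake_fit(draws_beta, n_chains):
    kept = draws_beta.shape[1]
    J = draws_beta.shape[2]
    draws = {
        "alpha": draws_beta.copy(),
        "beta": draws_beta,
        "gamma": draws_beta[..., :2].copy(),
        "s2": np.abs(draws_beta[..., 0]) + 0.1,
        "sigma_alpha2": np.abs(draws_beta[..., 0]) + 0.1,
        "sigma_beta2": np.abs(draws_beta[..., 0]) + 0.1,
        "sigma_gamma2": np.abs(draws_beta[..., 0]) + 0.1,
    }
    return hiermodel.HierarchicalFit(
        draws=draws,
        summaries=pd.DataFrame(),
        diagnostics=pd.DataFrame(),
        gene_labels=[f"g{j}" for j in range(J)],
        animal_labels=["a0", "a1"],
        region="x",
        converged=True,
    )


class TestDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        fit = _fake_fit(rng.normal(size=(4, 500, 3)), 4)
        d = hiermodel.diagnostics(fit)
        beta_rows = d[d["parameter"].str.startswith("beta")]
        assert (beta_rows["rhat"] < 1.01).all()
        # ESS of i.i.d. draws is near the draw count
        assert (beta_rows["ess"] > 0.8 * 2000).all()

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(4, 500, 2))
        draws[0] += 3.0
        fit = _fake_fit(draws, 4)
        d = hiermodel.diagnostics(fit)
        assert d[d["parameter"].str.startswith("beta")]["rhat"].max() > 1.1

    def test_nonconvergence_sets_flag(self):
        data, _ = model_simulated(np.random.default_rng(7))
        fit = hiermodel.fit_gibbs(data, chains=2, iters=60, warmup=20, seed=0)
        assert not fit.converged
        assert fit.warnings


class TestPosteriorPredictive:
    @pytest.fixture(scope="class")
    def fit_and_data(self):
        data, _ = model_simulated(np.random.default_rng(8))
        fit = hiermodel.fit_gibbs(data, chains=2, iters=1500, warmup=500, seed=4)
        return fit, data

    def test_replicates_have_observation_shape(self, fit_and_data):
        fit, data = fit_and_data
        ppc = hiermodel.posterior_predictive(fit, data, n_rep=1, seed=0)
        assert ppc.y_rep.shape == (1, len(data.y))

    def test_seed_reproducible(self, fit_and_data):
        fit, data = fit_and_data
        a = hiermodel.posterior_predictive(fit, data, n_rep=10, seed=3)
        b = hiermodel.posterior_predictive(fit, data, n_rep=10, seed=3)
        assert np.array_equal(a.y_rep, b.y_rep)

    def test_too_many_reps_rejected(self, fit_and_data):
        fit, data = fit_and_data
        with pytest.raises(ValueError, match="exceeds"):
            hiermodel.posterior_predictive(fit, data, n_rep=10**6)

    def test_model_data_quantiles_inside_band(self, fit_and_data):
        """On model-simulated data the observed quantiles sit inside the
        central 95% replicate band at nearly all probe points."""
        fit, data = fit_and_data
        ppc = hiermodel.posterior_predictive(fit, data, n_rep=200, seed=1)
        inside = (
            (ppc.observed_quantiles >= ppc.rep_quantile_lo)
            & (ppc.observed_quantiles <= ppc.rep_quantile_hi)
        ).mean()
        assert inside >= 0.9
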