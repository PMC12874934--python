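import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logit

from districtsae import mcmc, synthetic
from districtsae.hierarchy import HierarchyError, HierarchyIndex
from districtsae.mcmc import (
    DivergenceError,
    InitializationError,
    ModelConfig,
    compute_vpc,
    effective_sample_size,
    gibbs_variance_draw,
    initialize_chain,
    mh_update_scalar,
    run_mcmc,
)

from ._oracles import rw_metropolis_acceptance_normal
from .conftest import ar1_series, two_level_table


class TestBuildIndex:
    def test_counts(self):
        cfg = synthetic.SimConfig(
            n_states=2,
            districts_per_state=3,
            clusters_per_district=4,
            women_per_cluster=5,
            frac_ineligible=0.0,
            n_unmatched_clusters=0,
        )
        idx = synthetic.generate_hierarchy(cfg)
        table = synthetic.simulate_outcomes(idx, cfg).rename(
            columns={"district_id_true": "district_id"}
        )
        built = mcmc.build_index(table)
        assert (built.n_states, built.n_districts, built.n_clusters) == (2, 6, 24)

    def test_single_cluster_degenerate(self):
        table = two_level_table([4], [2])
        idx = mcmc.build_index(table)
        assert (idx.n_clusters, idx.n_districts, idx.n_states) == (1, 1, 1)

    def test_crossed_cluster_rejected(self):
        table = two_level_table([4, 4], [2, 2])
        table.loc[table.index[-1], "district_id"] = "D_OTHER"
        with pytest.raises(HierarchyError):
            mcmc.build_index(table)


class TestInitialization:
    def test_intercept_is_empirical_logit(self):
        table = two_level_table([10, 10], [5, 5])
        state = initialize_chain(table["y"].to_numpy(), mcmc.build_index(table))
        assert state.beta0 == pytest.approx(0.0)
        table2 = two_level_table([50, 50], [42, 42])
        state2 = initialize_chain(table2["y"].to_numpy(), mcmc.build_index(table2))
        assert state2.beta0 == pytest.approx(logit(0.84), abs=1e-9)

    def test_degenerate_outcomes_rejected(self):
        table = two_level_table([5, 5], [5, 5])
        with pytest.raises(InitializationError):
            initialize_chain(table["y"].to_numpy(), mcmc.build_index(table))

    def test_deterministic_and_floored(self):
        table = two_level_table([10, 10, 10], [2, 5, 9])
        idx = mcmc.build_index(table)
        a = initialize_chain(table["y"].to_numpy(), idx)
        b = initialize_chain(table["y"].to_numpy(), idx)
        assert (a.beta0, a.sigma2_u0, a.sigma2_v0, a.sigma2_f0) == (
            b.beta0,
            b.sigma2_u0,
            b.sigma2_v0,
            b.sigma2_f0,
        )
        assert min(a.sigma2_u0, a.sigma2_v0, a.sigma2_f0) >= 0.01


class TestMetropolisKernel:
    def test_acceptance_matches_numerical_integral(self):
        """Long-run acceptance on a standard-normal target matches the
        brute-force double integral of the acceptance probability."""
        rng = np.random.default_rng(5)
        x, hits, n = 0.0, 0, 20_000
        for _ in range(n):
            x, acc = mh_update_scalar(x, lambda z: -z * z / 2.0, 2.0, rng)
            hits += acc
        assert hits / n == pytest.approx(rw_metropolis_acceptance_normal(2.0), abs=0.02)

    def test_tiny_proposal_always_accepts(self):
        rng = np.random.default_rng(1)
        hits = sum(
            mh_update_scalar(0.3, lambda z: -z * z / 2.0, 1e-12, rng)[1] for _ in range(200)
        )
        assert hits == 200

    def test_impossible_proposal_rejected(self):
        rng = np.random.default_rng(2)
        log_target = lambda z: 0.0 if z <= 0.5 else -np.inf
        for _ in range(100):
            new, acc = mh_update_scalar(0.0, log_target, 10.0, rng)
            assert new <= 0.5

    def test_nonfinite_current_state_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(DivergenceError):
            mh_update_scalar(5.0, lambda z: -np.inf, 1.0, rng)


class TestGibbsVariance:
    def test_zero_residuals_concentrate_near_prior_scale(self):
        rng = np.random.default_rng(0)
        draws = [gibbs_variance_draw(np.zeros(50), 0.001, 0.001, rng) for _ in range(500)]
        assert np.median(draws) < 1e-3

    def test_posterior_mean_matches_inverse_gamma_formula(self):
        rng = np.random.default_rng(1)
        r = rng.normal(0, np.sqrt(0.94), 10_000)
        a, b = 0.001, 0.001
        draws = np.array([gibbs_variance_draw(r, a, b, rng) for _ in range(2000)])
        expected = (b + r @ r / 2) / (a + r.size / 2 - 1)
        assert draws.mean() == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(0.94, rel=0.05)


class TestSampler:
    def test_bit_reproducible_under_seed(self):
        table = two_level_table([20, 20, 20], [5, 10, 15])
        idx = mcmc.build_index(table)
        cfg = ModelConfig(burn_in=100, n_iter=300, seed=9)
        y = table["y"].to_numpy()
        a = run_mcmc(y, idx, cfg)
        b = run_mcmc(y, idx, cfg)
        np.testing.assert_array_equal(a.beta0, b.beta0)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.sigma2_f0, b.sigma2_f0)

    def test_null_truth_gives_small_variances(self):
        """Fitting data generated with all variances zero shrinks every
        variance posterior mean below 0.05 (n = 5,000 women)."""
        cfg = synthetic.SimConfig(
            n_states=5,
            districts_per_state=5,
            clusters_per_district=8,
            women_per_cluster=25,
            sigma2_state=0.0,
            sigma2_district=0.0,
            sigma2_cluster=0.0,
            frac_ineligible=0.0,
            n_unmatched_clusters=0,
            seed=9,
        )
        idx = synthetic.generate_hierarchy(cfg)
        table = synthetic.simulate_outcomes(idx, cfg)
        samples = run_mcmc(
            table["outcome_any"].to_numpy(), idx, ModelConfig(burn_in=500, n_iter=2000, seed=2)
        )
        frame = mcmc.summarize_posterior(samples).variance_components.frame
        assert (frame["posterior_mean"] < 0.05).all()

    def test_adaptation_frozen_after_burn_in(self, fitted_small):
        _, samples, _ = fitted_small
        sds = samples.proposal_sd_monitored
        assert np.all(sds == sds[0])

    def test_row_order_invariance(self, sim_small):
        """Shuffling input rows leaves the fitted chain bit-identical
        (unit coding is canonical by sorted label)."""
        from districtsae import ingest

        table, _ = ingest.apply_eligibility_filter(sim_small.table, sim_small.crosswalk)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        cfg = ModelConfig(burn_in=100, n_iter=200, seed=5)
        a = run_mcmc(table["outcome_any"].to_numpy(), mcmc.build_index(table), cfg)
        b = run_mcmc(shuffled["outcome_any"].to_numpy(), mcmc.build_index(shuffled), cfg)
        np.testing.assert_array_equal(a.beta0, b.beta0)
        np.testing.assert_array_equal(a.v, b.v)

    def test_recovery_on_shared_fixture(self, fitted_small, sim_small):
        """Posterior means land in the right neighbourhood of the simulation
        truths and the credible intervals bracket them."""
        _, _, summary = fitted_small
        frame = summary.variance_components.frame.set_index("level")
        truth = {"state": 0.54, "district": 0.16, "cluster": 0.94}
        for level, t in truth.items():
            assert frame.loc[level, "ci_low"] <= t <= frame.loc[level, "ci_high"]
        assert frame.loc["cluster", "posterior_mean"] == pytest.approx(0.94, rel=0.35)


class TestEffectiveSampleSize:
    def test_iid_limit(self):
        x = np.random.default_rng(0).standard_normal(25_000)
        assert effective_sample_size(x) == pytest.approx(25_000, rel=0.10)

    @pytest.mark.parametrize("phi", [0.5, 0.9])
    def test_ar1_closed_form(self, phi):
        n = 25_000
        ess = effective_sample_size(ar1_series(phi, n))
        assert ess == pytest.approx(n * (1 - phi) / (1 + phi), rel=0.15)

    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size(np.ones(100)) == 0.0

    def test_matches_arviz(self):
        arviz = pytest.importorskip("arviz")
        x = ar1_series(0.7, 10_000, seed=4)
        mine = effective_sample_size(x)
        theirs = float(arviz.ess(x[None, :]))
        assert mine == pytest.approx(theirs, rel=0.10)


class TestSummaries:
    def test_constant_chain_degenerate_interval(self, fitted_small):
        _, samples, _ = fitted_small
        const = np.full(500, 0.5)
        mean, lo, hi = mcmc._mean_ci(const)
        assert (mean, lo, hi) == (0.5, 0.5, 0.5)

    def test_normal_draw_interval(self):
        draws = np.random.default_rng(1).standard_normal(200_000)
        _, lo, hi = mcmc._mean_ci(draws)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_low_ess_flagged(self, fitted_small):
        _, samples, _ = fitted_small
        strict = ModelConfig(
            burn_in=samples.config.burn_in,
            n_iter=samples.config.n_iter,
            seed=samples.config.seed,
            ess_threshold=10_000.0,
        )
        summary = mcmc.summarize_posterior(samples, strict)
        assert any(name == "beta0" for name, _ in summary.low_ess)


class TestVPC:
    @pytest.mark.parametrize(
        "variances, expected",
        [
            ((0.52, 0.20, 1.28), (26.0, 10.0, 64.0)),
            ((1.0, 1.0, 1.0), (100 / 3, 100 / 3, 100 / 3)),
            ((1.0, 0.0, 0.0), (100.0, 0.0, 0.0)),
        ],
    )
    def test_examples(self, variances, expected):
        assert compute_vpc(*variances) == pytest.approx(expected, abs=1e-9)

    @given(
        st.tuples(*[st.floats(min_value=0.001, max_value=10.0)] * 3),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_sums_to_100_and_scale_invariant(self, variances, c):
        vpc = compute_vpc(*variances)
        assert sum(vpc) == pytest.approx(100.0, abs=1e-9)
        scaled = compute_vpc(*(c * v for v in variances))
        assert scaled == pytest.approx(vpc, abs=1e-6)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            compute_vpc(0.0, 0.0, 0.0)
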