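import numpy as np
import pandas as pd
import pytest

from radrepeat.cohort import CohortSpec, generate_cohort
from radrepeat.model import (
    ConvergenceError,
    ModelConfig,
    PosteriorSamples,
    check_initials_within_prior,
    destandardise,
    fit_with_retries,
    gelman_rubin,
    initial_values,
    sample_posterior,
    standardise,
)
from conftest import make_table


class TestStandardise:
    def test_hand_worked_convention(self):
        table = make_table({"P1": [(0, 1)], "P2": [(2, 3)]})
        d = standardise(table, "feature")
        assert d.baseline1_mean == 1.0
        assert d.baseline1_var == 2.0  # unbiased
        assert d.x1 == pytest.approx([-0.7071, 0.7071], abs=1e-4)
        assert d.x2 == pytest.approx([0.0, 1.4142], abs=1e-4)

    def test_baseline1_mean_zero_var_one(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        assert d.x1.mean() == pytest.approx(0.0, abs=1e-10)
        assert d.x1.var(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_baseline_rejected(self):
        table = make_table({"P1": [(1, 2)], "P2": [(1, 3)]})
        with pytest.raises(ValueError, match="degenerate"):
            standardise(table, "feature")

    def test_missing_feature_rejected(self, micro_table):
        with pytest.raises(ValueError, match="nope"):
            standardise(micro_table, "nope")


class TestInitialValues:
    def test_micro_worked_example(self, micro_data):
        init = initial_values(micro_data)
        assert init.mu_ij0 == pytest.approx([2.0, 3.0, 6.0])
        assert init.sigma_r0 == pytest.approx(np.sqrt(2), abs=1e-10)
        assert init.mu_i0 == pytest.approx([2.5, 6.0])
        assert init.sigma_p0 == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert init.mu_00 == pytest.approx(4.25)
        assert init.sigma_00 == pytest.approx(2.4749, abs=1e-4)
        assert init.epsilon_0 == pytest.approx(2.0)

    def test_identical_repeats(self):
        table = make_table({"P1": [(1, 1), (2, 2)], "P2": [(4, 4)]})
        init = initial_values(standardise(table, "feature"))
        assert init.sigma_r0 == 0.0
        assert init.epsilon_0 == 0.0

    def test_single_patient_rejected(self):
        table = make_table({"P1": [(1, 2), (3, 4), (5, 6)]})
        with pytest.raises(ValueError, match="2 patients"):
            initial_values(standardise(table, "feature"))

    def test_one_lesion_per_patient_fallback(self):
        table = make_table({"P1": [(0.0, 0.5)], "P2": [(2.0, 2.1)], "P3": [(4.0, 4.4)]})
        init = initial_values(standardise(table, "feature"))
        assert init.sigma_p0 == init.sigma_r0 > 0

    def test_prior_range_check(self, micro_data):
        init = initial_values(micro_data)
        check_initials_within_prior(init, ModelConfig())
        tight = ModelConfig(sigma_prior_scale=1e-4, mu_prior_sd=1e-4)
        with pytest.raises(ValueError, match="prior"):
            check_initials_within_prior(init, tight)


class TestSamplePosterior:
    def test_draw_count_under_defaults(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        cfg = ModelConfig(seed=0)
        s = sample_posterior(d, initial_values(d), cfg)
        assert s.mu0.shape == (3, 1500)  # 3 x (2000 - 500)
        assert s.n_chains * s.n_draws == 4500
        assert s.mu_i.shape == (3, 1500, 10)
        assert s.mu_ij.shape == (3, 1500, 80)
        assert (s.sigma0 > 0).all() and (s.sigma_p > 0).all() and (s.sigma_r > 0).all()

    def test_seeded_determinism(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        cfg = ModelConfig(n_samples=300, n_warmup=100, seed=5)
        a = sample_posterior(d, initial_values(d), cfg)
        b = sample_posterior(d, initial_values(d), cfg)
        assert np.array_equal(a.mu0, b.mu0)
        assert np.array_equal(a.mu_ij, b.mu_ij)
        c = sample_posterior(d, initial_values(d), cfg, attempt=1)
        assert not np.array_equal(a.mu0, c.mu0)

    def test_parameter_recovery(self, recovery_cohort):
        """Posterior medians recover the generating SDs within 30%."""
        d = standardise(recovery_cohort, "feature")
        s, _ = fit_with_retries(d, initial_values(d), ModelConfig(seed=1))
        s = destandardise(s, d)
        for name, true in [("sigma_r", 0.1), ("sigma_p", 0.3), ("sigma0", 0.5)]:
            med = float(np.median(s.flat(name)))
            assert abs(med - true) / true < 0.30, (name, med)

    def test_epsilon_interval_covers_zero(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        s = sample_posterior(d, initial_values(d), ModelConfig(seed=2))
        lo, hi = np.quantile(s.flat("epsilon"), [0.025, 0.975])
        assert lo < 0 < hi


class TestGelmanRubin:
    def _fake(self, chains: np.ndarray) -> PosteriorSamples:
        m, n = chains.shape
        z = np.zeros((m, n))
        return PosteriorSamples(
            mu0=chains, sigma0=np.abs(chains) + 1, sigma_p=np.abs(chains) + 1,
            sigma_r=np.abs(chains) + 1, epsilon=z,
            mu_i=z[:, :, None], mu_ij=z[:, :, None],
            patient_ids=["P1"], lesion_ids=["L1"],
        )

    def test_well_mixed_copies_pass(self):
        rng = np.random.default_rng(0)
        seq = rng.standard_normal(1000)
        rep = gelman_rubin(self._fake(np.stack([seq, seq, seq])))
        assert rep.rhat["mu0"] <= 1.02
        assert rep.passed

    def test_two_mode_chains_fail(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.standard_normal(1000),
                           rng.standard_normal(1000) + 10.0])
        rep = gelman_rubin(self._fake(chains))
        assert rep.rhat["mu0"] > 1.02
        assert not rep.passed

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._fake(np.zeros((1, 100))))

    def test_rank_normalised_variant(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.standard_normal(500),
                           rng.standard_normal(500) + 10.0])
        rep = gelman_rubin(self._fake(chains), ModelConfig(rhat_method="rank"))
        assert rep.rhat["mu0"] > 1.02


class TestFitWithRetries:
    def test_converges_quickly_on_well_specified_data(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        _, rep = fit_with_retries(d, initial_values(d), ModelConfig(seed=3))
        assert rep.passed
        assert rep.retries_used <= 2

    def test_zero_retry_budget_hard_failure(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        # coverage demand no sampler can meet under threshold barely above 1
        cfg = ModelConfig(n_samples=120, n_warmup=20, max_retries=0,
                          rhat_threshold=1.0000001, seed=4)
        with pytest.raises(ConvergenceError):
            fit_with_retries(d, initial_values(d), cfg)


class TestDestandardise:
    def test_identity_when_already_unit(self, micro_data):
        init = initial_values(micro_data)
        s = sample_posterior(micro_data, init,
                             ModelConfig(n_samples=200, n_warmup=50, seed=0))
        out = destandardise(s, micro_data)  # mean 0, var 1 stored
        assert np.array_equal(out.mu0, s.mu0)
        assert np.array_equal(out.sigma_r, s.sigma_r)

    def test_scale_and_shift(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        s = sample_posterior(d, initial_values(d),
                             ModelConfig(n_samples=300, n_warmup=100, seed=0))
        out = destandardise(s, d)
        sd1 = np.sqrt(d.baseline1_var)
        assert np.allclose(out.sigma_r, s.sigma_r * sd1)
        assert np.allclose(out.mu0, s.mu0 * sd1 + d.baseline1_mean)
        # epsilon is a difference: rescaled but not shifted
        assert np.allclose(out.epsilon, s.epsilon * sd1)

    def test_double_inversion_rejected(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        s = sample_posterior(d, initial_values(d),
                             ModelConfig(n_samples=200, n_warmup=50, seed=0))
        out = destandardise(s, d)
        with pytest.raises(ValueError):
            destandardise(out, d)

    def test_recovery_of_generating_mean(self, recovery_cohort):
        d = standardise(recovery_cohort, "feature")
        s, _ = fit_with_retries(d, initial_values(d), ModelConfig(seed=6))
        out = destandardise(s, d)
        mu0 = np.median(out.flat("mu0"))
        lo, hi = np.quantile(out.flat("mu0"), [0.005, 0.995])
        assert lo < 2.0 < hi, (mu0, lo, hi)

    def test_posterior_export_dataframe(self, micro_data):
        s = sample_posterior(micro_data, initial_values(micro_data),
                             ModelConfig(n_samples=150, n_warmup=50, seed=0))
        df = s.to_dataframe()
        # 5 globals + 2 patients + 3 lesions, 3 chains x 100 draws
        assert len(df) == 10 * 3 * 100
        assert set(df.columns) == {"chain", "draw", "parameter", "value"}
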