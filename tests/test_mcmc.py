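import math

import numpy as np
import pytest

from hiertx.kinetics import CellTimeSeries
from hiertx.mcmc import (
    McmcConfig,
    PARAM_NAMES,
    _PsiState,
    _gibbs_mu,
    initialize_state,
    propose_log_perturbation,
    run_mcmc,
    update_hyperparams,
)

FIXED = {"delta_M": 0.2, "delta_P": 0.05, "kappa": 1.0}


def small_config(**kw):
    base = dict(n_iterations=600, burn_in=200, thin=2, seed=0)
    base.update(kw)
    return McmcConfig(**base)


class TestProposals:
    def test_tiny_scale_is_identity(self):
        rng = np.random.default_rng(0)
        theta = np.array([1.0, 2.0, 3.0])
        prop, jac = propose_log_perturbation(theta, [1e-300] * 3, rng)
        assert np.allclose(prop, theta)
        assert jac == pytest.approx(0.0, abs=1e-290)

    def test_jacobian_antisymmetry(self):
        rng = np.random.default_rng(1)
        theta = np.array([0.5, 4.0])
        prop, jac = propose_log_perturbation(theta, [0.3, 0.3], rng)
        back_jac = float(np.sum(np.log(theta) - np.log(prop)))
        assert back_jac == pytest.approx(-jac, rel=1e-12)

    def test_log_scale_sampling_oracle(self):
        rng = np.random.default_rng(2)
        logs = []
        for _ in range(10**5):
            prop, _ = propose_log_perturbation([1.0], [0.1], rng)
            logs.append(math.log(prop[0]))
        logs = np.array(logs)
        assert logs.mean() == pytest.approx(0.0, abs=0.002)
        assert logs.std() == pytest.approx(0.1, rel=0.02)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            propose_log_perturbation([0.0], [0.1], np.random.default_rng(0))


class TestHyperUpdates:
    def test_gibbs_mu_matches_closed_form_posterior(self):
        """With sigma known, the mu draw follows the conjugate normal
        posterior: check first two moments over repeated draws."""
        rng = np.random.default_rng(3)
        x = rng.normal(1.7, 0.5, size=200)
        sigma = 0.5
        prec = len(x) / sigma**2 + 1.0 / 100.0
        post_mean = (x.sum() / sigma**2) / prec
        post_sd = 1.0 / math.sqrt(prec)
        draws = np.array([_gibbs_mu(x, sigma, rng) for _ in range(4000)])
        assert draws.mean() == pytest.approx(post_mean, abs=4 * post_sd / 60)
        assert draws.std() == pytest.approx(post_sd, rel=0.1)

    def test_lognormal_location_recovery_oracle(self):
        """With many cells' on-rates fixed at known lognormal draws, the
        location hyperparameter concentrates on the true mu."""
        rng = np.random.default_rng(4)
        n = 10**4
        true_mu, true_sig = 0.8, 0.4
        theta = np.ones((n, 6))
        theta[:, PARAM_NAMES.index("tau_on")] = rng.lognormal(true_mu, true_sig, n)
        theta[:, PARAM_NAMES.index("tau_off")] = rng.lognormal(-2.0, 0.5, n)
        theta[:, PARAM_NAMES.index("alpha")] = rng.lognormal(0.5, 0.3, n)
        theta[:, PARAM_NAMES.index("sigma_eps2")] = 1.0 / rng.gamma(2.0, 1.0 / 900.0, n)
        theta[:, PARAM_NAMES.index("copy_number")] = rng.poisson(3.0, n) + 1.0
        psi = _PsiState(["A"], [0.0], [1.0], [-2.0], [0.5], 0.5, 0.3,
                        2.0, 1800.0, 3.0)
        cfg = small_config()
        group_idx = np.zeros(n, dtype=np.int64)
        mus = []
        for _ in range(300):
            update_hyperparams(theta, group_idx, psi, cfg, rng)
            mus.append(psi.mu_on[0])
        mus = np.array(mus[100:])
        post_sd = true_sig / math.sqrt(n)
        assert abs(mus.mean() - true_mu) < 3 * post_sd + 0.01
        assert abs(psi.sig_on[0] - true_sig) < 0.05

    def test_copy_lambda_update_recovers_rate_when_enabled(self):
        """When the copy counts are held fixed (identified case), the lambda
        MH update concentrates near the truth."""
        rng = np.random.default_rng(5)
        n = 5000
        theta = np.ones((n, 6))
        theta[:, PARAM_NAMES.index("tau_on")] = 1.0
        theta[:, PARAM_NAMES.index("copy_number")] = np.maximum(
            rng.poisson(5.0, n), 1)
        theta[:, PARAM_NAMES.index("sigma_eps2")] = 1.0
        psi = _PsiState(["A"], [0.0], [1.0], [0.0], [1.0], 0.0, 1.0,
                        2.0, 2.0, 1.5)
        cfg = small_config(update_copy_lambda=True)
        group_idx = np.zeros(n, dtype=np.int64)
        lams = []
        for _ in range(400):
            update_hyperparams(theta, group_idx, psi, cfg, rng)
            lams.append(psi.copy_lambda)
        assert np.mean(lams[200:]) == pytest.approx(5.0, rel=0.1)

    def test_copy_lambda_frozen_by_default(self):
        rng = np.random.default_rng(6)
        theta = np.abs(np.ones((10, 6)))
        theta[:, PARAM_NAMES.index("copy_number")] = 4.0
        psi = _PsiState(["A"], [0.0], [1.0], [0.0], [1.0], 0.0, 1.0,
                        2.0, 2.0, 3.0)
        group_idx = np.zeros(10, dtype=np.int64)
        for _ in range(20):
            update_hyperparams(theta, group_idx, psi, small_config(), rng)
        assert psi.copy_lambda == 3.0


class TestRunMcmc:
    def test_same_seed_bit_identical(self, tiny_benchmark):
        cfg = small_config(n_iterations=120, burn_in=40)
        a = run_mcmc(tiny_benchmark.dataset, FIXED, cfg)
        b = run_mcmc(tiny_benchmark.dataset, FIXED, cfg)
        assert np.array_equal(a.cell_samples, b.cell_samples)
        assert np.array_equal(a.hyper_samples, b.hyper_samples)
        assert a.acceptance == b.acceptance

    def test_sample_count_bookkeeping(self, tiny_benchmark):
        cfg = small_config(n_iterations=500, burn_in=100, thin=4)
        ch = run_mcmc(tiny_benchmark.dataset, FIXED, cfg)
        assert ch.n_kept == 100
        assert ch.cell_samples.shape == (100, 9, 6)
        assert ch.loglik_trace.shape == (100, 9)

    def test_samples_stay_in_support(self, tiny_benchmark):
        ch = run_mcmc(tiny_benchmark.dataset, FIXED, small_config())
        pos = ch.cell_samples[:, :, [0, 1, 3, 4, 5]]
        assert np.all(pos > 0)
        s = ch.cell_samples[:, :, 2]
        times = tiny_benchmark.spec.obs_times
        assert np.all((s >= times[0]) & (s <= times[-1]))

    def test_standard_mode_never_touches_psi(self, tiny_benchmark):
        ch = run_mcmc(tiny_benchmark.dataset, FIXED, small_config(mode="standard"))
        assert np.all(ch.hyper_samples == ch.hyper_samples[0])

    def test_hierarchical_mode_moves_psi(self, tiny_benchmark):
        ch = run_mcmc(tiny_benchmark.dataset, FIXED, small_config())
        assert ch.hyper_samples.std(axis=0).max() > 0

    def test_missing_fixed_constant_raises(self, tiny_benchmark):
        with pytest.raises(ValueError):
            run_mcmc(tiny_benchmark.dataset, {"delta_M": 0.1}, small_config())

    @staticmethod
    def _toy():
        from hiertx.simulate import PopulationSpec, make_benchmark

        spec = PopulationSpec(n_cells_per_group={"A": 3},
                              group_tau_on_means={"A": 8.0})
        return make_benchmark(spec, seed=3)

    @staticmethod
    def _ln_amplitude(ch):
        """Posterior mean of ln(c·tau_on·alpha), the signal-amplitude product
        the data identify sharply (c·tau alone is ridge-diffuse without the
        hierarchy, so its mean is a poor convergence probe)."""
        return np.log(
            ch.cell_samples[:, :, PARAM_NAMES.index("copy_number")]
            * ch.cell_samples[:, :, PARAM_NAMES.index("tau_on")]
            * ch.cell_samples[:, :, PARAM_NAMES.index("alpha")]
        ).mean(axis=0)

    def test_acceptance_styles_target_same_posterior(self):
        """per_cell and joint_block acceptance agree on posterior means
        (3-cell toy, long runs; standard mode isolates the cell-update
        machinery)."""
        b = self._toy()
        res = {}
        for style in ("per_cell", "joint_block"):
            cfg = McmcConfig(n_iterations=12000, burn_in=4000, thin=4,
                             acceptance_style=style, seed=9, mode="standard")
            res[style] = self._ln_amplitude(run_mcmc(b.dataset, FIXED, cfg))
        assert np.allclose(res["per_cell"], res["joint_block"], atol=0.05)

    def test_block_size_does_not_change_target(self):
        """block_size 1 (round-robin) and block_size = n sample the same
        posterior (3-cell toy)."""
        b = self._toy()
        res = {}
        for bs, iters in ((1, 36000), (None, 12000)):
            cfg = McmcConfig(n_iterations=iters, burn_in=iters // 3, thin=4,
                             block_size=bs, seed=10, mode="standard")
            res[bs] = self._ln_amplitude(run_mcmc(b.dataset, FIXED, cfg))
        assert np.allclose(res[1], res[None], atol=0.05)


class TestInitialization:
    def test_deterministic_given_seed(self, tiny_benchmark):
        cfg = small_config()
        a = initialize_state(tiny_benchmark.dataset, cfg,
                             np.random.default_rng(3), FIXED)
        b = initialize_state(tiny_benchmark.dataset, cfg,
                             np.random.default_rng(3), FIXED)
        assert np.array_equal(a[0], b[0])

    def test_start_inside_prior_support(self, tiny_benchmark):
        theta, group_idx, groups, psi = initialize_state(
            tiny_benchmark.dataset, small_config(), np.random.default_rng(4),
            FIXED)
        assert np.all(theta[:, [0, 1, 3, 4, 5]] > 0)
        for i, ts in enumerate(tiny_benchmark.dataset):
            assert ts.times[0] <= theta[i, 2] <= ts.times[-1]

    def test_noiseless_ramp_switch_detection(self):
        """A flat-then-ramp signal starts the switch estimate within one
        frame of the ramp onset."""
        times = np.arange(0.0, 30.0)
        y = np.where(times < 12.0, 0.0, (times - 12.0) * 50.0)
        ts = CellTimeSeries("r", "A", times, y)
        theta, *_ = initialize_state([ts], small_config(),
                                     np.random.default_rng(5), FIXED)
        assert abs(theta[0, 2] - 12.0) <= 1.5

    def test_constant_signal_warns_and_uses_midpoint(self):
        times = np.arange(0.0, 20.0)
        ts = CellTimeSeries("flat", "A", times, np.full(len(times), 5.0))
        with pytest.warns(UserWarning):
            theta, *_ = initialize_state([ts], small_config(),
                                         np.random.default_rng(6), FIXED)
        assert theta[0, 2] == pytest.approx(9.5, abs=0.5)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(burn_in=600, n_iterations=600),
        dict(thin=0),
        dict(block_size=0),
        dict(mode="bayes"),
        dict(acceptance_style="metropolis"),
        dict(params_per_cell_proposal=7),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            McmcConfig(**kw)
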