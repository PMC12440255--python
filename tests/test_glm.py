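"""Design construction, AR-IRLS fitting, bin averaging, contrasts, FDR."""

import warnings

import numpy as np
import pytest
from scipy import signal as sps, stats

from nidot import glm, synth
from nidot.containers import EXPECTED, UNEXPECTED
from nidot.glm import DesignMatrix


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        assert glm.canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_peak_time_on_fine_grid(self):
        t = np.arange(0, 12, 0.01)
        h = glm.canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(4.00, abs=0.005)
        assert h.max() == pytest.approx(1.0)

    def test_default_peak_parameter(self):
        import inspect

        assert inspect.signature(glm.canonical_hrf).parameters["peak_s"].default == 4.0


class TestBuildDesign:
    def test_fir_column_count(self):
        """2 conditions x 28 bins + modulator + intercept + drift = 59."""
        s = synth.generate_trial_schedule(27, seed=1)
        d = glm.build_design(s, np.full(27, 0.5), basis="fir", rate_hz=4.0)
        assert d.n_regressors == 59
        assert d.names.count("modulator") == 1
        for cond in (EXPECTED, UNEXPECTED):
            assert sum(n.startswith(cond + ":") for n in d.names) == 28

    def test_constant_dtr_collinearity_warning(self):
        """Equal scaled DTRs make the modulator a multiple of the summed
        canonical condition regressors; must warn."""
        s = synth.generate_trial_schedule(20, seed=2)
        with pytest.warns(UserWarning, match="collinear"):
            glm.build_design(s, np.full(20, 0.5), basis="canonical", rate_hz=4.0)

    def test_missing_dtr_trials_excluded(self):
        s = synth.generate_trial_schedule(10, seed=3)
        dtr = np.full(10, 0.8)
        dtr[[2, 5]] = np.nan
        d = glm.build_design(s, dtr, basis="fir", rate_hz=4.0)
        first_bins = [d.X[:, d.bin_map[(c, 1)]].sum() for c in (EXPECTED, UNEXPECTED)]
        assert sum(first_bins) == 8  # one impulse per usable trial

    def test_all_missing_rejected(self):
        s = synth.generate_trial_schedule(5, seed=4)
        with pytest.raises(ValueError):
            glm.build_design(s, np.full(5, np.nan), rate_hz=4.0)

    def test_deterministic_and_stable_order(self):
        s = synth.generate_trial_schedule(15, seed=5)
        d1 = glm.build_design(s, np.full(15, 0.7), rate_hz=4.0)
        d2 = glm.build_design(s, np.full(15, 0.7), rate_hz=4.0)
        assert d1.names == d2.names
        np.testing.assert_array_equal(d1.X, d2.X)


def random_design(rng, n=80, p=4):
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    names = [f"c{i}" for i in range(p)]
    return DesignMatrix(X=X, names=names, rate_hz=4.0, basis="canonical")


class TestARIRLS:
    def test_order_zero_identity_weights_equals_ols(self):
        """Least-squares mode with no whitening reproduces the
        normal-equations solution on 100 random small designs."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = random_design(rng)
            beta_true = rng.normal(size=4)
            y = d.X @ beta_true + rng.normal(0, 0.5, d.X.shape[0])
            fit = glm.ar_irls_fit(y, d, max_ar_order=0, robust=False)
            ols = np.linalg.solve(d.X.T @ d.X, d.X.T @ y)
            assert np.max(np.abs(fit.beta - ols)) < 1e-6

    def test_yule_walker_recovers_ar1_coefficient(self):
        rng = np.random.default_rng(1)
        d = random_design(rng, n=2000)
        noise = sps.lfilter([1.0], [1.0, -0.6], rng.normal(0, 1, 2000))
        y = d.X @ np.array([1.0, 0.5, -0.3, 0.2]) + noise
        fit = glm.ar_irls_fit(y, d, max_ar_order=4)
        assert fit.ar_order >= 1
        assert fit.ar_coeffs[0] == pytest.approx(0.6, abs=0.1)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
        d = DesignMatrix(X=X, names=["intercept", "a", "dup_a"], rate_hz=4.0)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            glm.ar_irls_fit(rng.normal(size=50), d, max_ar_order=0)

    def test_too_short_series_rejected(self):
        d = random_design(np.random.default_rng(3), n=10)
        with pytest.raises(ValueError):
            glm.ar_irls_fit(np.zeros(10), d, max_ar_order=8)

    def test_robust_fit_downweights_spikes(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, n=400)
        beta_true = np.array([0.0, 1.0, 0.0, 0.0])
        y = d.X @ beta_true + rng.normal(0, 0.1, 400)
        y[::37] += 5.0
        fit = glm.ar_irls_fit(y, d, max_ar_order=0)
        assert fit.beta[1] == pytest.approx(1.0, abs=0.05)
        assert fit.weights.min() < 0.05  # spikes effectively rejected


class TestAverageBins:
    def fir_fit(self, betas_by_cond, rate=4.0, n_bins=28):
        names, bin_map, beta = [], {}, []
        for cond in (EXPECTED, UNEXPECTED):
            for b in range(1, n_bins + 1):
                bin_map[(cond, b)] = len(names)
                names.append(f"{cond}:bin{b:02d}")
                beta.append(betas_by_cond[cond][b - 1])
        beta = np.array(beta)
        return glm.GLMFit(
            beta=beta, cov=np.eye(len(beta)) * 0.01, names=names, dof=100.0,
            ar_order=0, ar_coeffs=np.array([]), weights=np.ones(10),
            residuals=np.zeros(10), converged=True, basis="fir",
            bin_map=bin_map, rate_hz=rate,
        )

    def test_constant_bins_average_to_constant(self):
        fit = self.fir_fit({EXPECTED: np.full(28, 0.4), UNEXPECTED: np.full(28, 0.9)})
        s = glm.average_bins(fit)
        assert s.estimates[EXPECTED] == pytest.approx(0.4)
        assert s.estimates[UNEXPECTED] == pytest.approx(0.9)

    def test_labeled_window_starts_at_three_seconds(self):
        assert glm.bins_to_window(12, 24, 4.0) == (3.0, 6.0)
        fit = self.fir_fit({EXPECTED: np.arange(28.0), UNEXPECTED: np.arange(28.0)})
        s = glm.average_bins(fit, 12, 24)
        assert s.window_s == (3.0, 6.0)
        assert s.estimates[EXPECTED] == pytest.approx(np.mean(np.arange(12, 24)))

    def test_canonical_fit_rejected(self):
        fit = self.fir_fit({EXPECTED: np.zeros(28), UNEXPECTED: np.zeros(28)})
        fit.basis = "canonical"
        with pytest.raises(ValueError):
            glm.average_bins(fit)


class TestContrast:
    def test_equal_betas_give_zero(self):
        fit = TestAverageBins().fir_fit({EXPECTED: np.full(28, 0.5), UNEXPECTED: np.full(28, 0.5)})
        s = glm.average_bins(fit)
        c = glm.contrast(s, {UNEXPECTED: 1.0, EXPECTED: -1.0}, label="U-E")
        assert c.estimate == pytest.approx(0.0, abs=1e-12)
        assert c.t == pytest.approx(0.0, abs=1e-9)

    def test_unknown_label_rejected(self):
        fit = TestAverageBins().fir_fit({EXPECTED: np.zeros(28), UNEXPECTED: np.zeros(28)})
        with pytest.raises(KeyError):
            glm.contrast(glm.average_bins(fit), {"surprise": 1.0})

    def test_recovers_planted_difference_with_valid_ci(self):
        """U-E contrast covers the planted difference at ~95% over sims."""
        rng = np.random.default_rng(5)
        s = synth.generate_trial_schedule(27, seed=6)
        d = glm.build_design(s, np.linspace(0.3, 0.9, 27), basis="canonical", rate_hz=4.0)
        iU, iE = d.names.index(UNEXPECTED), d.names.index(EXPECTED)
        planted = 0.3
        cover = 0
        n_sim = 120
        for _ in range(n_sim):
            beta = np.zeros(d.n_regressors)
            beta[iE], beta[iU] = 0.2, 0.2 + planted
            y = d.X @ beta + rng.normal(0, 0.3, d.X.shape[0])
            fit = glm.ar_irls_fit(y, d, max_ar_order=0, robust=False)
            c = glm.contrast(fit, {UNEXPECTED: 1.0, EXPECTED: -1.0})
            tcrit = stats.t.ppf(0.975, c.dof)
            cover += abs(c.estimate - planted) <= tcrit * c.se
        assert 0.90 <= cover / n_sim <= 0.99


class TestFDR:
    def test_step_up_worked_example(self):
        p_adj, reject = glm.fdr_bh([0.001, 0.01, 0.02, 0.03, 0.5], q=0.05)
        np.testing.assert_allclose(p_adj, [0.005, 0.025, 1 / 30, 0.0375, 0.5], atol=1e-10)
        assert reject.sum() == 4

    def test_all_ones_no_rejections(self):
        _, reject = glm.fdr_bh([1.0] * 6)
        assert not reject.any()

    def test_empty_input(self):
        p_adj, reject = glm.fdr_bh([])
        assert p_adj.size == 0 and reject.size == 0

    def test_matches_brute_force_step_up(self, rng):
        def brute(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(50):
            p = rng.random(rng.integers(1, 15))
            ours, _ = glm.fdr_bh(p)
            np.testing.assert_allclose(ours, brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            glm.fdr_bh([0.5, 1.5])


class TestEngagementMasking:
    def test_true_contrast_masked_without_modulator(self, single_pair_probe):
        """With unequal gains and lower engagement on unexpected trials, the
        naive contrast underestimates the planted difference; modeling
        engagement moves the estimate toward it (the qualitative pattern that
        condition effects emerge only when engagement is modeled)."""
        import nidot.preprocess as preprocess
        from nidot import gaze

        noise = synth.NoiseConfig(white_sd=5e-4, ar1_phi=0.5, drift_amp=0.0, cardiac_amp=0.0)
        naive, modeled = [], []
        used = rep = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            while used < 60:
                rep += 1
                s = synth.generate_trial_schedule(27, seed=rep)
                if min(s.counts().values()) < 3:
                    continue
                t = synth.make_ground_truth(
                    s, seed=rep + 50_000, attention_coupling=0.4,
                    beta_expected=0.3, beta_unexpected=0.7,
                )
                ts, _ = synth.generate_channel_data(
                    s, t, single_pair_probe, noise_cfg=noise, seed=rep + 60_000, rate_hz=4.0
                )
                hb = preprocess.mbll(ts)
                rng = np.random.default_rng(rep + 70_000)
                meas = rng.binomial(255, t.dtr_true) / 255
                scaled = gaze.scale_dtr(meas)
                dm = glm.build_design(s, scaled, basis="canonical", rate_hz=4.0, n_times=hb.n_times)
                dn = glm.build_design(
                    s, scaled, basis="canonical", rate_hz=4.0, n_times=hb.n_times, include_modulator=False
                )
                fm = glm.ar_irls_fit(hb.data[0], dm, max_ar_order=1)
                fn = glm.ar_irls_fit(hb.data[0], dn, max_ar_order=1)
                modeled.append(fm[UNEXPECTED] - fm[EXPECTED])
                naive.append(fn[UNEXPECTED] - fn[EXPECTED])
                used += 1
        planted = 0.7 - 0.3
        err_naive = abs(np.mean(naive) - planted)
        err_modeled = abs(np.mean(modeled) - planted)
        assert np.mean(naive) < planted  # attenuated toward null
        assert err_modeled < err_naive  # engagement model recovers more
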