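"""Kinetic model simulation and least-squares parameter recovery."""

import numpy as np
import pytest

import shellfield as sf
from shellfield.kinetics import KineticModel, log_spaced_delays, model_curve

MONO = KineticModel("mono_decay_offset")
RISE = KineticModel("biphasic_rise")
DPR = KineticModel("decay_plus_rise")

SHORT = np.linspace(0.2, 8.0, 60)
LONG = log_spaced_delays(0.2, 100.0, 80)


class TestSimulate:
    def test_zero_noise_returns_exact_curve(self):
        params = {"amplitude": -2.0, "tau": 1.0, "offset": -0.1}
        tr = sf.simulate_transient(MONO, params, SHORT, 0.0)
        np.testing.assert_array_equal(tr.delta_a, model_curve(MONO, params, SHORT))

    def test_same_seed_identical(self):
        params = {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}
        a = sf.simulate_transient(RISE, params, LONG, 0.03, seed=4)
        b = sf.simulate_transient(RISE, params, LONG, 0.03, seed=4)
        np.testing.assert_array_equal(a.delta_a, b.delta_a)

    def test_replicate_mean_converges_to_model(self):
        params = {"amplitude": -2.0, "tau": 1.5, "offset": -0.1}
        sigma, n = 0.03, 1000
        stack = np.array([
            sf.simulate_transient(MONO, params, SHORT, sigma, seed=s).delta_a
            for s in range(n)
        ])
        se = sigma / np.sqrt(n)
        # 4σ bound: with 60 delay points the family-wise false-alarm
        # probability stays below ~0.4%
        np.testing.assert_array_less(
            np.abs(stack.mean(axis=0) - model_curve(MONO, params, SHORT)), 4.0 * se
        )

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            sf.simulate_transient(MONO, {"amplitude": 1, "tau": -1, "offset": 0}, SHORT)

    def test_irf_convolution_matches_numeric_convolution(self):
        """Analytic Gaussian-IRF decay equals brute-force numerical
        convolution of the causal exponential with the Gaussian."""
        tau, fwhm = 1.5, 0.3
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        model = KineticModel("mono_decay_offset", irf_fwhm=fwhm)
        t = np.linspace(-1, 6, 50)
        analytic = model_curve(model, {"amplitude": 1.0, "tau": tau, "offset": 0.0}, t)
        dt = 2.5e-4
        tt = np.arange(-8, 12, dt)
        causal = np.where(tt >= 0, np.exp(-np.clip(tt, 0, None) / tau), 0.0)
        tk = np.arange(-6 * sigma, 6 * sigma + dt / 2, dt)  # symmetric, odd length
        kernel = np.exp(-0.5 * (tk / sigma) ** 2)
        kernel /= kernel.sum()
        numeric = np.convolve(causal, kernel, mode="same")
        interp = np.interp(t, tt, numeric)
        np.testing.assert_allclose(analytic, interp, atol=2e-4)


class TestTraceValidation:
    def test_non_increasing_delays_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sf.TransientTrace([0.2, 0.2, 0.5], [0, 0, 0])

    def test_too_few_points_rejected_at_fit_time(self):
        tr = sf.TransientTrace([0.2, 0.5, 1.0], [1.0, 0.5, 0.2])
        with pytest.raises(ValueError, match="8 points"):
            sf.fit_monoexponential(tr)


class TestMonoexponentialFit:
    def test_noiseless_recovery(self):
        params = {"amplitude": -2.0, "tau": 1.5, "offset": -0.1}
        fit = sf.fit_monoexponential(sf.simulate_transient(MONO, params, SHORT))
        assert fit.converged
        for k, v in params.items():
            assert fit.params[k] == pytest.approx(v, abs=1e-6)

    def test_error_estimate_calibrated_by_monte_carlo(self):
        """Empirical scatter of τ̂ across seeded replicates matches the
        mean covariance-based 1σ within 30%."""
        params = {"amplitude": -2.0, "tau": 1.0, "offset": -0.1}
        taus, sigmas = [], []
        for s in range(200):
            tr = sf.simulate_transient(MONO, params, SHORT, 0.03, seed=10_000 + s)
            fit = sf.fit_monoexponential(tr)
            taus.append(fit.params["tau"])
            sigmas.append(fit.stderr["tau"])
        emp = np.std(taus, ddof=1)
        rep = np.mean(sigmas)
        assert abs(emp - rep) / rep < 0.30

    def test_gauge_invariance_under_amplitude_rescaling(self):
        params = {"amplitude": -2.0, "tau": 1.3, "offset": -0.1}
        tr = sf.simulate_transient(MONO, params, SHORT, 0.03, seed=3)
        fit1 = sf.fit_monoexponential(tr)
        scaled = sf.TransientTrace(tr.delays, 10.0 * tr.delta_a)
        fit2 = sf.fit_monoexponential(scaled)
        assert fit2.params["tau"] == pytest.approx(fit1.params["tau"], rel=1e-6)
        assert fit2.params["amplitude"] == pytest.approx(
            10 * fit1.params["amplitude"], rel=1e-6
        )


class TestBiphasicFit:
    def test_noiseless_recovery(self):
        params = {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}
        fit = sf.fit_biphasic(sf.simulate_transient(RISE, params, LONG))
        for k, v in params.items():
            assert fit.params[k] == pytest.approx(v, abs=1e-4)

    @pytest.mark.parametrize("form,params", [
        ("biphasic_rise", {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}),
        ("decay_plus_rise", {"a1": -1.5, "tau1": 1.1, "a2": -0.5, "tau2": 17.0}),
        ("mono_decay_offset", {"amplitude": -2.0, "tau": 1.0, "offset": -0.1}),
    ])
    def test_noiseless_recovery_from_perturbed_guesses(self, form, params):
        """±50% perturbed initial guesses still recover noiseless data to
        at least 6 significant figures."""
        model = KineticModel(form)
        delays = SHORT if form == "mono_decay_offset" else LONG
        tr = sf.simulate_transient(model, params, delays)
        rng = np.random.default_rng(1)
        p0 = {k: v * (1 + rng.uniform(-0.5, 0.5)) for k, v in params.items()}
        if form == "mono_decay_offset":
            fit = sf.fit_monoexponential(tr, p0=p0)
        else:
            fit = sf.fit_biphasic(tr, form, p0=p0)
        for k, v in params.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-6, abs=1e-6)

    def test_tau_ordering_enforced(self):
        params = {"a1": 0.4, "tau1": 11.0, "a2": 1.2, "tau2": 1.1}  # reversed
        fit = sf.fit_biphasic(sf.simulate_transient(RISE, params, LONG, 0.03, seed=0))
        assert fit.params["tau1"] < fit.params["tau2"]

    def test_degenerate_taus_flagged_ill_conditioned(self):
        params = {"a1": 0.6, "tau1": 5.0, "a2": 0.6, "tau2": 5.2}
        fit = sf.fit_biphasic(sf.simulate_transient(RISE, params, LONG, 0.02, seed=2))
        assert fit.ill_conditioned

    def test_nested_model_consistency(self):
        """decay_plus_rise with A₂ = 0 reduces to the mono-exponential fit
        (compared on the same decay-to-zero data within 1σ)."""
        params = {"a1": -1.5, "tau1": 1.1, "a2": 0.0, "tau2": 10.0}
        tr = sf.simulate_transient(DPR, params, LONG, 0.03, seed=6)
        biph = sf.fit_biphasic(tr, "decay_plus_rise")
        mono = sf.fit_monoexponential(tr)
        err = max(mono.stderr["tau"], 1e-3)
        assert abs(biph.params["tau1"] - mono.params["tau"]) < max(3 * err, 0.1)

    def test_water_control_does_not_hallucinate_slow_rise(self):
        """Neat-water-like traces (pure 1.1 ps decay to a residual, no
        slow component) must not yield a slow amplitude beyond 3σ."""
        params = {"a1": 1.5, "tau1": 1.1, "a2": 0.0, "tau2": 15.0}
        for s in range(5):
            tr = sf.simulate_transient(DPR, params, LONG, 0.03, seed=100 + s)
            fit = sf.fit_biphasic(tr, "decay_plus_rise")
            assert abs(fit.params["a2"]) < 3 * fit.stderr["a2"] + 0.02


class TestGlobalFit:
    def test_identical_noiseless_traces_match_single_fit(self):
        params = {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}
        tr = sf.simulate_transient(RISE, params, LONG)
        res = sf.global_fit([tr, tr], "biphasic_rise", shared=("tau1", "tau2"))
        single = sf.fit_biphasic(tr)
        assert res.shared["tau1"] == pytest.approx(single.params["tau1"], abs=1e-6)
        assert res.shared["tau2"] == pytest.approx(single.params["tau2"], abs=1e-6)

    def test_pooling_reduces_slow_constant_variance(self):
        """Sharing τ₂ across four traces estimates it with less scatter
        than per-trace fits on the same data."""
        fasts = [0.9, 1.033, 1.167, 1.3]
        shared_est, single_est = [], []
        for rep in range(30):
            traces = [
                sf.simulate_transient(
                    RISE, {"a1": 1.2, "tau1": t1, "a2": 0.4, "tau2": 17.0},
                    LONG, 0.03, seed=500 + 10 * rep + i,
                )
                for i, t1 in enumerate(fasts)
            ]
            g = sf.global_fit(traces, "biphasic_rise", shared=("tau2",))
            shared_est.append(g.shared["tau2"])
            single_est.extend(sf.fit_biphasic(t).params["tau2"] for t in traces)
        assert np.var(shared_est, ddof=1) < np.var(single_est, ddof=1)

    def test_mixed_delay_grids_allowed(self):
        params = {"a1": 1.2, "tau1": 1.1, "a2": 0.4, "tau2": 11.0}
        tr1 = sf.simulate_transient(RISE, params, LONG, 0.03, seed=1)
        tr2 = sf.simulate_transient(RISE, params, log_spaced_delays(0.3, 80, 50),
                                    0.03, seed=2)
        res = sf.global_fit([tr1, tr2], "biphasic_rise", shared=("tau2",))
        assert res.converged
        assert len(res.per_trace) == 2

    def test_empty_trace_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.global_fit([], "biphasic_rise")
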