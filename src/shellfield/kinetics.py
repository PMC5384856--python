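"""Pump-probe kinetic models: simulation and least-squares fitting.

Transient absorbance changes ΔA(t) (mOD vs. delay in ps) at a fixed
probe frequency are described by three model forms:

``mono_decay_offset``
    A·exp(−t/τ) + C — bleach recovery after direct excitation of a
    backbone mode (population decay of v = 1 to a residual offset).
``biphasic_rise``
    A₁·(1−exp(−t/τ₁)) + A₂·(1−exp(−t/τ₂)) — response after OH-stretch
    excitation of the water shell: a fast ~1 ps rise tracking the
    formation of the hot water ground state, and a slow rise on tens of
    picoseconds from energy flow into the helix.
``decay_plus_rise``
    A₁·exp(−t/τ₁) + A₂·(1−exp(−t/τ₂)) — traces that start with a fast
    decay (e.g. the neat-water response, where A₂ = 0).

An optional Gaussian instrument response (FWHM in ps) can be convolved
analytically with every exponential term; it is off by default since the
fit window normally starts after the coherent-artifact region (0.2 ps).

Fitting uses scipy.optimize.least_squares; 1σ uncertainties come from
the Jacobian-based covariance scaled by the residual variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc

__all__ = [
    "TransientTrace",
    "KineticModel",
    "FitResult",
    "GlobalFitResult",
    "model_curve",
    "simulate_transient",
    "fit_monoexponential",
    "fit_biphasic",
    "global_fit",
    "log_spaced_delays",
]

MODEL_FORMS = ("mono_decay_offset", "biphasic_rise", "decay_plus_rise")
_PARAM_NAMES = {
    "mono_decay_offset": ("amplitude", "tau", "offset"),
    "biphasic_rise": ("a1", "tau1", "a2", "tau2"),
    "decay_plus_rise": ("a1", "tau1", "a2", "tau2"),
}


@dataclass
class TransientTrace:
    """ΔA(t) at one probe frequency: delays (ps, strictly increasing),
    absorbance change (mOD), and a noise σ estimate (mOD)."""

    delays: np.ndarray
    delta_a: np.ndarray
    probe_frequency: float = float("nan")  # cm⁻¹
    noise_sigma: float = 0.0  # mOD

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.delays.shape != self.delta_a.shape:
            raise ValueError("delays and delta_a must have identical shape")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")


@dataclass(frozen=True)
class KineticModel:
    """Model form plus optional Gaussian IRF FWHM (ps, 0 = no convolution)."""

    form: str
    irf_fwhm: float = 0.0

    def __post_init__(self):
        if self.form not in MODEL_FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.irf_fwhm < 0:
            raise ValueError("IRF FWHM must be non-negative")


@dataclass
class FitResult:
    """Parameter estimates with 1σ uncertainties and fit diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    residual_rms: float  # mOD
    converged: bool
    ill_conditioned: bool = False
    model: KineticModel | None = None
    seed: int | None = None


@dataclass
class GlobalFitResult:
    """Shared time constants across traces plus per-trace amplitudes."""

    shared: dict[str, float]
    shared_stderr: dict[str, float]
    per_trace: list[dict[str, float]]
    residual_rms: float
    converged: bool


# ---------------------------------------------------------------- models


def _exp_decay(t, tau, sigma):
    """exp(−t/τ) (causal) convolved with a unit-area Gaussian of width σ."""
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    arg = sigma**2 / (2 * tau**2) - t / tau
    return 0.5 * np.exp(arg) * erfc((sigma**2 / tau - t) / (math.sqrt(2) * sigma))


def _step(t, sigma):
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        return (t >= 0).astype(float)
    return 0.5 * erfc(-t / (math.sqrt(2) * sigma))


def model_curve(model: KineticModel, params: dict[str, float], t) -> np.ndarray:
    """Evaluate a kinetic model (IRF-convolved when ``irf_fwhm`` > 0)."""
    sigma = model.irf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t = np.asarray(t, dtype=float)
    if model.form == "mono_decay_offset":
        return params["amplitude"] * _exp_decay(t, params["tau"], sigma) + params["offset"]
    if model.form == "biphasic_rise":
        return params["a1"] * (_step(t, sigma) - _exp_decay(t, params["tau1"], sigma)) + params[
            "a2"
        ] * (_step(t, sigma) - _exp_decay(t, params["tau2"], sigma))
    # decay_plus_rise
    return params["a1"] * _exp_decay(t, params["tau1"], sigma) + params["a2"] * (
        _step(t, sigma) - _exp_decay(t, params["tau2"], sigma)
    )


def log_spaced_delays(t_min: float = 0.2, t_max: float = 100.0, n: int = 80) -> np.ndarray:
    """Logarithmically spaced pump-probe delays (ps), the usual sampling
    for kinetics spanning two orders of magnitude in time."""
    return np.geomspace(t_min, t_max, n)


def simulate_transient(
    model: KineticModel,
    params: dict[str, float],
    delays,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    probe_frequency: float = float("nan"),
) -> TransientTrace:
    """Model curve plus i.i.d. Gaussian noise of the stated σ (mOD).

    With ``noise_sigma`` = 0 the exact curve is returned; a seed makes
    noisy traces bit-reproducible.  The default experimental noise floor
    is 0.03 mOD.
    """
    for tau_key in ("tau", "tau1", "tau2"):
        if tau_key in params and params[tau_key] <= 0:
            raise ValueError(f"{tau_key} must be positive")
    curve = model_curve(model, params, delays)
    if noise_sigma > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        curve = curve + rng.normal(0.0, noise_sigma, size=curve.shape)
    return TransientTrace(np.asarray(delays, dtype=float), curve, probe_frequency, noise_sigma)


# ---------------------------------------------------------------- fitting


def _check_fittable(trace: TransientTrace, n_params: int) -> None:
    if len(trace.delays) < max(8, n_params + 1):
        raise ValueError("need at least 8 points to fit a transient")


def _tau_from_tail(t, y, baseline, amplitude):
    """Log-linear regression of |y − baseline| against t (initial guess)."""
    resid = y - baseline
    mask = (np.sign(resid) == np.sign(amplitude)) & (
        np.abs(resid) > max(abs(amplitude) * 0.02, 1e-12)
    )
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(np.abs(resid[mask])), 1)[0]
        if slope < 0:
            return -1.0 / slope
    return (t[-1] - t[0]) / 3.0


def _run_least_squares(model, trace, p0_vec, names, weights=None):
    lower = np.array([1e-6 if n.startswith("tau") else -np.inf for n in names])
    upper = np.full(len(names), np.inf)
    p0_vec = np.clip(p0_vec, lower + 1e-9, None)
    w = 1.0 if weights is None else weights

    def residuals(vec):
        params = dict(zip(names, vec))
        return (model_curve(model, params, trace.delays) - trace.delta_a) * w

    res = least_squares(residuals, p0_vec, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
    n, p = len(trace.delays), len(names)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    dof = max(n - p, 1)
    sigma2 = float(np.sum(res.fun**2)) / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * sigma2
        stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(p, np.nan)
    return (
        dict(zip(names, map(float, res.x))),
        dict(zip(names, map(float, stderr))),
        rms,
        bool(res.success),
    )


def fit_monoexponential(
    trace: TransientTrace,
    model: KineticModel | None = None,
    p0: dict[str, float] | None = None,
) -> FitResult:
    """Fit A·exp(−t/τ) + C.  Non-convergence is flagged on the result,
    never raised; the residual RMS is reported either way."""
    model = model or KineticModel("mono_decay_offset")
    names = _PARAM_NAMES["mono_decay_offset"]
    _check_fittable(trace, 3)
    t, y = trace.delays, trace.delta_a
    if p0 is None:
        offset = float(np.mean(y[-max(3, len(y) // 10) :]))
        amplitude = float(y[0] - offset)
        if amplitude == 0.0:
            amplitude = float(np.ptp(y)) or 1.0
        tau = _tau_from_tail(t, y, offset, amplitude)
        p0 = {"amplitude": amplitude, "tau": tau, "offset": offset}
    params, stderr, rms, ok = _run_least_squares(
        model, trace, np.array([p0[n] for n in names]), names
    )
    return FitResult(params, stderr, rms, ok, model=model)


def fit_biphasic(
    trace: TransientTrace,
    form: str = "biphasic_rise",
    model: KineticModel | None = None,
    p0: dict[str, float] | None = None,
) -> FitResult:
    """Fit a two-component model (biphasic_rise or decay_plus_rise).

    For ``biphasic_rise`` (whose components are exchangeable) τ₁ < τ₂ is
    enforced by post-hoc reordering; if the two constants converge to
    within 10 % of each other the result is flagged ill-conditioned (the
    amplitudes are then strongly anticorrelated).
    """
    if form not in ("biphasic_rise", "decay_plus_rise"):
        raise ValueError(f"fit_biphasic does not handle form {form!r}")
    model = model or KineticModel(form)
    if model.form != form:
        raise ValueError("model form disagrees with requested form")
    names = _PARAM_NAMES[form]
    _check_fittable(trace, 4)
    t, y = trace.delays, trace.delta_a
    if p0 is None:
        y_inf = float(np.mean(y[-max(3, len(y) // 10) :]))
        if form == "biphasic_rise":
            p0 = {"a1": 0.75 * y_inf, "tau1": 1.0, "a2": 0.25 * y_inf, "tau2": t[-1] / 5.0}
        else:
            p0 = {"a1": float(y[0]), "tau1": 1.0, "a2": y_inf, "tau2": t[-1] / 5.0}
        for key in ("a1", "a2"):
            if p0[key] == 0.0:
                p0[key] = float(np.ptp(y)) or 1.0
    params, stderr, rms, ok = _run_least_squares(
        model, trace, np.array([p0[n] for n in names]), names
    )
    # the two rise components of biphasic_rise are exchangeable, so order
    # them; in decay_plus_rise the components are structurally distinct
    if form == "biphasic_rise" and params["tau1"] > params["tau2"]:
        params = {
            "a1": params["a2"], "tau1": params["tau2"],
            "a2": params["a1"], "tau2": params["tau1"],
        }
        stderr = {
            "a1": stderr["a2"], "tau1": stderr["tau2"],
            "a2": stderr["a1"], "tau2": stderr["tau1"],
        }
    ill = abs(params["tau2"] - params["tau1"]) < 0.1 * params["tau2"]
    return FitResult(params, stderr, rms, ok, ill_conditioned=ill, model=model)


def global_fit(
    traces: list[TransientTrace],
    form: str = "biphasic_rise",
    shared: tuple[str, ...] = ("tau1", "tau2"),
    irf_fwhm: float = 0.0,
) -> GlobalFitResult:
    """Simultaneous fit of several traces with shared time constants.

    ``shared`` selects which of τ₁/τ₂ are common to all traces (the
    amplitudes are always free per trace; unshared time constants are
    also per trace).  Residuals from all traces are stacked, so the
    delay grids need not match.
    """
    if not traces:
        raise ValueError("empty trace list")
    if form not in ("biphasic_rise", "decay_plus_rise"):
        raise ValueError(f"global_fit does not handle form {form!r}")
    bad = set(shared) - {"tau1", "tau2"}
    if bad:
        raise ValueError(f"cannot share {sorted(bad)}")
    model = KineticModel(form, irf_fwhm)
    names = _PARAM_NAMES[form]
    free = [n for n in names if n not in shared]

    # initial guesses from independent per-trace fits
    singles = [fit_biphasic(tr, form) for tr in traces]
    shared_names = sorted(shared)
    x0 = [float(np.mean([s.params[n] for s in singles])) for n in shared_names]
    for s in singles:
        x0.extend(s.params[n] for n in free)
    x0 = np.asarray(x0)

    n_shared = len(shared_names)
    n_free = len(free)

    def unpack(vec):
        out = []
        for k in range(len(traces)):
            p = dict(zip(shared_names, vec[:n_shared]))
            p.update(
                zip(free, vec[n_shared + k * n_free : n_shared + (k + 1) * n_free])
            )
            out.append(p)
        return out

    def residuals(vec):
        parts = [
            model_curve(model, p, tr.delays) - tr.delta_a
            for p, tr in zip(unpack(vec), traces)
        ]
        return np.concatenate(parts)

    lower = np.array(
        [1e-6 if n.startswith("tau") else -np.inf for n in shared_names]
        + [1e-6 if n.startswith("tau") else -np.inf for _ in traces for n in free]
    )
    x0 = np.clip(x0, lower + 1e-9, None)
    res = least_squares(residuals, x0, bounds=(lower, np.inf), xtol=1e-12, ftol=1e-12)

    n_pts = sum(len(tr.delays) for tr in traces)
    n_par = len(x0)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    sigma2 = float(np.sum(res.fun**2)) / max(n_pts - n_par, 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * sigma2
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        err = np.full(n_par, np.nan)
    per_trace = [
        {k: float(v) for k, v in p.items() if k in free} for p in unpack(res.x)
    ]
    return GlobalFitResult(
        shared={n: float(v) for n, v in zip(shared_names, res.x[:n_shared])},
        shared_stderr={n: float(e) for n, e in zip(shared_names, err[:n_shared])},
        per_trace=per_trace,
        residual_rms=rms,
        converged=bool(res.success),
    )
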