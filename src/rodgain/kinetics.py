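"""Gain-control kinetics from background-step protocols.

Probe flashes delivered at delays after a background step onset or offset
measure the gain timecourse; subtracting the step-only response isolates each
probe response.  The gain-versus-delay series is fit with a single
exponential

    gain(t) = asymptote + amplitude * exp(-t / tau),

by least squares with multiplicative-error weighting (sigma proportional to
the model gain), matching data whose per-delay errors scale with gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .metrics import default_baseline_window, find_response_window, gain_from_responses
from .simulate import ResponseTrace, TraceSet

__all__ = [
    "StepGainSeries",
    "ExponentialFit",
    "isolate_flash_response",
    "fit_gain_kinetics",
    "step_gain_series",
]


@dataclass(frozen=True)
class StepGainSeries:
    direction: str              # "onset" or "offset"
    probe_delays: np.ndarray    # s after the step edge, ascending
    gains: np.ndarray           # gain at each delay
    n_trials: np.ndarray

    def __post_init__(self):
        if self.direction not in ("onset", "offset"):
            raise ValueError("direction must be 'onset' or 'offset'")
        d = np.asarray(self.probe_delays, float)
        if np.any(np.diff(d) <= 0) or np.any(d < 0):
            raise ValueError("probe delays must be ascending and >= 0")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("gains must be finite")


@dataclass(frozen=True)
class ExponentialFit:
    tau: float                  # s
    asymptote: float
    amplitude: float
    stderr_tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("fitted tau must be > 0")

    def predict(self, t):
        return self.asymptote + self.amplitude * np.exp(-np.asarray(t, float) / self.tau)


def isolate_flash_response(step_plus_flash: ResponseTrace,
                           step_only: ResponseTrace) -> ResponseTrace:
    """Pointwise difference isolating the probe-flash response from a step
    trial.  Both traces must share the step protocol (same background
    segments and sampling)."""
    if step_plus_flash.samples.size != step_only.samples.size:
        raise ValueError("traces differ in length")
    if step_plus_flash.dt != step_only.dt:
        raise ValueError("traces differ in sampling rate")
    if (step_plus_flash.protocol.background_segments
            != step_only.protocol.background_segments):
        raise ValueError("traces come from different step protocols")
    return ResponseTrace(step_plus_flash.samples - step_only.samples,
                         step_plus_flash.dt, step_plus_flash.protocol,
                         step_plus_flash.trial_index,
                         step_plus_flash.ground_truth,
                         dict(step_plus_flash.labels))


def fit_gain_kinetics(series: StepGainSeries, n_grid: int = 200) -> ExponentialFit:
    """Single-exponential fit of a gain-versus-delay series.

    Least squares on linear gain with multiplicative-error weighting
    (residuals divided by the observed gain), appropriate when per-delay
    errors scale with gain.  The fit is global: tau is profiled on a log
    grid spanning [first delay / 20, 2 x delay span] — for fixed tau the
    asymptote and amplitude solve a weighted linear problem — then refined
    by bounded scalar minimization.  Requires >= 4 delays.
    """
    t = np.asarray(series.probe_delays, float)
    g = np.asarray(series.gains, float)
    if t.size < 4:
        raise ValueError("need >= 4 probe delays to fit an exponential")
    scale = np.abs(g).max()
    if scale <= 0:
        raise RuntimeError("kinetics fit impossible: all gains are zero")
    w = 1.0 / np.maximum(np.abs(g), 1e-9 * scale)

    def solve(tau):
        """Weighted linear solve for (asymptote, amplitude) at fixed tau."""
        X = np.column_stack([w, w * np.exp(-t / tau)])
        beta, *_ = np.linalg.lstsq(X, w * g, rcond=None)
        r = X @ beta - w * g
        return float(r @ r), beta

    span = t[-1] - t[0]
    grid = np.geomspace(t[0] / 20.0, 2.0 * span, n_grid)
    costs = [solve(tau)[0] for tau in grid]
    i = int(np.argmin(costs))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda x: solve(x)[0], bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-12 * span})
    tau = float(res.x)
    _, (asym, amp) = solve(tau)
    stderr = _tau_stderr(t, g, w, asym, amp, tau)
    return ExponentialFit(tau, float(asym), float(amp), stderr)


def _tau_stderr(t, g, w, asym, amp, tau) -> float:
    """Asymptotic standard error of tau from the weighted-LS covariance."""
    e = np.exp(-t / tau)
    J = np.column_stack([w, w * e, w * amp * e * t / tau ** 2])
    r = w * (asym + amp * e - g)
    dof = max(t.size - 3, 1)
    s2 = float(r @ r) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return float(np.sqrt(max(cov[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        return float("nan")


def synthetic_gain_series(direction: str, tau: float, probe_delays=None,
                          asymptote: float = 0.0, amplitude: float = 1.0,
                          noise_cv: float = 0.1,
                          rng: np.random.Generator | None = None
                          ) -> StepGainSeries:
    """A gain-change-versus-delay series drawn from a single exponential
    with multiplicative lognormal noise per point.

    The default (asymptote 0, amplitude 1) models the gain *change* relative
    to the post-step steady state — the quantity that decays as a single
    exponential after a background step in either direction.  Probe delays
    default to {0.1, 0.2, 0.4, 0.8, 1.6, 2.0} s.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray([0.1, 0.2, 0.4, 0.8, 1.6, 2.0] if probe_delays is None
                   else probe_delays, float)
    clean = asymptote + amplitude * np.exp(-t / tau)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("rng required when noise_cv > 0")
        clean = clean * rng.lognormal(0.0, noise_cv, t.size)
    return StepGainSeries(direction, t, clean, np.ones(t.size, int))


def _mean_step_only(traceset: TraceSet) -> ResponseTrace:
    only = traceset.select(phase="step_only").traces
    if not only:
        raise ValueError("trace set has no step_only trials for subtraction")
    mean = np.mean([tr.samples for tr in only], axis=0)
    ref = only[0]
    return ResponseTrace(mean, ref.dt, ref.protocol, ground_truth=ref.ground_truth)


def step_gain_series(traceset: TraceSet, direction: str) -> StepGainSeries:
    """Build the gain-versus-delay series for one step direction.

    For each probe delay: subtract the mean step-only trace from every probe
    trial, window the mean isolated response (20% criterion), and compute the
    gain of the isolated responses.
    """
    step_only = _mean_step_only(traceset)
    delays = sorted(d for d in traceset.label_values("delay") if d is not None
                    and traceset.select(phase=direction, delay=d).traces)
    if not delays:
        raise ValueError(f"no {direction} probe trials in trace set")
    gains, ns = [], []
    for d in delays:
        grp = traceset.select(phase=direction, delay=d)
        iso = [isolate_flash_response(tr, step_only) for tr in grp]
        t_flash = grp.traces[0].labels["flash_time"]
        s = grp.traces[0].labels["flash_strength"]
        dt = iso[0].dt
        mean = np.mean([tr.samples for tr in iso], axis=0)
        win = find_response_window(mean, t_flash, dt)
        base = default_baseline_window(t_flash, dt)
        gp = gain_from_responses(iso, win, base, s, dt)
        gains.append(gp.gain)
        ns.append(gp.n_trials)
    return StepGainSeries(direction, np.asarray(delays, float),
                          np.asarray(gains), np.asarray(ns))
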