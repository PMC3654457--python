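"""Stochastic simulation of rod-pathway flash-response experiments.

The generator produces trial x time current traces with known ground truth so
that every analysis stage (gain, noise, threshold, Weber fits, kinetics,
spatial transfer, rod/cone separation) can be validated by parameter
recovery.  The model is deliberately phenomenological:

* photon absorptions are Poisson across a pool of rods at the background rate
  (R*/rod/s), plus Poisson flash absorptions (mean = flash strength in R*/rod
  per rod);
* each absorbed photon contributes a stereotyped single-photon current
  waveform (alpha function) scaled by the instantaneous pathway gain;
* gain follows one of three laws: constant (``none``), the half-desensitizing
  background law G = G_D / (1 + I_B/I_0) (``weber``), or a per-photon
  multiplicative reduction with exponential recovery (``per_photon``);
* continuous dark noise is additive Gaussian (optionally low-pass filtered).

Traces are emitted positive-up (an On response is an inward current; the sign
flip is applied at generation so downstream metrics never re-flip).

Units are fixed package-wide: pA, s, R*/rod (flash strength), R*/rod/s
(background), µm (space).

Reproducibility: one root seed; per-trial child generators derived with
``numpy.random.SeedSequence.spawn`` in trial order, so a fixed seed yields a
bit-identical trace set regardless of how many trials are consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "WeberGain",
    "PerPhotonGain",
    "BarPattern",
    "Flash",
    "StimulusProtocol",
    "SimulationConfig",
    "ResponseTrace",
    "TraceSet",
    "single_photon_waveform",
    "generate_absorptions",
    "simulate_trial",
    "simulate_protocol_suite",
    "to_spike_counts",
]

PROTOCOL_KINDS = ("flash_series", "step_series", "bar_adaptation", "dual_wavelength")


# --------------------------------------------------------------------------
# gain laws
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeberGain:
    """Steady-state gain G = G_D / (1 + I_B / I_0).

    ``G_D`` is the maximal (dark-adapted) gain scaling applied to each
    single-photon waveform; ``I_0`` is the background (R*/rod/s) that halves
    it.
    """

    G_D: float = 1.0
    I_0: float = 0.08

    def __post_init__(self):
        if self.G_D <= 0 or self.I_0 <= 0:
            raise ValueError("WeberGain requires G_D > 0 and I_0 > 0")

    def gain_at(self, background):
        return self.G_D / (1.0 + np.asarray(background, float) / self.I_0)


@dataclass(frozen=True)
class PerPhotonGain:
    """Each absorbed photon in the pool multiplies gain by (1 - alpha).

    Two recovery laws are available.  ``exponential`` (default): the gain
    state relaxes back to 1 with time constant ``tau_recovery``; its exact
    steady-state mean gain is 1 / (1 + alpha * mu * tau_recovery * C)
    (the multiplicative jump process closes in expectation).  ``boxcar``:
    each photon's suppression expires after exactly ``tau_recovery``
    seconds, so the gain is (1 - alpha)**N with N the pooled count in the
    trailing window, and the steady-state mean gain is exactly the Poisson
    pool-model value exp(-mu * tau_recovery * C * alpha).
    """

    alpha: float
    tau_recovery: float = 0.4
    recovery: Literal["exponential", "boxcar"] = "exponential"

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tau_recovery <= 0:
            raise ValueError("tau_recovery must be > 0")
        if self.recovery not in ("exponential", "boxcar"):
            raise ValueError("recovery must be 'exponential' or 'boxcar'")


GainLaw = WeberGain | PerPhotonGain | None


# --------------------------------------------------------------------------
# stimulus description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BarPattern:
    """Periodic bright/dark bar grating (square wave in one dimension).

    ``bar_width`` is the width of one bar (µm); the spatial period is twice
    that.  ``phase`` shifts the pattern (µm).  ``intensity`` is the bright-bar
    intensity (R*/rod/s); dark bars carry the protocol's background.
    """

    bar_width: float
    intensity: float
    phase: float = 0.0

    def __post_init__(self):
        if self.bar_width <= 0:
            raise ValueError("bar_width must be > 0")
        if self.intensity < 0:
            raise ValueError("bar intensity must be >= 0")


@dataclass(frozen=True)
class Flash:
    time: float
    strength: float  # R*/rod
    location_id: int = 0

    def __post_init__(self):
        if self.strength <= 0:
            raise ValueError("flash strength must be > 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Background timeline plus flash times; optionally a spatial pattern.

    ``background_segments`` is a list of (start, end, intensity R*/rod/s)
    tuples that must tile [0, trial_duration) without gaps or overlap.
    """

    background_segments: tuple
    flashes: tuple = ()
    spatial_pattern: BarPattern | None = None
    channel: Literal["short_wavelength", "long_wavelength"] = "short_wavelength"

    def __init__(self, background_segments, flashes=(), spatial_pattern=None,
                 channel="short_wavelength"):
        object.__setattr__(self, "background_segments",
                           tuple((float(a), float(b), float(i)) for a, b, i in background_segments))
        object.__setattr__(self, "flashes",
                           tuple(f if isinstance(f, Flash) else Flash(*f) for f in flashes))
        object.__setattr__(self, "spatial_pattern", spatial_pattern)
        if channel not in ("short_wavelength", "long_wavelength"):
            raise ValueError("channel must be short_wavelength or long_wavelength")
        object.__setattr__(self, "channel", channel)

    def validate(self, trial_duration: float) -> None:
        segs = sorted(self.background_segments)
        if not segs:
            raise ValueError("protocol needs at least one background segment")
        for idx, (a, b, inten) in enumerate(segs):
            if inten < 0:
                raise ValueError(f"background segment {idx} has negative intensity {inten}")
            if b <= a:
                raise ValueError(f"background segment {idx} is empty or reversed")
        if not math.isclose(segs[0][0], 0.0, abs_tol=1e-9):
            raise ValueError("background segments must start at t=0")
        for (a0, b0, _), (a1, b1, _) in zip(segs, segs[1:]):
            if not math.isclose(b0, a1, abs_tol=1e-9):
                raise ValueError("background segments must tile the trial without gaps/overlap")
        if segs[-1][1] < trial_duration - 1e-9:
            raise ValueError("background segments must cover the full trial duration")
        for f in self.flashes:
            if not 0 <= f.time < trial_duration:
                raise ValueError(f"flash at t={f.time} s lies outside the trial window")

    def intensity_timeline(self, n_samples: int, dt: float) -> np.ndarray:
        """Per-rod background rate (R*/rod/s) sampled on the trial grid."""
        t = np.arange(n_samples) * dt
        out = np.zeros(n_samples)
        for a, b, inten in self.background_segments:
            out[(t >= a - 1e-12) & (t < b - 1e-12)] = inten
        return out

    @staticmethod
    def constant(intensity: float, duration: float, flashes=(), **kw) -> "StimulusProtocol":
        return StimulusProtocol([(0.0, duration, intensity)], flashes, **kw)

    @staticmethod
    def step(pre: float, post: float, t_on: float, t_off: float, duration: float,
             flashes=()) -> "StimulusProtocol":
        segs = [(0.0, t_on, pre), (t_on, t_off, post), (t_off, duration, pre)]
        return StimulusProtocol(segs, flashes)


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated cell.

    Defaults: 1 kHz sampling, 2 s trials, alpha-function single-photon
    response peaking at 0.1 s with 1 pA amplitude.
    """

    n_rods: int = 800
    sampling_rate: float = 1000.0
    trial_duration: float = 2.0
    spr_amplitude: float = 1.0
    spr_time_to_peak: float = 0.1
    continuous_noise_sd: float = 1.0
    gain_law: GainLaw = None
    noise_cutoff_hz: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_rods < 1:
            raise ValueError("n_rods must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be > 0")
        if self.spr_time_to_peak <= 0:
            raise ValueError("spr_time_to_peak must be > 0")
        if self.continuous_noise_sd < 0:
            raise ValueError("continuous_noise_sd must be >= 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sampling_rate)

    @property
    def spr_integral(self) -> float:
        """Closed-form time integral of the single-photon response (pA*s)."""
        return self.spr_amplitude * self.spr_time_to_peak * math.e


@dataclass
class ResponseTrace:
    """One trial's sampled current (pA, positive-up) plus provenance."""

    samples: np.ndarray
    dt: float
    protocol: StimulusProtocol
    trial_index: int = 0
    ground_truth: SimulationConfig | None = None
    labels: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass
class TraceSet:
    """A labelled collection of trials from one protocol suite."""

    kind: str
    traces: list[ResponseTrace]
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def select(self, **labels) -> "TraceSet":
        keep = [tr for tr in self.traces
                if all(tr.labels.get(k) == v for k, v in labels.items())]
        return TraceSet(self.kind, keep, self.params, self.seed)

    def label_values(self, key: str) -> list:
        seen = []
        for tr in self.traces:
            v = tr.labels.get(key)
            if v not in seen:
                seen.append(v)
        return seen

    def stack(self) -> np.ndarray:
        return np.stack([tr.samples for tr in self.traces])

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# --------------------------------------------------------------------------
# elementary pieces
# --------------------------------------------------------------------------

def single_photon_waveform(t_grid, spr_amplitude: float, spr_time_to_peak: float) -> np.ndarray:
    """Alpha-function elementary response a * (t/tp) * exp(1 - t/tp) for t >= 0.

    Peaks at ``spr_time_to_peak`` with value ``spr_amplitude``; its time
    integral is ``amplitude * time_to_peak * e``.
    """
    if spr_time_to_peak <= 0:
        raise ValueError("spr_time_to_peak must be > 0")
    t = np.asarray(t_grid, float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly ascending")
    x = np.where(t >= 0, t / spr_time_to_peak, 0.0)
    w = spr_amplitude * x * np.exp(1.0 - x)
    return np.where(t >= 0, w, 0.0)


def generate_absorptions(intensity_timeline, n_rods: int, dt: float,
                         rng: np.random.Generator) -> list[np.ndarray]:
    """Per-rod photon-arrival times for a piecewise-constant rate timeline.

    ``intensity_timeline`` gives the per-rod rate (R*/rod/s) in each time bin
    of width ``dt``.  Counts per bin are Poisson(rate*dt) independently per
    rod; arrival times are placed uniformly within the bin.  Returns a list
    of ``n_rods`` sorted arrays of times (s).
    """
    rate = np.asarray(intensity_timeline, float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bad = np.nonzero(rate < 0)[0]
    if bad.size:
        raise ValueError(f"negative intensity in timeline segment at bin {bad[0]}")
    counts = rng.poisson(rate * dt, size=(n_rods, rate.size))
    out = []
    for r in range(n_rods):
        bins = np.repeat(np.nonzero(counts[r])[0], counts[r][counts[r] > 0])
        times = (bins + rng.random(bins.size)) * dt
        out.append(np.sort(times))
    return out


def _pooled_counts(rate_per_rod: np.ndarray, n_rods: int, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Pooled Poisson counts per bin across the whole rod pool."""
    return rng.poisson(rate_per_rod * dt * n_rods)


def _per_photon_gain_at_events(event_bins: np.ndarray, counts: np.ndarray, dt: float,
                               law: PerPhotonGain,
                               all_counts: np.ndarray | None = None) -> np.ndarray:
    """Gain applied to the photons in each event bin, sequentially.

    Photons arriving in a bin are scaled by the gain state *before* their own
    reduction takes effect.  ``all_counts`` (full per-bin count array) is
    required for the boxcar recovery law.
    """
    one_minus = 1.0 - law.alpha
    if law.recovery == "boxcar":
        if all_counts is None:
            raise ValueError("boxcar recovery needs the full count array")
        w = max(1, round(law.tau_recovery / dt))
        cum = np.concatenate([[0], np.cumsum(all_counts)])
        lo = np.maximum(event_bins - w, 0)
        n_recent = cum[event_bins] - cum[lo]  # photons in (t - tau, t), excl. current bin
        return one_minus ** n_recent
    g = 1.0
    t_prev = 0.0
    gains = np.empty(event_bins.size)
    for i, (b, k) in enumerate(zip(event_bins, counts)):
        t = b * dt
        g = 1.0 + (g - 1.0) * math.exp(-(t - t_prev) / law.tau_recovery)
        gains[i] = g
        g *= one_minus ** k
        t_prev = t
    return gains


def _continuous_noise(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, n)
    if config.noise_cutoff_hz is not None:
        from scipy.signal import butter, filtfilt
        b, a = butter(2, config.noise_cutoff_hz / (0.5 * config.sampling_rate))
        noise = filtfilt(b, a, noise)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return config.continuous_noise_sd * noise


def simulate_trial(config: SimulationConfig, protocol: StimulusProtocol,
                   rng: np.random.Generator) -> ResponseTrace:
    """Simulate one trial: Poisson absorptions -> gain-scaled waveforms + noise.

    Under ``WeberGain`` the expected integrated flash response at background
    I_B is G_D/(1 + I_B/I_0) * strength * n_rods * spr_integral; under
    ``PerPhotonGain`` each pooled absorption multiplies subsequent gain by
    (1 - alpha) with exponential recovery.
    """
    protocol.validate(config.trial_duration)
    n, dt = config.n_samples, config.dt
    rate = protocol.intensity_timeline(n, dt)

    counts = _pooled_counts(rate, config.n_rods, dt, rng)
    for f in protocol.flashes:
        counts[int(round(f.time / dt))] += rng.poisson(f.strength * config.n_rods)

    amps = np.zeros(n)
    ev = np.nonzero(counts)[0]
    if ev.size:
        law = config.gain_law
        if law is None:
            gains = np.ones(ev.size)
        elif isinstance(law, WeberGain):
            gains = law.gain_at(rate[ev])
        elif isinstance(law, PerPhotonGain):
            gains = _per_photon_gain_at_events(ev, counts[ev], dt, law, counts)
        else:
            raise TypeError(f"unknown gain law {law!r}")
        amps[ev] = counts[ev] * gains

    kernel_t = np.arange(0.0, 10.0 * config.spr_time_to_peak, dt)
    kernel = single_photon_waveform(kernel_t, config.spr_amplitude, config.spr_time_to_peak)
    samples = np.convolve(amps, kernel)[:n] + _continuous_noise(config, n, rng)
    return ResponseTrace(samples, dt, protocol, ground_truth=config)


def to_spike_counts(trace: ResponseTrace, rng: np.random.Generator,
                    bin_width: float = 0.01, spikes_per_pa: float = 2.0) -> np.ndarray:
    """Spike-count view of a current trace: Poisson counts per bin with rate
    proportional to the rectified current.  Used to check that spike- and
    current-based gain estimates agree."""
    if bin_width <= 0 or spikes_per_pa <= 0:
        raise ValueError("bin_width and spikes_per_pa must be > 0")
    per_bin = max(1, round(bin_width / trace.dt))
    n_bins = trace.samples.size // per_bin
    rect = np.clip(trace.samples[: n_bins * per_bin], 0.0, None)
    rate = rect.reshape(n_bins, per_bin).sum(axis=1) * trace.dt * spikes_per_pa
    return rng.poisson(rate).astype(float)


def steady_state_gain(background: float, n_rods: int, law: PerPhotonGain,
                      rng: np.random.Generator, n_trials: int = 10000,
                      dt: float = 0.001, burn_in_factor: float = 8.0
                      ) -> np.ndarray:
    """Monte-Carlo samples of the per-photon gain state at steady state.

    Each trial runs the simulator's gain machinery on a pooled Poisson
    photon stream of duration ``burn_in_factor * tau_recovery`` and returns
    the gain state at the final time point.  Used to check the simulator
    against the closed-form pooled gains (exp(-lambda*alpha) for boxcar
    recovery, 1/(1+alpha*lambda) for exponential).
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    n_bins = max(2, round(burn_in_factor * law.tau_recovery / dt))
    rate = background * n_rods * dt
    counts = rng.poisson(rate, size=(n_trials, n_bins))
    out = np.empty(n_trials)
    if law.recovery == "boxcar":
        w = max(1, round(law.tau_recovery / dt))
        n_recent = counts[:, -w:].sum(axis=1)
        out[:] = (1.0 - law.alpha) ** n_recent
    else:
        t_end = (n_bins - 1) * dt
        for i in range(n_trials):
            row = counts[i]
            ev = np.nonzero(row)[0]
            g, t_prev = 1.0, 0.0
            for b, k in zip(ev, row[ev]):
                t = b * dt
                g = 1.0 + (g - 1.0) * math.exp(-(t - t_prev) / law.tau_recovery)
                g *= (1.0 - law.alpha) ** k
                t_prev = t
            out[i] = 1.0 + (g - 1.0) * math.exp(-(t_end - t_prev) / law.tau_recovery)
    return out


# --------------------------------------------------------------------------
# protocol suites
# --------------------------------------------------------------------------

def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _flash_series(config: SimulationConfig, params: dict, n_trials: int,
                  seed: int) -> TraceSet:
    backgrounds = list(params.get("backgrounds", [0.0, 0.02, 0.08, 0.32, 1.28]))
    flash_time = params.get("flash_time", 1.0)
    strengths = params.get("flash_strengths")
    if strengths is None:
        strengths = [params.get("flash_strength", 0.01)] * len(backgrounds)
    if len(strengths) != len(backgrounds):
        raise ValueError("flash_strengths must match backgrounds in length")
    rngs = iter(_spawn(seed, len(backgrounds) * n_trials))
    traces = []
    for bg, s in zip(backgrounds, strengths):
        proto = StimulusProtocol.constant(bg, config.trial_duration,
                                          [Flash(flash_time, s)])
        for i in range(n_trials):
            tr = simulate_trial(config, proto, next(rngs))
            tr.trial_index = i
            tr.labels = {"background": bg, "flash_strength": s,
                         "flash_time": flash_time, "phase": "flash"}
            traces.append(tr)
    return TraceSet("flash_series", traces,
                    {"backgrounds": backgrounds, "flash_strengths": strengths,
                     "flash_time": flash_time}, seed)


def _step_series(config: SimulationConfig, params: dict, n_trials: int,
                 seed: int) -> TraceSet:
    pre = params.get("pre_background", 0.02)
    post = params.get("post_background", 0.08)
    t_on = params.get("t_on", 0.5)
    t_off = params.get("t_off", 3.0)
    duration = params.get("trial_duration", 6.0)
    delays = list(params.get("probe_delays", [0.1, 0.2, 0.4, 0.8, 1.6, 2.0]))
    s_pre = params.get("flash_strength_pre", 0.01)
    s_post = params.get("flash_strength_post", s_pre)
    cfg = replace(config, trial_duration=duration)
    conditions = ([("onset", d, s_post) for d in delays]
                  + [("offset", d, s_pre) for d in delays]
                  + [("step_only", None, None)])
    rngs = iter(_spawn(seed, len(conditions) * n_trials))
    traces = []
    for phase, d, s in conditions:
        if phase == "step_only":
            flashes = []
        else:
            t_flash = (t_on if phase == "onset" else t_off) + d
            flashes = [Flash(t_flash, s)]
        proto = StimulusProtocol.step(pre, post, t_on, t_off, duration, flashes)
        for i in range(n_trials):
            tr = simulate_trial(cfg, proto, next(rngs))
            tr.trial_index = i
            tr.labels = {"phase": phase, "delay": d, "flash_strength": s,
                         "flash_time": None if phase == "step_only" else flashes[0].time}
            traces.append(tr)
    return TraceSet("step_series", traces,
                    {"pre_background": pre, "post_background": post, "t_on": t_on,
                     "t_off": t_off, "probe_delays": delays,
                     "flash_strength_pre": s_pre, "flash_strength_post": s_post},
                    seed)


def _bar_adaptation(config: SimulationConfig, params: dict, n_trials: int,
                    seed: int) -> TraceSet:
    from .spatial import pooled_bar_intensity

    bar_width = params.get("bar_width", 50.0)
    pool_diameter = params.get("pool_diameter", 100.0)
    baseline = params.get("baseline_intensity", 0.02)
    adapting = params.get("adapting_intensity", 0.2)
    strength = params.get("flash_strength", 0.01)
    flash_time = params.get("flash_time", 1.0)
    kernel = params.get("kernel", "uniform")
    law = config.gain_law if isinstance(config.gain_law, WeberGain) else WeberGain()
    cfg = replace(config, gain_law=law)
    # probe locations: adapted at a bright-bar center, unadapted at a dark-bar
    # center, half a period apart
    locations = {"adapted": 0.0, "unadapted": bar_width}
    conditions = [(phase, loc) for phase in ("baseline", "adapting")
                  for loc in locations]
    rngs = iter(_spawn(seed, len(conditions) * n_trials))
    traces = []
    for phase, loc in conditions:
        if phase == "baseline":
            eff_bg = baseline
        else:
            eff_bg = pooled_bar_intensity(locations[loc], bar_width, pool_diameter,
                                          baseline, adapting, kernel=kernel)
        proto = StimulusProtocol.constant(eff_bg, cfg.trial_duration,
                                          [Flash(flash_time, strength, 0 if loc == "adapted" else 1)])
        for i in range(n_trials):
            tr = simulate_trial(cfg, proto, next(rngs))
            tr.trial_index = i
            tr.labels = {"phase": phase, "location": loc, "background": eff_bg,
                         "flash_strength": strength, "flash_time": flash_time}
            traces.append(tr)
    return TraceSet("bar_adaptation", traces,
                    {"bar_width": bar_width, "pool_diameter": pool_diameter,
                     "baseline_intensity": baseline, "adapting_intensity": adapting,
                     "flash_strength": strength, "kernel": kernel}, seed)


def _dual_wavelength(config: SimulationConfig, params: dict, n_trials: int,
                     seed: int) -> TraceSet:
    """Rod + cone mixture.  Long-wavelength flashes drive L-cones ~600x more
    effectively than rods; the cone component has fixed gain and faster
    kinetics, the rod component adapts by the Weber law."""
    backgrounds = list(params.get("backgrounds", [0.02, 0.08, 0.32]))
    rod_strength = params.get("rod_flash_strength", 0.01)
    flash_time = params.get("flash_time", 1.0)
    cone_t_peak = params.get("cone_time_to_peak", 0.035)
    cone_gain = params.get("cone_gain_pa_per_rstar", 30.0)
    sens_ratio = params.get("cone_rod_sensitivity_ratio", 600.0)
    short_leak = params.get("short_wavelength_cone_leak", 1.0 / sens_ratio)
    law = config.gain_law if isinstance(config.gain_law, WeberGain) else WeberGain()
    cfg = replace(config, gain_law=law)
    dt, n = cfg.dt, cfg.n_samples
    kernel_t = np.arange(0.0, 10.0 * cone_t_peak, dt)
    conditions = [(bg, ch) for bg in backgrounds
                  for ch in ("short_wavelength", "long_wavelength")]
    rngs = iter(_spawn(seed, len(conditions) * n_trials))
    traces = []
    for bg, ch in conditions:
        # rod drive matched across wavelengths by construction; cone drive is
        # rod_strength in R*/cone-equivalents for long, a small leak for short
        cone_drive = rod_strength * (1.0 if ch == "long_wavelength" else short_leak)
        cone_wave = np.zeros(n)
        i0 = int(round(flash_time / dt))
        w = single_photon_waveform(kernel_t, cone_gain * cone_drive, cone_t_peak)
        cone_wave[i0: i0 + w.size] += w[: n - i0]
        proto = StimulusProtocol.constant(bg, cfg.trial_duration,
                                          [Flash(flash_time, rod_strength)], channel=ch)
        for i in range(n_trials):
            tr = simulate_trial(cfg, proto, next(rngs))
            tr.samples = tr.samples + cone_wave
            tr.trial_index = i
            tr.labels = {"background": bg, "channel": ch,
                         "flash_strength": rod_strength, "flash_time": flash_time}
            tr.components = {"cone": cone_wave.copy()}
            traces.append(tr)
    return TraceSet("dual_wavelength", traces,
                    {"backgrounds": backgrounds, "rod_flash_strength": rod_strength,
                     "flash_time": flash_time, "cone_time_to_peak": cone_t_peak,
                     "cone_gain_pa_per_rstar": cone_gain,
                     "cone_rod_sensitivity_ratio": sens_ratio}, seed)


_SUITES = {
    "flash_series": _flash_series,
    "step_series": _step_series,
    "bar_adaptation": _bar_adaptation,
    "dual_wavelength": _dual_wavelength,
}


def simulate_protocol_suite(kind: str, config: SimulationConfig,
                            params: dict | None = None, n_trials: int = 20,
                            seed: int | None = None) -> TraceSet:
    """Generate a labelled trial set for one of the standard protocols.

    Kinds: ``flash_series`` (probe flashes across steady backgrounds),
    ``step_series`` (probe flashes at delays after background step on/offset,
    plus step-only trials for subtraction), ``bar_adaptation`` (probes at
    adapted/unadapted bar locations in baseline and adapting phases),
    ``dual_wavelength`` (rod+cone mixtures at short/long wavelengths).
    """
    if kind not in _SUITES:
        raise ValueError(f"unknown protocol kind {kind!r}; valid kinds: "
                         + ", ".join(PROTOCOL_KINDS))
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seed is None:
        seed = config.seed
    return _SUITES[kind](config, dict(params or {}), n_trials, seed)
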