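"""Per-flash response estimators: response window, gain, template projection,
baseline noise, and ideal-observer detection threshold.

The response window is the contiguous run of samples where the trial-averaged
response exceeds 20% of its post-flash maximum.  Gain is the baseline-
subtracted integrated current in that window divided by the flash strength
(pC per R*/rod).  Detection threshold is the flash strength at which the
expected template-projected signal equals the SD of the template-projected
pre-flash noise (signal-to-noise ratio of 1):

    theta = sigma_nu / mean(gamma),

with gamma the per-trial template projection per unit flash strength and nu
the projection of pre-flash noise (no flash-strength division: noise is a
property of the cell, not of the probe).  theta is invariant under rescaling
the template, so the template is used raw (mean windowed response), not
unit-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ResponseTrace, TraceSet

__all__ = [
    "NoDetectableResponse",
    "Template",
    "GainPoint",
    "ThresholdPoint",
    "find_response_window",
    "gain_from_responses",
    "make_template",
    "template_projection",
    "baseline_noise_sd",
    "detection_threshold",
    "default_baseline_window",
    "analyze_flash_group",
    "metrics_table",
]

# baseline window default: 0.5 s ending 50 ms before flash onset
BASELINE_LENGTH = 0.5
BASELINE_GAP = 0.05


class NoDetectableResponse(ValueError):
    """Raised when the mean trace shows no positive post-flash deflection."""


@dataclass(frozen=True)
class Template:
    """Mean windowed response used for signal/noise projections."""

    window: tuple[int, int]  # half-open sample window
    weights: np.ndarray
    flash_strength_ref: float

    def __post_init__(self):
        if self.window[1] <= self.window[0]:
            raise ValueError("template window is empty")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("template weights must be finite")

    @property
    def length(self) -> int:
        return self.window[1] - self.window[0]


@dataclass(frozen=True)
class GainPoint:
    background: float        # R*/rod/s
    gain: float              # pC per R*/rod (or spikes per R*/rod)
    sd: float
    n_trials: int

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class ThresholdPoint:
    background: float
    theta: float             # R*/rod
    gamma_mean: float        # projection units per R*/rod
    noise_sd: float          # projection units


def find_response_window(mean_trace, flash_time: float, dt: float,
                         criterion: float = 0.2) -> tuple[int, int]:
    """Half-open sample window where the mean response exceeds ``criterion``
    (default 20%) of its post-flash maximum.

    If several disjoint supra-criterion runs exist, the run containing the
    global post-flash peak is kept.  Raises :class:`NoDetectableResponse`
    when the maximal post-flash deflection is not positive.
    """
    m = np.asarray(mean_trace, float)
    if not np.all(np.isfinite(m)):
        raise ValueError("mean trace must be finite")
    i_flash = int(round(flash_time / dt))
    if not 0 <= i_flash < m.size:
        raise ValueError("flash time lies outside the trace")
    post = m[i_flash:]
    peak = post.max(initial=-np.inf)
    if peak <= 0:
        raise NoDetectableResponse("no detectable response: max post-flash deflection <= 0")
    above = post >= criterion * peak
    i_peak = int(np.argmax(post))
    # contiguous run containing the peak
    start = i_peak
    while start > 0 and above[start - 1]:
        start -= 1
    stop = i_peak + 1
    while stop < post.size and above[stop]:
        stop += 1
    return (i_flash + start, i_flash + stop)


def default_baseline_window(flash_time: float, dt: float,
                            length: float = BASELINE_LENGTH,
                            gap: float = BASELINE_GAP) -> tuple[int, int]:
    """Pre-flash baseline window: ``length`` s ending ``gap`` s before flash."""
    stop = int(round((flash_time - gap) / dt))
    start = max(0, stop - int(round(length / dt)))
    if stop <= start:
        raise ValueError("baseline window is empty; flash too early in trial")
    return (start, stop)


def _integrate(samples: np.ndarray, window: tuple[int, int], dt: float) -> float:
    a, b = window
    return float(samples[a:b].sum() * dt)


def gain_from_responses(trials, window: tuple[int, int],
                        baseline_window: tuple[int, int], flash_strength: float,
                        dt: float, background: float = 0.0) -> GainPoint:
    """Gain = mean over trials of (integrated windowed current minus baseline
    mean x window duration) / flash strength; ``sd`` is the SD of the
    per-trial values."""
    if flash_strength <= 0:
        raise ValueError("flash_strength must be > 0")
    if baseline_window[1] <= baseline_window[0]:
        raise ValueError("baseline window has zero length")
    if not (baseline_window[1] <= window[0] or window[1] <= baseline_window[0]):
        raise ValueError("response and baseline windows must be disjoint")
    w_len = (window[1] - window[0]) * dt
    values = []
    for tr in trials:
        s = tr.samples if isinstance(tr, ResponseTrace) else np.asarray(tr, float)
        base = s[baseline_window[0]: baseline_window[1]].mean()
        values.append((_integrate(s, window, dt) - base * w_len) / flash_strength)
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return GainPoint(background, float(values.mean()), sd, values.size)


def make_template(trials, window: tuple[int, int], flash_strength: float,
                  baseline_window: tuple[int, int] | None = None) -> Template:
    """Average (baseline-subtracted) current in the response window."""
    stack = np.stack([tr.samples if isinstance(tr, ResponseTrace) else np.asarray(tr, float)
                      for tr in trials])
    mean = stack.mean(axis=0)
    base = mean[baseline_window[0]: baseline_window[1]].mean() if baseline_window else 0.0
    return Template(window, mean[window[0]: window[1]] - base, flash_strength)


def template_projection(segment, template: Template,
                        flash_strength: float | None = None) -> float:
    """Dot product of a trace segment with the template weights.

    For flash segments pass the flash strength: the projection is divided by
    it (signal per unit flash, gamma).  For pre-flash noise segments leave it
    None (nu is a property of the noise alone).
    """
    seg = np.asarray(segment, float)
    if seg.size != template.length:
        raise ValueError(f"segment length {seg.size} != template length {template.length}")
    p = float(seg @ template.weights)
    if flash_strength is not None:
        if flash_strength <= 0:
            raise ValueError("flash_strength must be > 0")
        p /= flash_strength
    return p


def baseline_noise_sd(trials, pre_flash_window: tuple[int, int],
                      template: Template) -> float:
    """SD over trials of template projections of pre-flash segments.

    The pre-flash window must have the template's length; it is anchored at
    its own start (the template weights are applied to the pre-flash segment
    directly)."""
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to estimate noise SD")
    a = pre_flash_window[0]
    vals = []
    for tr in trials:
        s = tr.samples if isinstance(tr, ResponseTrace) else np.asarray(tr, float)
        seg = s[a: a + template.length]
        vals.append(template_projection(seg, template))
    return float(np.std(vals, ddof=1))


def detection_threshold(gamma_values, nu_values,
                        background: float = 0.0) -> ThresholdPoint:
    """Flash strength at which expected signal equals noise SD (SNR = 1):
    theta = SD(nu) / mean(gamma)."""
    gamma_values = np.asarray(gamma_values, float)
    nu_values = np.asarray(nu_values, float)
    if nu_values.size < 2:
        raise ValueError("need >= 2 noise projections")
    g = float(gamma_values.mean())
    if g <= 0:
        raise NoDetectableResponse("response not detectable; threshold undefined")
    sigma = float(nu_values.std(ddof=1))
    return ThresholdPoint(background, sigma / g, g, sigma)


# --------------------------------------------------------------------------
# trace-set level drivers
# --------------------------------------------------------------------------

def analyze_flash_group(trials: list[ResponseTrace], flash_time: float,
                        flash_strength: float, background: float = 0.0,
                        window: tuple[int, int] | None = None
                        ) -> tuple[GainPoint, ThresholdPoint]:
    """Full per-background analysis of one group of flash trials."""
    dt = trials[0].dt
    stack = np.stack([tr.samples for tr in trials])
    mean = stack.mean(axis=0)
    base_win = default_baseline_window(flash_time, dt)
    if window is None:
        window = find_response_window(mean - mean[base_win[0]:base_win[1]].mean(),
                                      flash_time, dt)
    gp = gain_from_responses(trials, window, base_win, flash_strength, dt, background)
    if len(trials) < 2:
        # noise SD and threshold are undefined from a single trial
        return gp, ThresholdPoint(background, float("nan"), float("nan"),
                                  float("nan"))
    tmpl = make_template(trials, window, flash_strength, base_win)
    gammas = [template_projection(tr.samples[window[0]: window[1]], tmpl, flash_strength)
              for tr in trials]
    pre = (max(0, window[0] - tmpl.length - int(round(BASELINE_GAP / dt))), None)
    nus = [template_projection(tr.samples[pre[0]: pre[0] + tmpl.length], tmpl)
           for tr in trials]
    tp = detection_threshold(gammas, nus, background)
    return gp, tp


def metrics_table(traceset: TraceSet, fixed_window: tuple[int, int] | None = None
                  ) -> pd.DataFrame:
    """Per-background metrics of a flash_series trace set.

    Columns: background, gain, gain_sd, noise_sd, threshold, n_trials.
    """
    rows = []
    for bg in traceset.label_values("background"):
        grp = traceset.select(background=bg)
        trials = grp.traces
        s = trials[0].labels["flash_strength"]
        t_flash = trials[0].labels["flash_time"]
        gp, tp = analyze_flash_group(trials, t_flash, s, bg, window=fixed_window)
        rows.append({"background": bg, "gain": gp.gain, "gain_sd": gp.sd,
                     "noise_sd": tp.noise_sd, "threshold": tp.theta,
                     "n_trials": gp.n_trials})
    return pd.DataFrame(rows)
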