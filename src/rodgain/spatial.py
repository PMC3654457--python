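"""Spatial scale of gain control and rod/cone pathway separation.

Bar-adaptation experiments adapt one set of bar locations and probe gain at
adapted and unadapted locations; adaptation transfer is the gain change at
the unadapted location divided by the gain change at the adapted location
(gain change = adapting-phase gain / baseline-phase gain).  A raw ratio of 1
means complete transfer.  An auxiliary normalized index maps complete
transfer to 1 and no transfer to 0:

    index = (1 - gain_change_unadapted) / (1 - gain_change_adapted).

The geometric prediction pools the bar pattern through a spatial aperture
(uniform 1-D aperture of width = pool diameter by default; chord-weighted
disk and Gaussian kernels optional) and applies the Weber gain law to the
pooled local intensity.

Dual-wavelength analysis: a matched short-wavelength (rod-only) response is
scaled and subtracted from the long-wavelength (rod+cone) response to
isolate the cone component; gain-versus-background slopes are then computed
per pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import (default_baseline_window, find_response_window,
                      gain_from_responses)
from .simulate import ResponseTrace, TraceSet
from .weber import RegionSlope, loglog_slope, weber_gain

__all__ = [
    "TransferMeasurement",
    "pooled_bar_intensity",
    "adaptation_transfer",
    "predict_transfer",
    "measure_transfer",
    "rods_in_field",
    "isolate_cone_response",
    "pathway_gains",
    "pathway_gain_slopes",
]


@dataclass(frozen=True)
class TransferMeasurement:
    bar_width: float               # µm
    gain_change_adapted: float     # adapting / baseline gain ratio
    gain_change_unadapted: float
    transfer: float                # unadapted change / adapted change
    transfer_index: float          # 1 = complete, 0 = none

    def __post_init__(self):
        if self.gain_change_adapted <= 0 or self.gain_change_unadapted <= 0:
            raise ValueError("gain changes must be positive ratios")


# --------------------------------------------------------------------------
# bar-pattern pooling
# --------------------------------------------------------------------------

def _bright_coverage(x: float, bar_width: float) -> float:
    """Measure of bright bars in [0, x] for a square grating of period
    2*bar_width with a bright bar centered at 0.  Odd in x (exact closed
    form, no quadrature)."""
    if x < 0:
        return -_bright_coverage(-x, bar_width)
    w, p = bar_width, 2.0 * bar_width
    k, r = divmod(x, p)
    # within one period [0, p): bright on [0, w/2) and [p - w/2, p)
    frac = min(r, w / 2.0) + max(0.0, r - (p - w / 2.0))
    return k * w + frac


def pooled_bar_intensity(x0: float, bar_width: float, pool_diameter: float,
                         baseline: float, bright_intensity: float,
                         kernel: str = "uniform", n_grid: int = 4001) -> float:
    """Mean intensity seen through a pooling aperture centered at ``x0``
    (µm) on a square grating: bright bars of ``bright_intensity`` centered at
    multiples of the period 2*bar_width, dark bars at ``baseline``.

    Kernels: ``uniform`` (1-D aperture of width = diameter; closed form),
    ``disk`` (chord-weighted section through a uniform disk), ``gaussian``
    (sigma = diameter/4).
    """
    if pool_diameter <= 0:
        raise ValueError("pool diameter must be > 0")
    if bar_width <= 0:
        raise ValueError("bar width must be > 0")
    if baseline < 0 or bright_intensity < 0:
        raise ValueError("intensities must be >= 0")
    R = pool_diameter / 2.0
    if kernel == "uniform":
        frac = (_bright_coverage(x0 + R, bar_width)
                - _bright_coverage(x0 - R, bar_width)) / pool_diameter
    elif kernel in ("disk", "gaussian"):
        if kernel == "disk":
            u = np.linspace(-R, R, n_grid)
            wgt = np.sqrt(np.maximum(R * R - u * u, 0.0))
        else:
            sigma = pool_diameter / 4.0
            u = np.linspace(-4 * sigma, 4 * sigma, n_grid)
            wgt = np.exp(-0.5 * (u / sigma) ** 2)
        period = 2.0 * bar_width
        phase = np.mod(x0 + u + bar_width / 2.0, period)
        bright = (phase < bar_width).astype(float)
        frac = float(np.trapezoid(wgt * bright, u) / np.trapezoid(wgt, u))
    else:
        raise ValueError(f"unknown kernel {kernel!r}; use uniform, disk, or gaussian")
    return baseline + frac * (bright_intensity - baseline)


# --------------------------------------------------------------------------
# transfer measurement and prediction
# --------------------------------------------------------------------------

def _transfer_from_changes(bar_width: float, change_adapted: float,
                           change_unadapted: float) -> TransferMeasurement:
    raw = change_unadapted / change_adapted
    denom = 1.0 - change_adapted
    index = (1.0 - change_unadapted) / denom if abs(denom) > 1e-12 else 1.0
    return TransferMeasurement(bar_width, change_adapted, change_unadapted,
                               raw, index)


def adaptation_transfer(baseline_gains: dict, adapting_gains: dict,
                        bar_width: float = float("nan")) -> TransferMeasurement:
    """Transfer from per-location gains measured in the two phases.

    ``baseline_gains`` and ``adapting_gains`` map location names
    ('adapted', 'unadapted') to gains.
    """
    for loc in ("adapted", "unadapted"):
        if loc not in baseline_gains or loc not in adapting_gains:
            raise ValueError(f"missing location {loc!r} in one of the phases")
    ch_a = adapting_gains["adapted"] / baseline_gains["adapted"]
    ch_u = adapting_gains["unadapted"] / baseline_gains["unadapted"]
    return _transfer_from_changes(bar_width, ch_a, ch_u)


def predict_transfer(bar_width: float, pool_diameter: float, baseline: float,
                     adapting_intensity: float, I_0: float,
                     kernel: str = "uniform") -> TransferMeasurement:
    """Geometric prediction of adaptation transfer.

    The adapted probe sits at a bright-bar center, the unadapted probe half a
    period away at a dark-bar center.  Local gain comes from the Weber law
    applied to the pooled local mean intensity; in the baseline phase the
    field is uniform at ``baseline``.
    """
    if I_0 <= 0:
        raise ValueError("I_0 must be > 0")
    g_base = weber_gain(baseline, 1.0, I_0)
    pooled_a = pooled_bar_intensity(0.0, bar_width, pool_diameter, baseline,
                                    adapting_intensity, kernel)
    pooled_u = pooled_bar_intensity(bar_width, bar_width, pool_diameter,
                                    baseline, adapting_intensity, kernel)
    ch_a = weber_gain(pooled_a, 1.0, I_0) / g_base
    ch_u = weber_gain(pooled_u, 1.0, I_0) / g_base
    return _transfer_from_changes(bar_width, ch_a, ch_u)


def measure_transfer(traceset: TraceSet) -> TransferMeasurement:
    """Transfer measured from a bar_adaptation trace set (both phases, both
    probe locations)."""
    gains = {}
    for phase in ("baseline", "adapting"):
        gains[phase] = {}
        for loc in ("adapted", "unadapted"):
            grp = traceset.select(phase=phase, location=loc)
            if not grp.traces:
                raise ValueError(f"trace set missing phase={phase}, location={loc}")
            t_flash = grp.traces[0].labels["flash_time"]
            s = grp.traces[0].labels["flash_strength"]
            dt = grp.traces[0].dt
            mean = grp.stack().mean(axis=0)
            win = find_response_window(mean, t_flash, dt)
            base = default_baseline_window(t_flash, dt)
            gains[phase][loc] = gain_from_responses(grp.traces, win, base, s, dt).gain
    return adaptation_transfer(gains["baseline"], gains["adapting"],
                               traceset.params.get("bar_width", float("nan")))


def rods_in_field(diameter_um: float, rod_density_per_um2: float) -> float:
    """Rod count within a circular field: pi * (d/2)^2 * density."""
    if diameter_um <= 0 or rod_density_per_um2 < 0:
        raise ValueError("diameter must be > 0 and density >= 0")
    return float(np.pi * (diameter_um / 2.0) ** 2 * rod_density_per_um2)


# --------------------------------------------------------------------------
# rod / cone separation
# --------------------------------------------------------------------------

def isolate_cone_response(long_trace, short_trace,
                          late_window: tuple[int, int] | None = None,
                          min_correlation: float = 0.5):
    """Cone component = long-wavelength trace minus the scaled matched
    short-wavelength (rod-only) trace.

    The scale factor is least squares on the late, rod-dominated segment
    (default: last 30% of the trace, where the fast cone component has
    decayed).  A poor correlation between the late segments triggers a
    warning that the rod components are grossly mismatched.
    """
    long_s = long_trace.samples if isinstance(long_trace, ResponseTrace) else np.asarray(long_trace, float)
    short_s = short_trace.samples if isinstance(short_trace, ResponseTrace) else np.asarray(short_trace, float)
    if long_s.size != short_s.size:
        raise ValueError("traces differ in length")
    n = long_s.size
    a, b = late_window if late_window is not None else (int(0.7 * n), n)
    ls, ss = long_s[a:b], short_s[a:b]
    denom = float(ss @ ss)
    scale = float(ls @ ss) / denom if denom > 0 else 1.0
    if ls.std() > 0 and ss.std() > 0:
        r = float(np.corrcoef(ls, ss)[0, 1])
        if r < min_correlation:
            warnings.warn(f"rod components poorly matched (late-segment r={r:.2f})",
                          stacklevel=2)
    cone = long_s - scale * short_s
    if isinstance(long_trace, ResponseTrace):
        return ResponseTrace(cone, long_trace.dt, long_trace.protocol,
                             long_trace.trial_index, long_trace.ground_truth,
                             dict(long_trace.labels))
    return cone


def pathway_gains(traceset: TraceSet):
    """Per-background rod and cone gains from a dual_wavelength trace set.

    Rod gain comes from the short-wavelength (rod-only) mean response; the
    cone gain from the isolated cone component of the long-wavelength mean
    response.  Returns (backgrounds, rod_gains, cone_gains).
    """
    backgrounds = sorted(traceset.label_values("background"))
    rod_g, cone_g = [], []
    for bg in backgrounds:
        short = traceset.select(background=bg, channel="short_wavelength")
        long_ = traceset.select(background=bg, channel="long_wavelength")
        if not short.traces or not long_.traces:
            raise ValueError(f"background {bg}: need both wavelength channels")
        dt = short.traces[0].dt
        t_flash = short.traces[0].labels["flash_time"]
        s = short.traces[0].labels["flash_strength"]
        mean_short = short.stack().mean(axis=0)
        mean_long = long_.stack().mean(axis=0)
        base = default_baseline_window(t_flash, dt)
        win = find_response_window(mean_short, t_flash, dt)
        rod_g.append(gain_from_responses([mean_short], win, base, s, dt).gain)
        # rod-dominated matching segment: late enough that the fast cone
        # component has decayed, early enough that the rod response persists
        i_flash = int(round(t_flash / dt))
        late = (min(i_flash + int(round(0.2 / dt)), mean_short.size - 2),
                min(i_flash + int(round(0.6 / dt)), mean_short.size))
        cone = isolate_cone_response(mean_long, mean_short, late_window=late)
        cwin = find_response_window(cone, t_flash, dt)
        cone_g.append(gain_from_responses([cone], cwin, base, s, dt).gain)
    return np.asarray(backgrounds), np.asarray(rod_g), np.asarray(cone_g)


def pathway_gain_slopes(backgrounds, rod_gains, cone_gains
                        ) -> tuple[RegionSlope, RegionSlope]:
    """Log-log slope of gain versus background per pathway, after
    normalizing each pathway by its gain at the lowest background."""
    bg = np.asarray(backgrounds, float)
    if bg.size < 3:
        raise ValueError("need >= 3 backgrounds per pathway")
    region = (bg.min(), bg.max())
    i0 = int(np.argmin(bg))
    rod = np.asarray(rod_gains, float) / rod_gains[i0]
    cone = np.asarray(cone_gains, float) / cone_gains[i0]
    return (loglog_slope(bg, rod, region), loglog_slope(bg, cone, region))
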