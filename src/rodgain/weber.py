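"""Background dependence of gain, noise, and threshold.

Fits the modified Weber function

    G(I_B) = G_D / (1 + I_B / I_0)

to gain-versus-background data (least squares on log gain, so decades of gain
are weighted equally), computes log-log slopes in background regions, and the
fluctuation-driven (Rose-deVries) prediction of gain from a noise-SD change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "WeberFitResult",
    "RegionSlope",
    "weber_gain",
    "fit_weber",
    "loglog_slope",
    "default_regions",
    "variance_gain_prediction",
]


@dataclass(frozen=True)
class WeberFitResult:
    G_D: float               # maximal gain, same units as the input gains
    I_0: float               # half-desensitizing background, R*/rod/s
    residual_norm: float     # ||log residuals||
    covariance: np.ndarray   # 2x2 covariance of (G_D, I_0)

    def __post_init__(self):
        if self.G_D <= 0 or self.I_0 <= 0:
            raise ValueError("fitted G_D and I_0 must be positive")

    def predict(self, background):
        return weber_gain(background, self.G_D, self.I_0)


@dataclass(frozen=True)
class RegionSlope:
    region: tuple[float, float]   # (I_low, I_high), R*/rod/s
    slope: float                  # log-log exponent
    stderr: float
    n_points: int


def weber_gain(background, G_D, I_0):
    """Modified Weber function G = G_D / (1 + I_B/I_0)."""
    return G_D / (1.0 + np.asarray(background, float) / I_0)


def fit_weber(backgrounds, gains, min_background: float = 0.0) -> WeberFitResult:
    """Least-squares fit of the Weber function in log-gain space.

    ``min_background`` masks out very dim backgrounds (the history-dependent
    dark-gain reduction is a separate mechanism and is excluded by default
    config rather than modelled).  Initialization: G_D = max gain, I_0 = the
    background nearest half-maximal gain; a log-spaced grid of I_0 starts is
    used as fallback if the first attempt fails.
    """
    bg = np.asarray(backgrounds, float)
    g = np.asarray(gains, float)
    mask = bg >= min_background
    bg, g = bg[mask], g[mask]
    if np.unique(bg).size < 3:
        raise ValueError("need >= 3 distinct backgrounds to fit")
    if np.any(g <= 0):
        raise ValueError("gains must be > 0 for a log-space fit")

    def model(b, log_GD, log_I0):
        return log_GD - np.log(1.0 + b / np.exp(log_I0))

    GD0 = g.max()
    I00 = bg[np.argmin(np.abs(g - GD0 / 2.0))]
    if I00 <= 0:
        I00 = np.median(bg[bg > 0]) if np.any(bg > 0) else 1.0
    starts = [I00] + list(np.geomspace(max(bg[bg > 0].min(), 1e-6),
                                       max(bg.max(), 1e-5), 5))
    last_err = None
    for i0 in starts:
        try:
            popt, pcov = optimize.curve_fit(model, bg, np.log(g),
                                            p0=[np.log(GD0), np.log(i0)],
                                            maxfev=10000)
            resid = np.log(g) - model(bg, *popt)
            G_D, I_0 = np.exp(popt)
            # delta-method transform of covariance from log to natural scale
            J = np.diag([G_D, I_0])
            cov = J @ pcov @ J
            return WeberFitResult(G_D, I_0, float(np.linalg.norm(resid)), cov)
        except RuntimeError as err:  # pragma: no cover - fallback path
            last_err = err
    raise RuntimeError(f"Weber fit did not converge; I_0 starts tried: "
                       f"{[f'{s:.3g}' for s in starts]}") from last_err


def loglog_slope(backgrounds, values, region: tuple[float, float]) -> RegionSlope:
    """OLS slope of log10(value) vs log10(background) within ``region``."""
    lo, hi = region
    if not lo < hi:
        raise ValueError("region must satisfy I_low < I_high")
    bg = np.asarray(backgrounds, float)
    v = np.asarray(values, float)
    m = (bg >= lo) & (bg <= hi)
    if m.sum() < 2:
        raise ValueError(f"fewer than 2 points inside region ({lo:g}, {hi:g}) R*/rod/s")
    if np.any(bg[m] <= 0) or np.any(v[m] <= 0):
        raise ValueError("log-log slope needs positive backgrounds and values")
    res = stats.linregress(np.log10(bg[m]), np.log10(v[m]))
    return RegionSlope((lo, hi), float(res.slope),
                       float(res.stderr) if m.sum() > 2 else float("nan"),
                       int(m.sum()))


def default_regions(I_0: float, width_decades: float = 0.8
                    ) -> list[tuple[float, float]]:
    """Three equal log-width background regions centered below, on, and above
    the half-desensitizing background."""
    half = width_decades / 2.0
    centers = [np.log10(I_0) - width_decades, np.log10(I_0),
               np.log10(I_0) + width_decades]
    return [(10 ** (c - half), 10 ** (c + half)) for c in centers]


def synthetic_gain_population(backgrounds, G_D: float, I_0: float,
                              noise_cv: float, n_cells: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Gain-versus-background curves for ``n_cells`` synthetic cells.

    Each cell's gains follow the Weber function exactly, multiplied by
    lognormal measurement noise with coefficient of variation ``noise_cv``
    (sigma of log gain).  Returns an (n_cells, n_backgrounds) array.  Used
    for generate-and-fit recovery studies of :func:`fit_weber`.
    """
    bg = np.asarray(backgrounds, float)
    clean = weber_gain(bg, G_D, I_0)
    noise = rng.lognormal(mean=0.0, sigma=noise_cv, size=(n_cells, bg.size))
    return clean[None, :] * noise


def variance_gain_prediction(sd_ratio: float) -> float:
    """Gain ratio predicted if gain were inversely proportional to the
    baseline noise SD (fluctuation-driven gain control): 1 / sd_ratio."""
    if sd_ratio <= 0:
        raise ValueError("sd_ratio must be > 0")
    return 1.0 / sd_ratio
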