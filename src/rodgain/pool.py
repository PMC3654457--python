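"""Poisson photon-pool model of gain control.

A "neural element" (e.g. an AII amacrine cell) pools signals from ``C`` rods
over an integration time ``tau`` at background rate ``mu`` (R*/rod/s).  The
number of photons ``k`` it collects in one integration window is Poisson with
mean ``lambda = mu * tau * C``.  If each collected photon multiplies the gain
applied to subsequent photon responses by ``(1 - alpha)``, the expected gain
of a population of such elements is

    Gamma(lambda, alpha) = sum_k P(k; lambda) (1 - alpha)**k = exp(-lambda*alpha),

normalized so that Gamma = 1 at maximal gain (alpha = 0 or lambda = 0).

All functions are closed-form and vectorize over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PoolModel",
    "expected_count",
    "prob_at_least_one",
    "required_convergence",
    "pool_gain",
    "pool_gain_series",
    "solve_alpha",
    "min_convergence_zero_gain",
]


def expected_count(mu, tau, C):
    """Mean photon count ``lambda = mu * tau * C`` collected by a pool.

    Parameters
    ----------
    mu : background intensity, R*/rod/s (>= 0)
    tau : integration time, s (> 0)
    C : rod convergence, count (>= 1)
    """
    mu, tau, C = np.asarray(mu, float), np.asarray(tau, float), np.asarray(C, float)
    if np.any(mu < 0):
        raise ValueError("background rate mu must be >= 0")
    if np.any(tau <= 0):
        raise ValueError("integration time tau must be > 0")
    if np.any(C < 1):
        raise ValueError("rod convergence C must be >= 1")
    return mu * tau * C


def prob_at_least_one(lam):
    """P(k >= 1) = 1 - exp(-lambda) for a Poisson count with mean ``lam``."""
    lam = np.asarray(lam, float)
    if np.any(lam < 0):
        raise ValueError("lambda must be >= 0")
    return -np.expm1(-lam)


def required_convergence(mu, tau, p_target=0.5):
    """Smallest real convergence C with P(>=1 photon in tau) >= p_target.

    Closed form: C = -ln(1 - p_target) / (mu * tau).  Real-valued; wrap in
    ``math.ceil`` for an integer rod count.
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must lie in (0, 1)")
    mu, tau = np.asarray(mu, float), np.asarray(tau, float)
    if np.any(mu * tau <= 0):
        raise ValueError("mu * tau must be positive: target unreachable at zero rate")
    return -np.log1p(-p_target) / (mu * tau)


def pool_gain(lam, alpha):
    """Expected pooled gain Gamma = exp(-lambda * alpha).

    Equals the Poisson expectation of the per-element gain (1-alpha)**k with
    the sum taken from k = 0, which honors the normalization Gamma = 1 at
    maximal gain (alpha = 0).
    """
    lam, alpha = np.asarray(lam, float), np.asarray(alpha, float)
    if np.any(lam < 0):
        raise ValueError("lambda must be >= 0")
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    return np.exp(-lam * alpha)


def pool_gain_series(lam: float, alpha: float, k_min: int = 0, k_max: int | None = None) -> float:
    """Truncated-series evaluation of Gamma = sum_k P(k;lambda)(1-alpha)**k.

    Test oracle for :func:`pool_gain`.  ``k_min=1`` evaluates the literal
    variant whose sum omits the zero-photon term; it is not the default
    because it violates the Gamma(alpha=0) = 1 normalization.

    Truncation: if ``k_max`` is None the sum stops once a term falls below
    1e-15 times the partial sum.
    """
    if lam < 0 or not 0 <= alpha <= 1:
        raise ValueError("require lambda >= 0 and alpha in [0, 1]")
    total = 0.0
    k = k_min
    while True:
        term = stats.poisson.pmf(k, lam) * (1.0 - alpha) ** k
        total += term
        k += 1
        if k_max is not None:
            if k > k_max:
                break
        elif k > lam and term < 1e-15 * max(total, 1e-300):
            break
    return total


def solve_alpha(lam, gamma_target):
    """Per-photon gain reduction alpha achieving pooled gain ``gamma_target``.

    Inverts Gamma = exp(-lambda*alpha): alpha = -ln(gamma_target)/lambda.
    Values above 1 are returned as computed (caller decides feasibility) but
    mean that even total gain removal per photon is insufficient.
    """
    lam = np.asarray(lam, float)
    gamma_target = np.asarray(gamma_target, float)
    if np.any(gamma_target <= 0) or np.any(gamma_target > 1):
        raise ValueError("gamma_target must lie in (0, 1]")
    if np.any(lam <= 0):
        raise ValueError("lambda must be > 0")
    return -np.log(gamma_target) / lam


def min_convergence_zero_gain(mu, tau, gamma_target):
    """Minimum convergence for pooled gain <= gamma_target when one photon kills gain.

    With alpha = 1 the pooled gain is the zero-photon probability
    exp(-mu*tau*C); solving gives C = -ln(gamma_target)/(mu*tau).  Identical
    to ``required_convergence(mu, tau, 1 - gamma_target)``.
    """
    if not 0 < gamma_target < 1:
        raise ValueError("gamma_target must lie in (0, 1)")
    return required_convergence(mu, tau, p_target=1.0 - gamma_target)


@dataclass(frozen=True)
class PoolModel:
    """A rod pool: background ``mu`` (R*/rod/s), integration time ``tau`` (s),
    convergence ``C`` (rods) and per-photon fractional gain reduction ``alpha``."""

    mu: float
    tau: float
    C: int
    alpha: float = 0.0

    def __post_init__(self):
        expected_count(self.mu, self.tau, self.C)  # validates
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def lam(self) -> float:
        """Mean photon count per integration window, mu*tau*C."""
        return float(expected_count(self.mu, self.tau, self.C))

    @property
    def gain(self) -> float:
        """Expected pooled gain Gamma = exp(-lambda*alpha)."""
        return float(pool_gain(self.lam, self.alpha))
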