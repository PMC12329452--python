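"""Closed-form timing laws for the hard-steps model of rare evolutionary transitions.

The model considers a large population of planets, each habitable for a
window of length ``t_h``.  A fixed sequence of ``n`` "hard" steps must occur
in order; once its predecessor is complete, each step occurs with a uniform,
very low probability per unit time, so that on almost every planet the
sequence never finishes.  Conditioning on the rare planets where all ``n``
steps do complete within the window, the time of the m-th step divided by
``t_h`` follows a Beta(m, n-m+1) law, i.e. the density is proportional to
``t**(m-1) * (t_h-t)**(n-m)`` on [0, t_h].  Its mean is ``m*t_h/(n+1)``:
the conditioned steps are evenly spaced through the window and the last one
tends to fall near its end.

A delayed variant inserts a "forbidden" period delta_i after step i (whole
Earth-system reorganization, e.g. the lag between oxygenic photosynthesis
and the Great Oxidation Event) during which step i+1 cannot occur.  With
``Delta`` the cumulative forbidden time over the n-1 predecessor steps, the
conditional expectation of the final step becomes ``(n*t_h + Delta)/(n+1)``.

All durations are plain floats in a single canonical unit (Gyr throughout
the Earth scenarios); every formula is scale-invariant, so ``t_h = 1``
gives a dimensionless mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InfeasibleModelError",
    "HardStepsModel",
    "StepTimingDistribution",
    "expected_step_time",
    "expected_last_step_delayed",
    "step_time_pdf",
    "step_time_cdf",
    "step_time_quantile",
    "completion_probability_lowrate",
]


class InfeasibleModelError(ValueError):
    """Raised when cumulative forbidden time leaves no room for the steps (Delta >= t_h)."""


def _check_step_index(m: int, n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not (isinstance(m, (int, np.integer)) and 1 <= m <= n):
        raise ValueError(f"step index m must satisfy 1 <= m <= n={n}, got {m!r}")


def _check_t_h(t_h: float) -> None:
    if not (t_h > 0 and math.isfinite(t_h)):
        raise ValueError(f"habitable lifetime t_h must be positive and finite, got {t_h!r}")


@dataclass(frozen=True)
class HardStepsModel:
    """Parameter bundle for a hard-steps model.

    Parameters
    ----------
    n
        Number of hard steps (>= 1).
    t_h
        Habitable lifetime of the planet (Gyr, or any fixed unit).
    delays
        Forbidden periods ``delta_i`` immediately after step ``i`` for
        ``i = 1..n-1`` (length ``n-1``; an empty tuple means no delays).
        A forbidden period after the final step would be unobservable and
        is therefore not representable.

    A model whose cumulative delay ``Delta`` is >= ``t_h`` admits no
    successful planet; it can still be constructed (``feasible`` is then
    False) but samplers and expectations refuse to operate on it.
    """

    n: int
    t_h: float
    delays: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        _check_t_h(self.t_h)
        delays = tuple(float(d) for d in self.delays)
        if len(delays) not in (0, self.n - 1):
            raise ValueError(
                f"delays must have length n-1={self.n - 1} (or be empty), got {len(delays)}"
            )
        if len(delays) == 0:
            delays = (0.0,) * (self.n - 1)
        if any(d < 0 for d in delays):
            raise ValueError(f"forbidden periods must be non-negative, got {delays}")
        object.__setattr__(self, "delays", delays)

    @property
    def total_delay(self) -> float:
        """Cumulative forbidden time Delta over the n-1 predecessor steps."""
        return float(sum(self.delays))

    @property
    def feasible(self) -> bool:
        """True when Delta < t_h so that successful planets exist."""
        return self.total_delay < self.t_h

    @property
    def span(self) -> float:
        """Free time t_h - Delta available for the n waiting times."""
        return self.t_h - self.total_delay

    def cum_delay(self, m: int) -> float:
        """Forbidden time accumulated before step m (zero for m = 1)."""
        _check_step_index(m, self.n)
        return float(sum(self.delays[: m - 1]))

    def cum_delays(self) -> np.ndarray:
        """Vector of ``cum_delay(m)`` for m = 1..n."""
        return np.concatenate([[0.0], np.cumsum(self.delays)]) if self.n > 1 else np.zeros(1)

    def require_feasible(self) -> None:
        if not self.feasible:
            raise InfeasibleModelError(
                f"cumulative delay Delta={self.total_delay} >= t_h={self.t_h}: "
                "no planet can complete the sequence"
            )


def expected_step_time(m: int, n: int, t_h: float) -> float:
    """Conditional expectation of the m-th of n hard steps: ``m * t_h / (n + 1)``.

    The expectation is over the sub-population of planets on which all n
    steps complete within the habitable lifetime ``t_h``.
    """
    _check_step_index(m, n)
    _check_t_h(t_h)
    return m * t_h / (n + 1)


def expected_last_step_delayed(n: int, t_h: float, delta: float = 0.0) -> float:
    """Conditional expectation of the last step with total forbidden time ``delta``.

    Returns ``(n * t_h + delta) / (n + 1)``; with ``delta = 0`` this is
    ``expected_step_time(n, n, t_h)``.  Raises :class:`InfeasibleModelError`
    when ``delta >= t_h``.
    """
    _check_step_index(n, n)
    _check_t_h(t_h)
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta!r}")
    if delta >= t_h:
        raise InfeasibleModelError(f"delta={delta} >= t_h={t_h}: no successful planet exists")
    return (n * t_h + delta) / (n + 1)


def _beta_frozen(m: int, n: int, t_h: float):
    # law of t_m is Beta(m, n-m+1) scaled to [0, t_h]; scipy computes the
    # normalization via log-gamma, stable for large n
    return stats.beta(m, n - m + 1, loc=0.0, scale=t_h)


def step_time_pdf(m: int, n: int, t_h: float, t):
    """Conditional density of the m-th step time at ``t``.

    Proportional to ``t**(m-1) * (t_h - t)**(n - m)``, normalized so the
    integral over [0, t_h] is 1 (the normalizing constant is
    ``1 / (t_h**n * B(m, n-m+1))``).  By convention the density is 0
    outside [0, t_h] rather than an error.  Accepts scalars or arrays.
    """
    _check_step_index(m, n)
    _check_t_h(t_h)
    return _beta_frozen(m, n, t_h).pdf(t)


def step_time_cdf(m: int, n: int, t_h: float, t):
    """Conditional CDF of the m-th step time (regularized incomplete Beta of t/t_h)."""
    _check_step_index(m, n)
    _check_t_h(t_h)
    return _beta_frozen(m, n, t_h).cdf(t)


def step_time_quantile(m: int, n: int, t_h: float, p):
    """Inverse of :func:`step_time_cdf`; ``p`` must lie in [0, 1]."""
    _check_step_index(m, n)
    _check_t_h(t_h)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("quantile level p must lie in [0, 1]")
    return _beta_frozen(m, n, t_h).ppf(p)


@dataclass(frozen=True)
class StepTimingDistribution:
    """The conditional law of the m-th step time given all n steps fit in t_h.

    ``t / t_h`` is Beta(m, n-m+1); support is [0, t_h] and the mean is
    exactly ``m * t_h / (n + 1)``.
    """

    m: int
    n: int
    t_h: float = 1.0

    def __post_init__(self) -> None:
        _check_step_index(self.m, self.n)
        _check_t_h(self.t_h)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, self.t_h)

    @property
    def mean(self) -> float:
        return expected_step_time(self.m, self.n, self.t_h)

    def pdf(self, t):
        return step_time_pdf(self.m, self.n, self.t_h, t)

    def cdf(self, t):
        return step_time_cdf(self.m, self.n, self.t_h, t)

    def quantile(self, p):
        return step_time_quantile(self.m, self.n, self.t_h, p)


def completion_probability_lowrate(model: HardStepsModel, rates: Sequence[float]) -> float:
    """Leading-order probability that all n steps complete within t_h.

    In the low-rate regime (every ``lambda_i * t_h << 1``) the probability
    that the sequence of exponential waits, plus the forbidden periods,
    fits inside the window is ``prod(lambda_i) * (t_h - Delta)**n / n!``
    to leading order.  Returns 0 when ``Delta >= t_h`` (no planet can
    succeed).  The caller is responsible for being in the regime where the
    approximation is meaningful.
    """
    rates = tuple(float(r) for r in rates)
    if len(rates) != model.n:
        raise ValueError(f"need {model.n} rates, got {len(rates)}")
    if any(r <= 0 for r in rates):
        raise ValueError(f"rates must be positive, got {rates}")
    span = model.span
    if span <= 0:
        return 0.0
    # log-space product avoids under/overflow for large n or tiny rates
    log_p = sum(math.log(r) for r in rates) + model.n * math.log(span) - math.lgamma(model.n + 1)
    return math.exp(log_p)
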