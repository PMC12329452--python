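"""Estimating the number of hard steps from an observed emergence time.

Within the hard-steps framework, the emergence of observers is the last of
n steps, so its timing as a fraction of the habitable lifetime carries
information about n: the conditional expectation of the final step is
``(n*t_h + Delta)/(n+1)``, which creeps toward ``t_h`` as n grows.  The
primary estimator here matches that expectation to the observed emergence
time ``t_obs``: the real-valued root of ``(n*t_h + Delta)/(n+1) = t_obs``
is ``n* = (t_obs - Delta)/(t_h - t_obs)``, and the integer fit minimizes
``|<t_n> - t_obs|`` over n (ties broken toward smaller n, the more
parsimonious model).

A maximum-likelihood alternative (no-delay case only) is provided as a
clearly labelled alternative; it maximizes the density of the last of n
steps, ``n * t_obs**(n-1) / t_h**n``, and is NOT the expectation-matching
estimator the Earth scenarios are built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import InfeasibleModelError, expected_last_step_delayed

__all__ = ["ScenarioSpec", "FitResult", "fit_n_expectation", "fit_n_likelihood"]

#: near-ties in log-likelihood below this absolute gap are broken toward smaller n
_LOGLIK_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioSpec:
    """A named (t_obs, t_h, Delta) case.

    ``t_obs`` is the observed emergence time measured from the start of
    the habitable window; ``delta`` is the cumulative forbidden time over
    the n-1 predecessor steps; ``n_max`` bounds the integer search.
    """

    name: str
    t_obs: float
    t_h: float
    delta: float = 0.0
    n_max: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.t_obs < self.t_h):
            raise ValueError(
                f"need 0 < t_obs < t_h, got t_obs={self.t_obs}, t_h={self.t_h}"
            )
        if not (0 <= self.delta < self.t_h):
            raise ValueError(f"need 0 <= delta < t_h, got delta={self.delta}")
        if self.delta > self.t_obs:
            raise ValueError(
                f"delta={self.delta} > t_obs={self.t_obs}: steps cannot complete "
                "inside forbidden time"
            )
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Integer and real-valued best-fit step counts with the per-n profile.

    ``profile`` has one row per candidate n; for the expectation method its
    columns are (n, expected_last_step, misfit), for the likelihood method
    (n, loglik).  ``n_star`` is the real-valued stationary point of the
    fitting criterion.
    """

    n_best: int
    n_star: float
    profile: pd.DataFrame
    method: str

    def to_dict(self) -> dict:
        return {
            "n_best": int(self.n_best),
            "n_star": float(self.n_star),
            "method": self.method,
            "profile": self.profile.to_dict(orient="records"),
        }


def fit_n_expectation(spec: ScenarioSpec) -> FitResult:
    """Fit n by matching the expected last-step time to ``t_obs``.

    Builds the profile of ``(n*t_h + Delta)/(n+1)`` for n = 1..n_max and
    returns the n with smallest absolute misfit (ties toward smaller n),
    together with the exact real root ``n* = (t_obs - Delta)/(t_h - t_obs)``.
    """
    if spec.t_obs <= spec.delta:
        raise InfeasibleModelError(
            f"t_obs={spec.t_obs} <= delta={spec.delta}: the final step cannot "
            "fall inside forbidden time"
        )
    ns = np.arange(1, spec.n_max + 1)
    expected = np.array(
        [expected_last_step_delayed(int(n), spec.t_h, spec.delta) for n in ns]
    )
    misfit = np.abs(expected - spec.t_obs)
    n_best = int(ns[int(np.argmin(misfit))])  # argmin returns the first (smallest n) tie
    n_star = (spec.t_obs - spec.delta) / (spec.t_h - spec.t_obs)
    profile = pd.DataFrame({"n": ns, "expected_last_step": expected, "misfit": misfit})
    return FitResult(n_best=n_best, n_star=n_star, profile=profile, method="expectation")


def fit_n_likelihood(spec: ScenarioSpec) -> FitResult:
    """Fit n by maximizing the last-step density at ``t_obs`` (no delays).

    The log-likelihood is ``log n + (n-1) log t_obs - n log t_h``.  Near
    ties (within 1e-9) are broken toward smaller n; in particular at
    ``t_obs/t_h = 0.8`` the values for n=4 and n=5 coincide exactly and
    n=4 is returned.  ``n_star`` is the continuous maximizer
    ``-1/log(t_obs/t_h)``.  Only the delay-free model is supported.
    """
    if spec.delta > 0:
        raise NotImplementedError(
            "likelihood fitting is only defined for the delay-free model (delta=0)"
        )
    ns = np.arange(1, spec.n_max + 1)
    log_x = math.log(spec.t_obs) - math.log(spec.t_h)
    loglik = np.log(ns) + (ns - 1) * math.log(spec.t_obs) - ns * math.log(spec.t_h)
    near_max = np.flatnonzero(loglik >= loglik.max() - _LOGLIK_TIE_TOL)
    n_best = int(ns[near_max[0]])
    n_star = -1.0 / log_x if log_x < 0 else math.inf
    profile = pd.DataFrame({"n": ns, "loglik": loglik})
    return FitResult(n_best=n_best, n_star=n_star, profile=profile, method="likelihood")
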