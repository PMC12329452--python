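"""Monte Carlo samplers for conditioned hard-step timings.

Two routes to the same conditional law:

* ``simulate_rejection`` — forward simulation over a planet population.
  Step m occurs at ``t_{m-1} + delta_{m-1} + Exponential(lambda_m)``; a
  planet is accepted iff the last step lands within the habitable window.
  This is the mechanistic model itself and doubles as a validation oracle,
  but its acceptance probability collapses like ``prod(lambda_i) *
  (t_h-Delta)^n / n!`` — the rarity that motivates the whole framework —
  so it is only practical at moderate rates.

* ``sample_conditional_exact`` — the exact conditional law in the
  low-rate limit.  Conditioned on success, the n waiting times are jointly
  uniform over the feasible simplex, so sorting n iid uniforms on
  ``[0, t_h - Delta]`` and shifting step m by the forbidden time
  accumulated before it reproduces the conditional step-time vector
  directly.  This is the default sampler.

The rejection sampler fast-forwards over planets that die at step 1
(the overwhelming majority when rates are low): the number of consecutive
step-1 failures before a survivor is Geometric, and a survivor's first
wait is a truncated exponential.  The simulated process is identical in
law to literal planet-by-planet simulation, including the
``accepted / planets_simulated`` bookkeeping; it just does not spend a
random draw on every doomed planet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analytic import HardStepsModel, InfeasibleModelError, completion_probability_lowrate

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "AcceptanceTooLowError",
    "EmptyResultError",
    "simulate",
    "simulate_rejection",
    "sample_conditional_exact",
    "summarize",
]

logger = logging.getLogger("hardsteps.simulator")

MODES = ("rejection", "exact_lowrate")


class AcceptanceTooLowError(ValueError):
    """Projected rejection-sampler acceptance is below the configured floor."""


class EmptyResultError(ValueError):
    """A summary was requested for a result with zero accepted samples."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation run.

    ``rates`` (per-step occurrence probabilities per unit time) are only
    used in rejection mode; the exact low-rate sampler is rate-free by
    construction.  ``acceptance_floor`` guards against accidentally
    launching a rejection run whose projected acceptance makes it
    effectively unbounded.
    """

    model: HardStepsModel
    rates: Optional[tuple[float, ...]] = None
    n_target: int = 10_000
    max_planets: int = 100_000_000
    seed: Optional[int] = None
    mode: str = "exact_lowrate"
    acceptance_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.rates is not None:
            rates = tuple(float(r) for r in self.rates)
            if len(rates) != self.model.n:
                raise ValueError(f"need {self.model.n} rates, got {len(rates)}")
            if any(r <= 0 for r in rates):
                raise ValueError("rates must be positive")
            object.__setattr__(self, "rates", rates)
        elif self.mode == "rejection":
            raise ValueError("rejection mode requires per-step rates")


@dataclass(frozen=True)
class SimulationResult:
    """Accepted step-time vectors plus acceptance bookkeeping.

    ``samples`` has one row per successful planet and columns t_1..t_n,
    strictly ordered with inter-step gaps of at least the forbidden
    periods.  ``acceptance_fraction`` is accepted/planets_simulated in
    rejection mode and None for the exact sampler.  ``truncated`` flags a
    rejection run that hit ``max_planets`` before reaching ``n_target``.
    """

    samples: np.ndarray
    planets_simulated: int
    acceptance_fraction: Optional[float]
    seed: Optional[int]
    mode: str
    config: SimulationConfig
    truncated: bool = False

    @property
    def n_accepted(self) -> int:
        return self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t_{m}" for m in range(1, self.config.model.n + 1)]
        return pd.DataFrame(self.samples, columns=cols)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the sampler selected by ``config.mode``."""
    if config.mode == "rejection":
        return simulate_rejection(config)
    return sample_conditional_exact(
        config.model, config.n_target, config.seed, _config=config
    )


def sample_conditional_exact(
    model: HardStepsModel,
    n_samples: int,
    seed: Optional[int] = None,
    _config: Optional[SimulationConfig] = None,
) -> SimulationResult:
    """Draw conditioned step-time vectors exactly (low-rate limit).

    Draws n iid uniforms on ``[0, t_h - Delta]``, sorts them, and shifts
    the m-th order statistic by the forbidden time accumulated before step
    m.  Every row satisfies the ordering/gap invariants by construction.
    """
    model.require_feasible()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, model.n)) * model.span
    u.sort(axis=1)  # stable ordering; ties have probability zero
    times = u + model.cum_delays()[None, :]
    config = _config or SimulationConfig(
        model=model, n_target=n_samples, seed=seed, mode="exact_lowrate"
    )
    return SimulationResult(
        samples=times,
        planets_simulated=n_samples,
        acceptance_fraction=None,
        seed=seed,
        mode="exact_lowrate",
        config=config,
    )


def simulate_rejection(config: SimulationConfig) -> SimulationResult:
    """Forward-simulate planets and keep those completing all steps in time.

    Returns the first ``n_target`` accepted planets (in simulation order)
    or stops at ``max_planets`` with ``truncated=True``.  Identical seed
    and config give bit-identical samples.
    """
    if config.mode != "rejection":
        raise ValueError("config.mode must be 'rejection'")
    model = config.model
    model.require_feasible()
    lam = np.asarray(config.rates, dtype=float)
    n = model.n
    span = model.span  # t_h - Delta: total free time the n waits must fit in

    p_proj = min(1.0, completion_probability_lowrate(model, lam))
    if p_proj < config.acceptance_floor:
        raise AcceptanceTooLowError(
            f"projected acceptance ~{p_proj:.3g} is below the floor "
            f"{config.acceptance_floor:.3g}; use mode='exact_lowrate' instead"
        )

    # P(first wait already exceeds the free span) — a planet failing this is
    # rejected with certainty, so runs of such planets are skipped via
    # geometric counts.
    p1 = -np.expm1(-lam[0] * span)
    rng = np.random.default_rng(config.seed)

    kept: list[np.ndarray] = []
    n_kept = 0
    planets = 0
    accepted_total = 0
    survivors_total = 0
    truncated = False

    while n_kept < config.n_target and planets < config.max_planets:
        need = config.n_target - n_kept
        # expected accepted per step-1 survivor, from what we've seen or the
        # low-rate projection; sizes the batch of survivors to attempt
        rate = (
            accepted_total / survivors_total
            if survivors_total > 0 and accepted_total > 0
            else max(p_proj / p1, 1e-12)
        )
        batch = int(np.clip(1.2 * need / rate, 10_000, 10_000_000))

        g = rng.geometric(p1, size=batch)  # planets consumed per survivor
        u = rng.random(batch)
        waits_sum = -np.log1p(-u * p1) / lam[0]  # truncated Exp on [0, span]
        times = np.empty((batch, n))
        times[:, 0] = waits_sum
        alive = np.ones(batch, dtype=bool)
        for m in range(1, n):
            idx = np.flatnonzero(alive)
            w = rng.exponential(1.0 / lam[m], size=idx.size)
            s = times[idx, m - 1] + w
            times[idx, m] = s
            alive[idx] = s <= span
        accepted_idx = np.flatnonzero(alive)

        cg = np.cumsum(g)
        budget = config.max_planets - planets
        if cg[-1] > budget:
            # trim survivors that fall beyond the planet budget
            n_within = int(np.searchsorted(cg, budget, side="right"))
            if n_within == 0:
                planets += budget
                truncated = True
                break
            accepted_idx = accepted_idx[accepted_idx < n_within]
            cg = cg[:n_within]
            batch = n_within

        survivors_total += batch
        accepted_total += accepted_idx.size
        if accepted_idx.size >= need:
            accepted_idx = accepted_idx[:need]
            # count planets up to and including the last accepted one
            planets += int(cg[accepted_idx[-1]])
        else:
            planets += int(cg[-1])
        if accepted_idx.size:
            kept.append(times[accepted_idx])
            n_kept += accepted_idx.size
        logger.debug(
            "rejection batch: %d survivors, %d accepted so far, %d planets simulated",
            batch,
            n_kept,
            planets,
        )
        if planets >= config.max_planets and n_kept < config.n_target:
            truncated = True
            break

    samples = np.vstack(kept) if kept else np.empty((0, n))
    # shift the cumulative waits by the forbidden time preceding each step
    samples = samples + model.cum_delays()[None, :]
    if truncated:
        logger.warning(
            "rejection run truncated at %d planets with %d/%d accepted",
            planets,
            samples.shape[0],
            config.n_target,
        )
    return SimulationResult(
        samples=samples,
        planets_simulated=planets,
        acceptance_fraction=samples.shape[0] / planets if planets else 0.0,
        seed=config.seed,
        mode="rejection",
        config=config,
        truncated=truncated,
    )


def summarize(
    result: SimulationResult,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-step conditional summary: mean, SD, SE and selected quantiles.

    Raises :class:`EmptyResultError` on a result with no accepted rows
    rather than returning silent NaNs.
    """
    k = result.n_accepted
    if k == 0:
        raise EmptyResultError("no accepted samples to summarize")
    x = result.samples
    sd = x.std(axis=0, ddof=1) if k > 1 else np.zeros(x.shape[1])
    out = pd.DataFrame(
        {
            "mean": x.mean(axis=0),
            "sd": sd,
            "se": sd / np.sqrt(k),
        },
        index=pd.Index(range(1, x.shape[1] + 1), name="step"),
    )
    for q in quantiles:
        out[f"q{q:g}"] = np.quantile(x, q, axis=0)
    out.attrs["n_accepted"] = k
    out.attrs["acceptance_fraction"] = result.acceptance_fraction
    return out
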