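# Methods

## Model and assumptions

The hard-steps framework treats the path to an observer species as an
ordered sequence of *n* rare transitions on a planet habitable for a
window of length *t*<sub>h</sub>. Assumptions:

1. Steps are strictly sequential: step *m* can only begin once step
   *m*−1 is complete.
2. Once enabled, a step occurs with a constant probability per unit time
   (an exponential waiting time with rate λ<sub>m</sub>).
3. Every rate is *hard*: λ<sub>m</sub>·*t*<sub>h</sub> ≪ 1, so the
   unconstrained expected waiting time exceeds the habitable lifetime and
   the sequence completes only on a vanishing fraction of planets.
4. Observers exist only on planets where all *n* steps completed
   (self-selection), so all observable timing statements are conditional
   on that success.

Under assumptions 1–4 the conditional joint law of the step times
converges, as all λ<sub>m</sub>·*t*<sub>h</sub> → 0, to the law of the
order statistics of *n* iid uniforms on [0, *t*<sub>h</sub>]: the
conditional density of the successful trajectory is proportional to
Πλ<sub>m</sub>·e<sup>−small</sup> → constant on the feasible simplex.
Hence *t*<sub>m</sub>/*t*<sub>h</sub> ~ Beta(*m*, *n*−*m*+1), with mean
*m*/(*n*+1) — independent of the individual rates, which is why the
framework can say anything at all without knowing the λ's.

### Delayed variant

A forbidden period δ<sub>i</sub> ≥ 0 after step *i* (*i* = 1..*n*−1)
blocks step *i*+1. Writing Δ = Σδ<sub>i</sub> and
D(*m*) = Σ<sub>i&lt;m</sub>δ<sub>i</sub> for the forbidden time
accumulated before step *m*, substitute
*s*<sub>m</sub> = *t*<sub>m</sub> − D(*m*): the *s*<sub>m</sub> are again
sequential exponential waits that must fit in a window of length
*t*<sub>h</sub> − Δ. In the low-rate limit the *s*<sub>m</sub> are
therefore uniform order statistics on [0, *t*<sub>h</sub> − Δ], giving

⟨*t*<sub>n</sub>⟩ = *n*(*t*<sub>h</sub> − Δ)/(*n*+1) + Δ
= (*n* *t*<sub>h</sub> + Δ)/(*n*+1).

This shifted-order-statistics construction is validated against the
mechanistic rejection simulator (per-step Kolmogorov–Smirnov agreement at
α = 0.001) rather than derived from any external source. A model with
Δ ≥ *t*<sub>h</sub> admits no successful planet; such a model can be
constructed (its `feasible` flag is False, which lets the low-rate
completion probability report 0) but every sampler and expectation
refuses it with `InfeasibleModelError`. Δ = *t*<sub>h</sub> exactly is
treated as infeasible — it is a probability-zero boundary.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| *n* | number of hard steps | — | — |
| *t*<sub>h</sub> | habitable lifetime | Gyr | 1.0 in the CLI (dimensionless mode) |
| δ<sub>i</sub> | forbidden period after step *i* | Gyr | 0 |
| λ<sub>m</sub> | per-step occurrence rate (rejection sampler only) | Gyr⁻¹ | — |
| *t*<sub>obs</sub> | observed emergence time | Gyr | — |
| `n_max` | largest step count searched in fitting | — | 20 |
| `acceptance_floor` | minimum projected rejection acceptance | — | 10⁻⁹ |
| `max_planets` | planet budget for a rejection run | — | 10⁸ |

Durations are plain floats in one canonical unit (Gyr for the Earth
scenarios); every formula is scale-invariant, so *t*<sub>h</sub> = 1
gives fractions of the habitable lifetime directly.

The Earth catalog fixes: `carter_1983` (*t*<sub>h</sub> = 10,
*t*<sub>obs</sub> = 4.5), `modern_th` (*t*<sub>h</sub> = 5.7,
*t*<sub>obs</sub> = 0.8·5.7 = 4.56), `delayed` (additionally Δ = 1.5,
split (0.5, 1.0) Gyr across the two pre-human steps), and `revised_th6`
(*t*<sub>h</sub> = 6, *t*<sub>obs</sub> = 4.5). Two documented tensions:
the human emergence time is quoted both as 4.5 Gyr and as 0.8 *t*<sub>h</sub>
(which with *t*<sub>h</sub> = 5.7 gives 4.56); the catalog uses 4.56 for
the modern scenarios and leaves the 0.06 Gyr discrepancy unresolved.
And expectation matching does not give one integer across the whole
5–6 Gyr lifetime range: the quoted 3–6 span is bracketed here by its
6 Gyr end (*n* = 3); shorter lifetimes push the fit higher.

## Estimators

*Expectation matching* (primary): the integer fit minimizes
|⟨*t*<sub>n</sub>⟩ − *t*<sub>obs</sub>| over *n* = 1..`n_max`, ties to
smaller *n* (parsimony); the real-valued
*n*\* = (*t*<sub>obs</sub> − Δ)/(*t*<sub>h</sub> − *t*<sub>obs</sub>) is
the exact root of the expectation equation. This criterion reproduces all
three headline Earth fits (*n* = 1, *n* = 4, *n*\* between 2 and 3) and
is therefore the default. *n*\* is increasing in *t*<sub>obs</sub> and
decreasing in Δ — delays always reduce the inferred step count.

*Maximum likelihood* (alternative, Δ = 0 only): maximizes the last-step
density *n*·*t*<sub>obs</sub><sup>n−1</sup>/*t*<sub>h</sub><sup>n</sup>.
It is clearly labelled `method="likelihood"` and is **not** the estimator
behind the Earth scenarios. At *t*<sub>obs</sub>/*t*<sub>h</sub> = 0.8 the
likelihoods of *n* = 4 and *n* = 5 coincide exactly; near-ties within an
absolute log-likelihood gap of 10⁻⁹ are broken toward smaller *n*, since
floating point cannot represent the tie exactly. As
*t*<sub>obs</sub> → *t*<sub>h</sub> the maximizer escapes to `n_max`
(boundary behaviour, by design: the likelihood is increasing in *n* there).

## Samplers

**Exact conditional sampler** (default): draws *n* iid uniforms on
[0, *t*<sub>h</sub> − Δ], sorts each row (stable sort; ties have
probability zero) and shifts step *m* by D(*m*). This *is* the
conditional law in the low-rate limit, every draw is accepted, and all
ordering/gap invariants hold by construction.

**Rejection sampler** (mechanistic oracle): forward-simulates planets —
step *m* at *t*<sub>m−1</sub> + δ<sub>m−1</sub> + Exp(λ<sub>m</sub>) —
and accepts a planet iff *t*<sub>n</sub> ≤ *t*<sub>h</sub>. Because the
acceptance probability collapses like
Πλ<sub>m</sub>·(*t*<sub>h</sub>−Δ)<sup>n</sup>/*n*! (the rarity that
motivates the whole framework), two guards apply: a run whose projected
acceptance falls below `acceptance_floor` is refused with a pointer to
the exact sampler, and a `max_planets` budget truncates runaway runs with
a warning flag.

Implementation note: at low rates almost every planet dies at step 1
(its first wait alone overshoots the free span *t*<sub>h</sub> − Δ).
The sampler therefore fast-forwards over runs of such planets: the
number of consecutive step-1 failures before a survivor is
Geometric(p₁) with p₁ = 1 − e<sup>−λ₁(t_h−Δ)</sup>, and a survivor's
first wait is a truncated exponential on [0, *t*<sub>h</sub> − Δ].
Subsequent steps are drawn as plain exponentials with early rejection.
The resulting process — accepted samples *and* the
accepted/planets-simulated bookkeeping — is identical in law to literal
planet-by-planet simulation; it simply does not spend a random draw on
each doomed planet. The equivalence is exercised by the per-step KS
comparison against the exact sampler and by the closed-form
acceptance-fraction checks (1 − e<sup>−λt_h</sup> at *n* = 1, the
Πλ(*t*<sub>h</sub>−Δ)<sup>n</sup>/*n*! asymptote at low rates).

Reproducibility: one seeded `numpy` generator per run; draws are consumed
in a fixed order (per batch: geometric skip counts, then step-1 uniforms,
then step-2..*n* exponentials for surviving planets), and batch sizes are
a deterministic function of the counts so far, so identical seed + config
gives bit-identical samples across machines. Progress is logged per
batch (cumulative planet count) at debug level.

## Numerical choices

- Beta densities/CDFs/quantiles come from `scipy.stats.beta`, whose
  normalization is computed via log-gamma and is stable for large *n*;
  density outside [0, *t*<sub>h</sub>] is 0 by convention rather than an
  error, which keeps quadrature and plotting simple.
- The low-rate completion probability is computed in log space to avoid
  under/overflow for many steps or tiny rates.
- Quantile/CDF round-trips are accurate to 10⁻¹⁰; pdf normalization and
  the moment identity are verified by quadrature to 10⁻⁸.
- CLI numbers print with 6 significant digits; data go to stdout/files,
  logs to stderr.

## What the tests do and do not show

The test suite checks the package against *its own* probability model:
closed forms against quadrature and symmetry, the exact sampler against
the closed forms, the rejection sampler against the exact sampler, and
the estimators against round-trip and simulation-based recovery. Problem
sizes were chosen to keep the default run comfortably interactive:
10⁵ draws for mean checks (Monte Carlo standard error ≈ 5×10⁻⁴·*t*<sub>h</sub>
on the last step at *n* = 4), 2×10³ per arm for the KS sampler-equivalence
cases at λ·*t*<sub>h</sub> = 0.01 (up to ~3×10¹⁰ simulated planets per
case via the geometric fast-forward), and *n* ≤ 10 grids for the exact
identities.

None of this validates the model *as a description of Earth history*: the
generator emulates the model's idealizations (instantaneous steps, constant
rates, sharp forbidden periods, a known habitable lifetime), not real
geological records. Passing tests show internal consistency and correct
reproduction of the published Earth parameterizations, not that evolution
actually proceeded by n hard steps.

## Known limitations

- Closed forms for *intermediate* step times under the delayed model are
  not provided (only the last-step expectation); intermediate delayed
  laws are available through the samplers.
- No uncertainty interval accompanies *n*\*, no Bayesian posterior over
  *n*, and no joint inference of (*n*, Δ).
- Habitable-lifetime uncertainty is not modelled as a distribution over
  *t*<sub>h</sub>; scenarios pin single values.
- The likelihood estimator is undefined for Δ > 0 and degenerates at
  *t*<sub>obs</sub> → *t*<sub>h</sub>.
- No variance reduction beyond the exact sampler; rejection runs are
  single-threaded.
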