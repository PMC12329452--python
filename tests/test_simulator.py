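"""Monte Carlo samplers: exact conditional draws, rejection runs, summaries."""

import numpy as np
import pytest

from hardsteps.analytic import (
    HardStepsModel,
    InfeasibleModelError,
    completion_probability_lowrate,
    expected_last_step_delayed,
    expected_step_time,
    step_time_quantile,
)
from hardsteps.simulator import (
    AcceptanceTooLowError,
    EmptyResultError,
    SimulationConfig,
    SimulationResult,
    sample_conditional_exact,
    simulate,
    simulate_rejection,
    summarize,
)


def three_se(samples: np.ndarray) -> float:
    return 3.0 * samples.std(ddof=1) / np.sqrt(samples.size)


class TestExactSampler:
    def test_single_step_uniform_mean(self):
        r = sample_conditional_exact(HardStepsModel(1, 1.0), 100_000, seed=11)
        t1 = r.samples[:, 0]
        assert abs(t1.mean() - 0.5) < three_se(t1)

    def test_delayed_two_step_mean(self):
        # with delta_1 = 0.5 the last-step expectation is (2*1 + 0.5)/3
        r = sample_conditional_exact(HardStepsModel(2, 1.0, (0.5,)), 100_000, seed=12)
        t2 = r.samples[:, 1]
        assert abs(t2.mean() - 0.8333333) < three_se(t2)

    def test_four_step_last_mean(self):
        r = sample_conditional_exact(HardStepsModel(4, 1.0), 100_000, seed=13)
        t4 = r.samples[:, 3]
        assert abs(t4.mean() - 0.8) < three_se(t4)

    @pytest.mark.parametrize("delays", [(), (0.2, 0.0), (0.1, 0.3)])
    def test_ordering_and_gap_invariants(self, delays):
        model = HardStepsModel(3, 2.0, delays)
        r = sample_conditional_exact(model, 5_000, seed=14)
        t = r.samples
        assert np.all(t[:, 0] >= 0)
        assert np.all(t[:, -1] <= model.t_h)
        d = np.asarray(model.delays)
        assert np.all(np.diff(t, axis=1) >= d[None, :])

    def test_infeasible_model(self):
        with pytest.raises(InfeasibleModelError):
            sample_conditional_exact(HardStepsModel(2, 1.0, (1.2,)), 100, seed=1)

    def test_determinism(self):
        a = sample_conditional_exact(HardStepsModel(3, 1.0), 1000, seed=42)
        b = sample_conditional_exact(HardStepsModel(3, 1.0), 1000, seed=42)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize(
        "n, delta_frac",
        # a single-step model carries no forbidden periods, so n=1 only at 0
        [(1, 0.0)] + [(n, d) for n in (2, 3, 4) for d in (0.0, 0.1, 0.26)],
    )
    def test_delayed_mean_identity(self, n, delta_frac):
        """Empirical last-step mean matches (n*t_h + Delta)/(n+1)."""
        t_h = 1.0
        delays = (delta_frac * t_h / (n - 1),) * (n - 1) if n > 1 else ()
        model = HardStepsModel(n, t_h, delays)
        r = sample_conditional_exact(model, 20_000, seed=100 + 10 * n + int(100 * delta_frac))
        last = r.samples[:, -1]
        expected = expected_last_step_delayed(n, t_h, model.total_delay)
        assert abs(last.mean() - expected) < three_se(last)


class TestRejectionSampler:
    def test_low_rate_two_step_mean(self):
        cfg = SimulationConfig(
            model=HardStepsModel(2, 1.0),
            rates=(0.01, 0.01),
            n_target=2000,
            max_planets=10**10,
            seed=21,
            mode="rejection",
        )
        r = simulate_rejection(cfg)
        assert r.n_accepted == 2000
        t2 = r.samples[:, 1]
        assert abs(t2.mean() - 2 / 3) < three_se(t2)

    def test_acceptance_fraction_high_rate(self):
        # outside the low-rate regime the closed-form exponential CDF applies
        cfg = SimulationConfig(
            model=HardStepsModel(1, 1.0),
            rates=(5.0,),
            n_target=20_000,
            seed=22,
            mode="rejection",
        )
        r = simulate_rejection(cfg)
        p = 1 - np.exp(-5.0)
        se = np.sqrt(p * (1 - p) / r.planets_simulated)
        assert abs(r.acceptance_fraction - p) < 3 * se

    def test_acceptance_fraction_matches_lowrate_formula(self):
        model = HardStepsModel(2, 1.0)
        rates = (0.01, 0.01)
        cfg = SimulationConfig(
            model=model, rates=rates, n_target=2000, max_planets=10**10,
            seed=23, mode="rejection",
        )
        r = simulate_rejection(cfg)
        p_hat = r.acceptance_fraction
        se = np.sqrt(p_hat * (1 - p_hat) / r.planets_simulated)
        assert abs(p_hat - completion_probability_lowrate(model, rates)) < 3 * se

    def test_rate_invariance_of_conditional_means(self):
        """Heterogeneous low rates leave the conditional step means unchanged."""
        cfg = SimulationConfig(
            model=HardStepsModel(3, 1.0),
            rates=(0.02, 0.005, 0.01),
            n_target=500,
            max_planets=10**11,
            seed=24,
            mode="rejection",
        )
        r = simulate_rejection(cfg)
        for m in range(1, 4):
            col = r.samples[:, m - 1]
            assert abs(col.mean() - expected_step_time(m, 3, 1.0)) < three_se(col)

    def test_gap_invariants_with_delays(self):
        model = HardStepsModel(2, 1.0, (0.3,))
        cfg = SimulationConfig(
            model=model, rates=(0.05, 0.05), n_target=500, max_planets=10**10,
            seed=25, mode="rejection",
        )
        r = simulate_rejection(cfg)
        assert np.all(r.samples[:, 1] - r.samples[:, 0] >= 0.3)
        assert np.all(r.samples[:, 1] <= 1.0)

    def test_determinism(self):
        cfg = SimulationConfig(
            model=HardStepsModel(1, 1.0), rates=(1.0,), n_target=1000, seed=26,
            mode="rejection",
        )
        a, b = simulate_rejection(cfg), simulate_rejection(cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.planets_simulated == b.planets_simulated

    def test_infeasible_model_errors(self):
        cfg = SimulationConfig(
            model=HardStepsModel(2, 1.0, (1.0,)), rates=(0.1, 0.1),
            n_target=10, mode="rejection",
        )
        with pytest.raises(InfeasibleModelError):
            simulate_rejection(cfg)

    def test_acceptance_floor_refusal(self):
        cfg = SimulationConfig(
            model=HardStepsModel(3, 1.0),
            rates=(1e-4, 1e-4, 1e-4),
            n_target=10,
            seed=1,
            mode="rejection",
        )
        with pytest.raises(AcceptanceTooLowError, match="exact_lowrate"):
            simulate_rejection(cfg)

    def test_max_planets_truncation(self):
        cfg = SimulationConfig(
            model=HardStepsModel(2, 1.0),
            rates=(0.01, 0.01),
            n_target=10**6,  # unreachable within the planet budget
            max_planets=200_000,
            seed=27,
            mode="rejection",
        )
        r = simulate_rejection(cfg)
        assert r.truncated
        assert r.n_accepted < 10**6
        assert r.planets_simulated <= cfg.max_planets

    def test_config_validation(self):
        with pytest.raises(ValueError, match="rates"):
            SimulationConfig(model=HardStepsModel(2, 1.0), mode="rejection")
        with pytest.raises(ValueError):
            SimulationConfig(model=HardStepsModel(2, 1.0), rates=(0.1,), mode="rejection")
        with pytest.raises(ValueError):
            SimulationConfig(model=HardStepsModel(2, 1.0), mode="bogus")

    def test_simulate_dispatch(self):
        cfg = SimulationConfig(model=HardStepsModel(2, 1.0), n_target=100, seed=3)
        assert simulate(cfg).mode == "exact_lowrate"


class TestSummarize:
    def test_three_step_means(self):
        r = sample_conditional_exact(HardStepsModel(3, 1.0), 20_000, seed=31)
        table = summarize(r)
        for m, target in zip([1, 2, 3], [0.25, 0.5, 0.75]):
            assert abs(table.loc[m, "mean"] - target) < 3 * table.loc[m, "se"]

    def test_single_row(self):
        r = sample_conditional_exact(HardStepsModel(2, 1.0), 1, seed=32)
        table = summarize(r)
        assert np.array_equal(table["mean"].to_numpy(), r.samples[0])
        assert np.all(table["sd"] == 0.0)

    def test_empty_result_errors(self):
        cfg = SimulationConfig(model=HardStepsModel(1, 1.0), n_target=1)
        empty = SimulationResult(
            samples=np.empty((0, 1)), planets_simulated=0, acceptance_fraction=0.0,
            seed=None, mode="rejection", config=cfg,
        )
        with pytest.raises(EmptyResultError):
            summarize(empty)

    def test_uniform_quantiles_within_dkw_band(self):
        """Empirical CDF of the single-step law stays inside the DKW envelope."""
        n = 50_000
        r = sample_conditional_exact(HardStepsModel(1, 1.0), n, seed=33)
        x = np.sort(r.samples[:, 0])
        ecdf = np.arange(1, n + 1) / n
        true = x  # uniform CDF on [0, 1]
        eps = np.sqrt(np.log(2 / 0.001) / (2 * n))
        assert np.max(np.abs(ecdf - true)) < eps
        # spot-check the quantile function against empirical quantiles
        for p in (0.1, 0.5, 0.9):
            assert abs(np.quantile(x, p) - step_time_quantile(1, 1, 1.0, p)) < eps
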