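import numpy as np
import pytest

from undocpop import (
    ParameterRanges,
    ParameterSet,
    conservative_trajectory,
    percentile_of,
    run_simulation,
    sample_parameters,
    simulate_trial,
)
from undocpop.monte_carlo import default_e1_crosser_lower, sample_trial_parameters

from conftest import make_inputs

ENTRY_YEARS = np.arange(1990, 2017)


def frozen_conservative_ranges():
    """All parameter distributions collapsed to the conservative preset."""
    return ParameterRanges(
        apprehension_rate_early=(0.39, 0.39),
        overstay_multiplier=(1.0, 1.0),
        e1_overstay=(0.40, 0.40),
        e1_crosser_upper=0.40,
        e1_crosser_lower=lambda y: np.full(np.shape(y), 0.40),
        e_mid=(0.04, 0.04),
        e_late=(0.01, 0.01),
        mortality=(0.007, 0.007),
    )


class TestParameterSampling:
    def test_same_seed_identical_parameter_set(self):
        a = sample_parameters(np.random.default_rng(42))
        b = sample_parameters(np.random.default_rng(42))
        assert a == b

    def test_marginals_cover_their_ranges(self):
        rng = np.random.default_rng(5)
        tp = sample_trial_parameters(ParameterRanges(), ENTRY_YEARS, 100_000, rng)
        checks = {
            "apprehension_rate_early": (tp.apprehension_rate_early, 0.25, 0.40),
            "overstay_multiplier": (tp.overstay_multiplier, 0.5, 1.5),
            "e1_overstay": (tp.e1_overstay, 0.25, 0.50),
            "e_mid": (tp.e_mid, 0.01, 0.05),
            "e_late": (tp.e_late, 0.005, 0.02),
            "mortality": (tp.mortality, 0.005, 0.010),
        }
        for name, (draws, lo, hi) in checks.items():
            assert draws.min() >= lo and draws.max() <= hi, name
            se = (hi - lo) / np.sqrt(12 * len(draws))
            assert abs(draws.mean() - (lo + hi) / 2) < 3 * se, name

    def test_cohort_first_year_bounds_rise_with_entry_year(self):
        lower = default_e1_crosser_lower(ENTRY_YEARS)
        assert lower[0] == pytest.approx(0.10)
        assert lower[-1] == pytest.approx(0.25)
        assert np.all(np.diff(lower) >= 0)
        rng = np.random.default_rng(6)
        tp = sample_trial_parameters(ParameterRanges(), ENTRY_YEARS, 20_000, rng)
        assert np.all(tp.e1_crosser >= lower[None, :] - 1e-12)
        assert np.all(tp.e1_crosser <= 0.50 + 1e-12)

    def test_negative_correlation_is_imposed(self):
        rng = np.random.default_rng(7)
        tp = sample_trial_parameters(ParameterRanges(), ENTRY_YEARS, 100_000, rng)
        for cohort in (0, 13, 26):
            r = np.corrcoef(tp.apprehension_rate_early, tp.e1_crosser[:, cohort])[0, 1]
            assert r == pytest.approx(-0.5, abs=0.02)

    def test_other_draws_uncorrelated_with_apprehension_rate(self):
        rng = np.random.default_rng(8)
        tp = sample_trial_parameters(ParameterRanges(), ENTRY_YEARS, 100_000, rng)
        for other in (tp.e_mid, tp.overstay_multiplier, tp.mortality):
            r = np.corrcoef(tp.apprehension_rate_early, other)[0, 1]
            assert abs(r) < 0.02


class TestSimulateTrial:
    def test_same_seed_identical_trajectory(self, us_inputs):
        params = sample_parameters(np.random.default_rng(11))
        t1 = simulate_trial(params, us_inputs, np.random.default_rng(99))
        t2 = simulate_trial(params, us_inputs, np.random.default_rng(99))
        assert np.array_equal(t1.population, t2.population)

    def test_zero_flow_population_is_poisson_at_initial_mean(self):
        # no inflows, no outflows: every year is Poisson(3.5M)
        inputs = make_inputs(apprehensions=0.0, visas=0.0, overstay_rate=0.0)
        params = ParameterSet(e1_overstay=0.0, e_mid=0.0, e_late=0.0, mortality=0.0)
        rng = np.random.default_rng(13)
        draws = np.array(
            [simulate_trial(params, inputs, rng).value(2016) for _ in range(3000)]
        )
        lam = 3.5e6
        assert draws.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / 3000))
        assert draws.var(ddof=1) == pytest.approx(lam, rel=0.1)

    def test_trial_mean_matches_deterministic_run(self, us_inputs):
        # frozen conservative parameters: only Poisson noise remains
        res = run_simulation(
            us_inputs, trials=4000, seed=21, ranges=frozen_conservative_ranges()
        )
        expected = conservative_trajectory(us_inputs).population
        se = np.sqrt(expected / res.trials)
        assert np.all(np.abs(res.mean - expected) < 4 * se)

    def test_poisson_variance_matches_mean_given_frozen_parameters(self, us_inputs):
        res = run_simulation(
            us_inputs, trials=4000, seed=22, ranges=frozen_conservative_ranges()
        )
        v = res.samples.var(axis=0, ddof=1)
        assert np.allclose(v, res.mean, rtol=0.15)


class TestRunSimulation:
    def test_reproducible_from_master_seed(self, us_inputs):
        r1 = run_simulation(us_inputs, trials=500, seed=17)
        r2 = run_simulation(us_inputs, trials=500, seed=17)
        assert np.array_equal(r1.samples, r2.samples)

    def test_single_trial_summary_is_the_trajectory(self, us_inputs):
        res = run_simulation(us_inputs, trials=1, seed=17)
        assert res.samples.shape == (1, 27)
        assert np.array_equal(res.mean, res.samples[0])
        assert np.array_equal(res.percentile(2.5), res.samples[0])

    def test_sample_count_and_interval_ordering(self, us_inputs):
        res = run_simulation(us_inputs, trials=2000, seed=18)
        assert res.samples.shape == (2000, len(us_inputs.years))
        lo, mid, hi = res.percentile(2.5), res.percentile(50), res.percentile(97.5)
        assert np.all(lo <= mid) and np.all(mid <= hi)
        assert np.all(lo <= res.mean) and np.all(res.mean <= hi)

    def test_correlation_reduces_variance_not_mean(self, us_inputs):
        corr = run_simulation(us_inputs, trials=20_000, seed=19)
        indep = run_simulation(
            us_inputs, trials=20_000, seed=19, ranges=ParameterRanges(correlation=0.0)
        )
        v_corr = corr.samples.var(axis=0)
        v_indep = indep.samples.var(axis=0)
        assert np.all(v_corr < v_indep)
        # the mean moves by at most a small fraction of the spread
        sd = indep.samples.std(axis=0)
        assert np.all(np.abs(corr.mean - indep.mean) < 0.15 * sd)

    def test_raising_early_apprehension_rate_lowers_every_year(self, us_inputs):
        lo = run_simulation(
            us_inputs, trials=5000, seed=23,
            ranges=ParameterRanges(apprehension_rate_early=(0.30, 0.30)),
        )
        hi = run_simulation(
            us_inputs, trials=5000, seed=23,
            ranges=ParameterRanges(apprehension_rate_early=(0.40, 0.40)),
        )
        assert np.all(hi.mean <= lo.mean)


class TestPercentileOf:
    def test_value_below_all_samples(self):
        assert percentile_of(-1.0, np.arange(100)) == 0.0

    def test_median_sits_near_fifty(self, rng):
        samples = rng.normal(size=10_001)
        assert percentile_of(np.median(samples), samples) == pytest.approx(50.0, abs=0.5)

    def test_midpoint_tie_convention(self):
        assert percentile_of(5, np.array([1, 5, 5, 9])) == pytest.approx(50.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            percentile_of(1.0, np.array([]))
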