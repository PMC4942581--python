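"""Learning-path analyses: scenario curves, random-walk null, trend fits."""

import math

import numpy as np
import pytest
from scipy import stats

from chunkopt.chunking import ALL_HALT, ChunkStructure, enumerate_structures
from chunkopt.learning import (
    COMPLEXITY_RANGE,
    DailySummary,
    GaussianStep,
    ScenarioSpec,
    ScoredTrial,
    complexity_curve,
    cumulative_complexity,
    daily_summaries,
    efficiency_curve,
    fit_day_transition_model,
    fit_degenerate_trend,
    percentile_score,
    prevalence_efficiency_correlation,
    rank_scenarios,
    simulate_null_walkers,
)
from chunkopt.pareto import tradeoff_landscape


def scored(trial_id, day, structure, jerk=1.0):
    return ScoredTrial(trial_id=trial_id, day=day, structure=structure,
                       efficiency=-jerk, squared_jerk=jerk)


class TestDailySummaries:
    def test_identical_trials(self):
        s = ChunkStructure.from_lengths("5-5")
        rows = [scored(i, 1, s) for i in range(10)]
        (summary,) = daily_summaries(rows)
        assert summary.n_unique_structures == 1
        assert summary.mean_consecutive_hamming == 0.0
        assert summary.n_trials == 10

    def test_random_structures_hamming_near_4_5(self):
        rng = np.random.default_rng(5)
        rows = [scored(i, 1, ChunkStructure(10, tuple(rng.integers(0, 2, 9))))
                for i in range(4000)]
        (summary,) = daily_summaries(rows)
        se = math.sqrt(9 * 0.25 / 4000)
        assert abs(summary.mean_consecutive_hamming - 4.5) < 4 * se


class TestScenarioCurves:
    @pytest.mark.parametrize("rate", [0.05, 0.1, 0.25, 0.4, 1.0])
    def test_efficiency_curve_endpoints(self, rate):
        assert efficiency_curve(0.0, rate) == pytest.approx(0.0, abs=1e-12)
        assert efficiency_curve(1.0, rate) == pytest.approx(1.0, rel=1e-12)

    def test_large_rate_limit_is_linear(self):
        t = np.linspace(0, 1, 11)
        np.testing.assert_allclose(efficiency_curve(t, 1e6), t, atol=1e-4)

    def test_smaller_curvature_hugs_frontier(self):
        e = np.linspace(0.05, 0.95, 19)
        prev = None
        for c in (0.05, 0.25, 0.5, 1.0, 2.0):
            x = complexity_curve(e, c)
            assert np.all(np.diff(x) > 0)
            if prev is not None:
                assert np.all(prev < x)
            prev = x

    def test_half_curvature_is_diagonal(self):
        e = np.linspace(0, 1, 11)
        np.testing.assert_allclose(complexity_curve(e, 0.5), e, atol=1e-12)

    def test_linear_scenario_integrates_to_half(self):
        assert cumulative_complexity(ScenarioSpec(math.inf, 0.5)) == \
            pytest.approx(0.5, abs=1e-8)

    def test_cumulative_monotone_in_curvature(self):
        for rate in (0.1, 0.25, 0.4):
            vals = [cumulative_complexity(ScenarioSpec(rate, c))
                    for c in (0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)]
            assert np.all(np.diff(vals) > 0)

    def test_rank_table_ties_deterministic(self):
        df = rank_scenarios(curvatures=(0.3, 0.3, 0.3), rates=(0.25,))
        assert list(df["rank"]) == [1, 2, 3]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ScenarioSpec(0.0, 0.5)
        with pytest.raises(ValueError):
            complexity_curve(0.5, -1.0)


class TestTransitionModel:
    def _summaries(self, path):
        return [DailySummary(day=i + 1, mean_efficiency=0.0,
                             mean_complexity=c, n_trials=1,
                             n_unique_structures=1,
                             mean_consecutive_hamming=0.0)
                for i, c in enumerate(path)]

    def test_constant_path(self):
        g = fit_day_transition_model(self._summaries([4.0] * 10))
        assert g.mean == 0.0 and g.sd == 0.0

    def test_arithmetic_path(self):
        g = fit_day_transition_model(self._summaries(np.linspace(4, 6, 11)))
        assert g.mean == pytest.approx(0.2)
        assert g.sd == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        steps = rng.normal(0.05, 0.2, size=50)
        path = 4.0 + np.concatenate([[0.0], np.cumsum(steps)])
        g = fit_day_transition_model(self._summaries(path))
        assert abs(g.mean - 0.05) < 3 * 0.2 / math.sqrt(50)
        assert abs(g.sd - 0.2) < 3 * 0.2 / math.sqrt(2 * 49)

    def test_too_few_days(self):
        with pytest.raises(ValueError):
            fit_day_transition_model(self._summaries([4.0, 4.1]))


class TestNullWalkers:
    def test_degenerate_transition_stays_put(self):
        null = simulate_null_walkers(5.0, 10, GaussianStep(0.0, 0.0),
                                     n_walkers=100, seed=0)
        np.testing.assert_allclose(null.walker_mean_complexities, 5.0)

    def test_seed_reproducibility(self):
        a = simulate_null_walkers(4.0, 15, GaussianStep(0.1, 0.3), 500, seed=9)
        b = simulate_null_walkers(4.0, 15, GaussianStep(0.1, 0.3), 500, seed=9)
        np.testing.assert_array_equal(a.walker_mean_complexities,
                                      b.walker_mean_complexities)

    def test_drift_increases_with_horizon(self):
        short = simulate_null_walkers(4.0, 5, GaussianStep(0.2, 0.1), 2000, seed=1)
        long = simulate_null_walkers(4.0, 20, GaussianStep(0.2, 0.1), 2000, seed=1)
        assert long.walker_mean_complexities.mean() > \
            short.walker_mean_complexities.mean()

    def test_states_clipped_to_attainable_range(self):
        null = simulate_null_walkers(9.9, 30, GaussianStep(1.0, 0.5), 500, seed=3)
        assert null.walker_mean_complexities.max() <= COMPLEXITY_RANGE[1] + 1e-9

    def test_percentile_of_minimal_path_is_zero(self):
        null = simulate_null_walkers(5.0, 10, GaussianStep(0.05, 0.2), 2000, seed=4)
        lo = [COMPLEXITY_RANGE[0]] * 10
        assert percentile_score(lo, null) <= 1.0

    def test_percentile_of_expected_path_near_50(self):
        g = GaussianStep(0.05, 0.2)
        null = simulate_null_walkers(5.0, 12, g, 5000, seed=5)
        observed = simulate_null_walkers(5.0, 12, g, 4001, seed=77)
        # median walker of an independent draw sits near the null's centre
        median_path_stat = float(np.median(observed.walker_mean_complexities))
        frac = np.mean(null.walker_mean_complexities < median_path_stat)
        assert abs(100 * frac - 50.0) < 5.0

    def test_percentile_invariant_to_walker_order(self):
        null = simulate_null_walkers(5.0, 10, GaussianStep(0.0, 0.3), 1000, seed=6)
        obs = [5.0] * 10
        p1 = percentile_score(obs, null)
        null.walker_mean_complexities = null.walker_mean_complexities[::-1].copy()
        assert percentile_score(obs, null) == p1

    def test_scenario1_learning_path_certified_cost_effective(self):
        # a frontier-hugging (scenario-1) learner over a 51-day course,
        # tested against a null fitted to its own day-to-day steps
        n_days = 51
        lo, hi = COMPLEXITY_RANGE
        t = np.linspace(0, 1, n_days)
        path = lo + (hi - lo) * complexity_curve(efficiency_curve(t, 0.25), 0.05)
        steps = np.diff(path)
        g = GaussianStep(float(steps.mean()), float(steps.std(ddof=1)))
        null = simulate_null_walkers(path[0], n_days, g, 5000, seed=12)
        assert percentile_score(path, null) < 5.0

    def test_day_count_mismatch_rejected(self):
        null = simulate_null_walkers(5.0, 10, GaussianStep(0.0, 0.3), 100, seed=0)
        with pytest.raises(ValueError):
            percentile_score([5.0] * 9, null)


def simulate_decay_trials(rng, b=-0.02, n_sets=8, per_set=200, sigma=0.25,
                          amplitudes=None):
    """Planted exponential-decay squared jerk across degenerate sets."""
    sets = [ChunkStructure.from_lengths(l) for l in
            ("10", "5-5", "4-6", "3-7", "2-8", "3-3-4", "2-3-5", "1-4-5",
             "2-2-6", "1-2-7")][:n_sets]
    if amplitudes is None:
        amplitudes = np.exp(rng.normal(0.0, 0.5, size=n_sets))
    rows, tid = [], 0
    for i, s in enumerate(sets):
        for r in range(per_set):
            jerk = amplitudes[i] * math.exp(b * r) * \
                math.exp(rng.normal(0.0, sigma))
            rows.append(ScoredTrial(trial_id=tid, day=1 + r // 50,
                                    structure=s, efficiency=-jerk,
                                    squared_jerk=jerk))
            tid += 1
    rng.shuffle(rows)
    # interleave so trial order mixes sets; repeat index is per-set cumcount
    rows.sort(key=lambda t: t.trial_id)
    return rows, amplitudes


class TestDegenerateTrend:
    def test_recovers_planted_decay(self):
        rng = np.random.default_rng(10)
        trials, _ = simulate_decay_trials(rng, b=-0.02, per_set=400)
        fit = fit_degenerate_trend(trials)
        assert fit.rate_b == pytest.approx(-0.02, abs=3 * fit.rate_se)
        assert fit.z_statistic < -1.96
        assert fit.p_value < 0.05

    def test_offsets_track_amplitude_order(self):
        rng = np.random.default_rng(11)
        amps = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        trials, _ = simulate_decay_trials(rng, b=-0.01, per_set=300,
                                          sigma=0.1, amplitudes=amps)
        fit = fit_degenerate_trend(trials)
        sigs = ["-".join(map(str, ChunkStructure.from_lengths(l).signature))
                for l in ("10", "5-5", "4-6", "3-7", "2-8", "3-3-4",
                          "2-3-5", "1-4-5")]
        offsets = [fit.set_offsets[s] for s in sigs]
        assert stats.spearmanr(offsets, amps).statistic == pytest.approx(1.0)

    def test_too_few_sets_rejected(self):
        s = ChunkStructure.from_lengths("5-5")
        trials = [scored(i, 1, s, jerk=1.0) for i in range(50)]
        with pytest.raises(ValueError):
            fit_degenerate_trend(trials)


@pytest.fixture(scope="module")
def landscape():
    return tradeoff_landscape()


class TestPrevalenceCorrelation:
    def _trials_weighted_by(self, landscape, weight_fn, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        structs = [p.structure for p in landscape]
        w = np.asarray([weight_fn(p) for p in landscape], dtype=float)
        w = w / w.sum()
        idx = rng.choice(len(structs), size=n, p=w)
        return [scored(i, 1, structs[j]) for i, j in enumerate(idx)]

    def test_efficiency_seeking_generator_positive(self, landscape):
        effs = np.asarray([p.efficiency for p in landscape])
        lo, hi = effs.min(), effs.max()

        def weight(p):
            return 0.01 + ((p.efficiency - lo) / (hi - lo)) ** 4

        trials = self._trials_weighted_by(landscape, weight, seed=1)
        rho, p = prevalence_efficiency_correlation(trials, landscape)
        assert rho > 0.1 and p < 0.05

    def test_uniform_generator_null(self, landscape):
        trials = self._trials_weighted_by(landscape, lambda p: 1.0, seed=2)
        rho, p = prevalence_efficiency_correlation(trials, landscape)
        assert abs(rho) < 0.15

    def test_per_set_mode_runs(self, landscape):
        trials = self._trials_weighted_by(landscape, lambda p: 1.0, seed=3)
        rho, p = prevalence_efficiency_correlation(trials, landscape,
                                                   mode="per_set")
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0

    def test_single_member_sets_skipped(self, landscape):
        # a dataset visiting only ALL-HALT (its degenerate set has 1 member)
        trials = [scored(i, 1, ALL_HALT) for i in range(20)]
        with pytest.raises(ValueError):
            prevalence_efficiency_correlation(trials, landscape)
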