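"""Start drawing, multistart bookkeeping, determinism, and hierarchy contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sspflanker import (
    PROFILES,
    SimulationConfig,
    SSPParameters,
    START_MEANS,
    STAGE_UPPER,
    simulate_dataset,
)
from sspflanker.fitting import (
    FitProfile,
    HierarchicalEstimates,
    StartDistribution,
    compose_within_transformed,
    delta_start_distribution,
    draw_starts,
    fit_dataset,
    fit_hierarchical,
    population_start_distribution,
)
from sspflanker.params import N_PARAMS, PARAM_NAMES


class TestDrawStarts:
    def test_collapsed_bounds_yield_the_point(self, rng):
        dist = StartDistribution(
            means=np.ones(6), sds=np.ones(6), lower=np.full(6, 2.0), upper=np.full(6, 2.0), n_starts=7
        )
        starts = draw_starts(dist, rng)
        assert np.all(starts == 2.0)

    def test_population_starts_within_printed_bounds(self, rng):
        dist = population_start_distribution(100)
        starts = draw_starts(dist, rng)
        assert starts.shape == (100, 6)
        assert np.all(starts >= dist.lower) and np.all(starts <= dist.upper)

    def test_truncated_normal_moments_oracle(self, rng):
        """Empirical means match scipy's truncated-normal moments within 3 SE."""
        dist = population_start_distribution(100_000)
        starts = draw_starts(dist, rng)
        for j in range(N_PARAMS):
            a = (dist.lower[j] - dist.means[j]) / dist.sds[j]
            b = (dist.upper[j] - dist.means[j]) / dist.sds[j]
            ref = stats.truncnorm(a, b, loc=dist.means[j], scale=dist.sds[j])
            se = ref.std() / np.sqrt(len(starts))
            assert abs(starts[:, j].mean() - ref.mean()) < 3 * se

    def test_delta_bounds_keep_composition_in_stage_bounds(self, rng):
        base = np.asarray(START_MEANS)
        dist = delta_start_distribution(base, 500)
        deltas = draw_starts(dist, rng)
        composed = base + deltas
        assert np.all(composed >= -1e-12)
        assert np.all(composed <= STAGE_UPPER + 1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            StartDistribution(np.zeros(6), np.ones(6), np.ones(6), np.zeros(6))


@pytest.fixture(scope="module")
def small_data():
    params = SSPParameters(*START_MEANS)
    return simulate_dataset(params, 1500, 1500, SimulationConfig(), np.random.default_rng(42))


class TestMultistart:
    def test_zero_iterations_returns_best_start(self, small_data, rng):
        profile = FitProfile(n_starts=3, n_sim=400, maxiter=0, n_polish=0)
        res = fit_dataset(small_data, profile=profile, rng=rng)
        # three drawn starts plus the deterministic start-distribution mean
        assert res.n_starts_run == 4
        assert res.objective == res.start_objectives.min()

    def test_best_objective_bounds_all_starts(self, small_data, rng):
        profile = FitProfile(n_starts=4, n_sim=400, maxiter=25, n_polish=0, explore_sizes=(0.5,))
        res = fit_dataset(small_data, profile=profile, rng=rng)
        assert res.objective <= res.start_objectives.min() + 1e-9

    def test_more_starts_never_increase_objective(self, small_data):
        """Minimum over a superset of starts, with identical CRN seeds."""
        profile = FitProfile(n_starts=2, n_sim=400, maxiter=20, n_polish=0, explore_sizes=(0.5,))
        dist = population_start_distribution(4)
        starts = draw_starts(dist, np.random.default_rng(5))
        res_small = fit_dataset(small_data, profile=profile, rng=np.random.default_rng(9), starts=starts[:2])
        res_large = fit_dataset(small_data, profile=profile, rng=np.random.default_rng(9), starts=starts)
        assert res_large.objective <= res_small.objective + 1e-9

    def test_bitwise_determinism(self, small_data, mini_profile):
        a = fit_dataset(small_data, profile=mini_profile, rng=np.random.default_rng(3))
        b = fit_dataset(small_data, profile=mini_profile, rng=np.random.default_rng(3))
        assert np.array_equal(a.parameters, b.parameters)
        assert a.objective == b.objective

    def test_parameters_within_stage_bounds(self, small_data, mini_profile, rng):
        res = fit_dataset(small_data, profile=mini_profile, rng=rng)
        assert np.all(res.parameters >= 0.0)
        assert np.all(res.parameters <= STAGE_UPPER)


class TestHierarchy:
    def test_compose_within_transformed_additivity(self):
        pop = np.asarray(START_MEANS)
        cond = {"FA": np.full(6, -0.5), "OM": np.zeros(6), "C": np.full(6, 0.25)}
        part = {"P01": np.full(6, 0.1), "P02": np.full(6, -0.1)}
        table = compose_within_transformed(pop, cond, part)
        assert len(table) == 6
        p1_fa = table.query("participant == 'P01' and condition == 'FA'").iloc[0]
        p1_om = table.query("participant == 'P01' and condition == 'OM'").iloc[0]
        for name in PARAM_NAMES:
            # differences across conditions equal the condition-delta differences
            assert p1_fa[name] - p1_om[name] == pytest.approx(-0.5, abs=1e-12)

    def test_zero_deltas_reproduce_population(self):
        pop = np.asarray(START_MEANS)
        est = HierarchicalEstimates(
            population=pop,
            condition_deltas={c: np.zeros(6) for c in ("FA", "OM", "C")},
            participant_deltas={p: np.zeros(6) for p in ("P01", "P02")},
        )
        table = est.within_transformed()
        for name, value in zip(PARAM_NAMES, pop):
            assert np.all(table[name] == value)

    def test_observation_values_require_noise_stage(self):
        est = HierarchicalEstimates(
            population=np.asarray(START_MEANS),
            condition_deltas={"C": np.zeros(6)},
            participant_deltas={"P01": np.zeros(6)},
        )
        with pytest.raises(ValueError, match="noise"):
            est.observation_values()

    def test_full_hierarchy_smoke(self, mini_profile):
        """Stages 1-4 run end to end on a tiny study; composed observation
        sums respect the stage bounds and the run is seed-reproducible."""
        from sspflanker.synthetic_data import StudyDesign, generate_study

        design = StudyDesign(n_participants=2, trials_per_condition=32)
        trials, _ = generate_study(design, SimulationConfig(), np.random.default_rng(0))

        est, results = fit_hierarchical(
            trials, SimulationConfig(), mini_profile, np.random.default_rng(1)
        )
        obs = est.observation_values()
        assert len(obs) == 6
        vals = obs[list(PARAM_NAMES)].to_numpy()
        assert np.all(vals >= 0.0) and np.all(vals <= STAGE_UPPER)

        est2, _ = fit_hierarchical(
            trials, SimulationConfig(), mini_profile, np.random.default_rng(1)
        )
        assert np.array_equal(est.population, est2.population)
        for c in est.condition_deltas:
            assert np.array_equal(est.condition_deltas[c], est2.condition_deltas[c])
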