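"""CDF/CAF summaries, binomial deviance, chi-square and RMSEA."""

import math

import numpy as np
import pandas as pd
import pytest

from sspflanker.summaries import (
    CAF_PROBS,
    CDF_PROBS,
    chi_square,
    classify_cells,
    goodness_of_fit,
    neg2_log_binomial,
    predicted_proportions,
    rmsea,
    summarize,
    summarize_by_type,
    summary_to_frame,
)
from conftest import make_trials


class TestSummarize:
    def test_default_probabilities(self):
        trials = make_trials(rt_correct=np.linspace(300, 600, 50), rt_error=[350, 380])
        s = summarize(trials, "congruent")
        assert s.cdf_probs == (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        assert s.caf_probs == (0.25, 0.5, 0.75, 1.0)

    def test_identical_rts_all_correct(self):
        trials = make_trials(rt_correct=[400.0] * 100, rt_error=[])
        s = summarize(trials, "congruent")
        assert np.all(s.cdf_edges == 400.0)
        assert np.all(s.caf_accuracy == 1.0)
        assert s.n_trials == 100
        assert s.cell_counts.sum() == 100

    def test_fast_correct_slow_error_caf(self):
        """50 correct at 300 ms, 50 errors at 600 ms: accuracy 1 below the
        median and 0 above it, by direct counting."""
        trials = make_trials(rt_correct=[300.0] * 50, rt_error=[600.0] * 50)
        s = summarize(trials, "congruent")
        assert np.allclose(s.caf_accuracy, [1.0, 1.0, 0.0, 0.0])
        # error cells carry 25 errors in each of the two upper quartiles
        assert list(s.cell_counts[-4:]) == [0, 0, 25, 25]

    def test_counts_partition_trials(self, mean_params, sim_config, rng):
        from sspflanker import simulate_dataset

        df = simulate_dataset(mean_params, 400, 400, sim_config, rng)
        for s in summarize_by_type(df).values():
            assert s.cell_counts.sum() == s.n_trials
            assert np.all(np.diff(s.cdf_edges) >= 0)
            assert np.all((s.caf_accuracy >= 0) & (s.caf_accuracy <= 1))

    def test_empty_cell_is_named(self):
        empty = make_trials(rt_correct=[], rt_error=[])
        with pytest.raises(ValueError, match="incongruent"):
            summarize(empty, "incongruent")

    def test_no_correct_trials_rejected(self):
        trials = make_trials(rt_correct=[], rt_error=[300.0, 400.0])
        with pytest.raises(ValueError, match="correct"):
            summarize(trials, "congruent")

    def test_serialization_one_row_per_cell(self):
        trials = make_trials(rt_correct=np.linspace(250, 700, 80), rt_error=[320, 410, 520])
        frame = summary_to_frame(summarize(trials, "congruent"))
        assert len(frame) == 10
        assert frame["count"].sum() == 83


class TestPredictedProportions:
    def test_self_consistency(self, rng):
        """Classifying the summarized data itself reproduces the observed
        proportions within one-trial resolution."""
        rt = rng.gamma(9.0, 40.0, size=400) + 200
        acc = (rng.random(400) < 0.85).astype(int)
        trials = make_trials(rt_correct=rt[acc == 1], rt_error=rt[acc == 0])
        s = summarize(trials, "congruent")
        pi = predicted_proportions(s, rt, acc, floor=1e-12)
        assert np.max(np.abs(pi - s.observed_proportions)) <= 2.0 / s.n_trials

    def test_uniform_rts_give_near_equal_interior_bins(self, rng):
        """Uniform simulated RTs across a uniform-quantile CDF grid fill the
        interior bins according to the quantile spacing (analytic oracle)."""
        obs = make_trials(rt_correct=np.linspace(200, 1000, 500), rt_error=[])
        s = summarize(obs, "congruent")
        sim_rt = rng.uniform(200, 1000, 50_000)
        pi = predicted_proportions(s, sim_rt, np.ones_like(sim_rt, dtype=int))
        # expected CDF masses equal the quantile increments (.1,.2,.2,.2,.2,.1)
        expected = np.diff(np.concatenate([[0], np.asarray(CDF_PROBS)]))
        assert np.max(np.abs(pi[:6] - expected)) < 0.01

    def test_degenerate_mass_below_first_quantile(self):
        obs = make_trials(rt_correct=np.linspace(400, 800, 100), rt_error=[])
        s = summarize(obs, "congruent")
        sim_rt = np.full(1000, 250.0)
        pi = predicted_proportions(s, sim_rt, np.ones(1000, dtype=int))
        assert pi[0] > 0.99

    def test_classify_matches_manual_binning(self):
        obs = make_trials(rt_correct=[300, 400, 500, 600, 700], rt_error=[350, 650])
        s = summarize(obs, "congruent")
        counts = classify_cells(s, np.array([299.0, 450.0, 9999.0]), np.array([1, 1, 0]))
        assert counts.sum() == 3
        assert counts[0] == 1  # 299 in the first CDF bin
        assert counts[-1] == 1  # 9999 error in the last CAF bin


class TestDeviance:
    def test_single_cell_binomial_arithmetic(self):
        # -2 log [ C(10,5) 0.5^10 ] computed by independent arithmetic
        expected = -2.0 * math.log(math.comb(10, 5) * 0.5**10)
        got = neg2_log_binomial(np.array([5]), 10, np.array([0.5]))
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.8041, abs=5e-4)

    def test_minimized_at_observed_proportions(self):
        """Grid search oracle: deviance over candidate pi is minimized where
        pi equals the observed proportion, cell by cell."""
        counts = np.array([30, 70])
        grid = np.linspace(0.05, 0.95, 181)
        for cell, n in ((0, 100), (1, 100)):
            devs = [neg2_log_binomial(counts[[cell]], n, np.array([g])) for g in grid]
            best = grid[int(np.argmin(devs))]
            assert best == pytest.approx(counts[cell] / n, abs=0.006)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            neg2_log_binomial(np.array([1]), 10, np.array([0.0]))
        with pytest.raises(ValueError):
            neg2_log_binomial(np.array([1]), 10, np.array([1.0]))

    def test_impossible_cells_explode(self):
        small = neg2_log_binomial(np.array([5]), 10, np.array([0.5]))
        large = neg2_log_binomial(np.array([5]), 10, np.array([1e-6]))
        assert large > small + 100


class TestChiSquare:
    def test_exact_zero_when_equal(self):
        p = [np.array([0.2, 0.3, 0.5])]
        chi2, df, acceptable = chi_square(p, p, [100], n_free_params=0)
        assert chi2 == 0.0 and acceptable

    def test_direct_arithmetic_oracle(self):
        chi2, df, _ = chi_square(
            [np.array([0.5, 0.5])], [np.array([0.6, 0.4])], [100], n_free_params=0
        )
        assert chi2 == pytest.approx(100 * (0.01 / 0.6 + 0.01 / 0.4), rel=1e-12)
        assert chi2 == pytest.approx(4.1667, abs=5e-5)
        assert df == 1

    def test_linear_in_trial_count(self):
        p = [np.array([0.5, 0.3, 0.2])]
        q = [np.array([0.4, 0.35, 0.25])]
        c1, _, _ = chi_square(p, q, [100], n_free_params=0)
        c2, _, _ = chi_square(p, q, [200], n_free_params=0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_invariant_to_bin_relabeling(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        q = np.array([0.15, 0.25, 0.25, 0.35])
        perm = np.array([2, 0, 3, 1])
        c1, _, _ = chi_square([p], [q], [50], n_free_params=0)
        c2, _, _ = chi_square([p[perm]], [q[perm]], [50], n_free_params=0)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_non_positive_df_rejected(self):
        with pytest.raises(ValueError):
            chi_square([np.array([0.5, 0.5])], [np.array([0.5, 0.5])], [10], n_free_params=6)


class TestRmsea:
    def test_no_excess_misfit_is_zero(self):
        assert rmsea(5.0, 10, 500) == 0.0

    def test_direct_arithmetic(self):
        assert rmsea(20.0, 10, 101) == pytest.approx(0.1, rel=1e-12)

    def test_df_and_n_validation(self):
        with pytest.raises(ValueError):
            rmsea(5.0, 0, 100)
        with pytest.raises(ValueError):
            rmsea(5.0, 10, 1)

    def test_goodness_of_fit_self_simulation_is_acceptable_scale(self, mean_params, sim_config):
        """Simulating at the generating parameters yields a small RMSEA."""
        from sspflanker import simulate_dataset

        data = simulate_dataset(mean_params, 2000, 2000, sim_config, np.random.default_rng(3))
        sim = simulate_dataset(mean_params, 20_000, 20_000, sim_config, np.random.default_rng(4))
        fs = goodness_of_fit(summarize_by_type(data), sim)
        assert fs.chi_square >= 0
        assert fs.rmsea < 0.05
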