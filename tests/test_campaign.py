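"""Campaign pooling, convergence detection, summaries and the grid oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import formopt
from formopt.campaign import (
    CampaignResult,
    convergence_generation,
    grid_pareto_oracle,
    hypervolume_2d,
    run_campaign,
    select_ideal,
    summarize_campaign,
    thin_by_crowding,
)
from formopt.moea.core import GAParams, Individual

TINY = GAParams(max_generations=15, n_searches=30)


@pytest.fixture(scope="module")
def small_campaign(problem):
    objective, _, bounds = problem
    return run_campaign("nsga2", objective, bounds, TINY, seeds=[0, 1, 2])


class TestConvergenceGeneration:
    def test_constant_trace_converges_immediately(self):
        assert convergence_generation(np.full((10, 2), 3.0)) == 1

    def test_improving_then_flat_detects_the_knee(self):
        y = np.concatenate([np.linspace(0.1, 0.15, 7), np.full(13, 0.15)])
        trace = np.column_stack([y, y])
        assert convergence_generation(trace) == 7

    def test_late_jump_resets_convergence(self):
        y = np.concatenate([np.full(10, 1.0), np.full(5, 2.0)])
        trace = np.column_stack([y, y])
        assert convergence_generation(trace) == 11

    def test_both_objectives_must_settle(self):
        y1 = np.full(10, 1.0)
        y2 = np.concatenate([np.linspace(0.5, 1.0, 6), np.full(4, 1.0)])
        assert convergence_generation(np.column_stack([y1, y2])) == 6

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            convergence_generation(np.empty((0, 2)))


class TestThinning:
    def test_small_sets_pass_through(self):
        F = np.array([[1, 0], [0, 1]], float)
        assert list(thin_by_crowding(F, F, 30)) == [0, 1]

    def test_objective_extremes_always_kept(self, rng):
        y = np.sort(rng.random(200))
        F = np.column_stack([y, 1 - y])
        keep = thin_by_crowding(F, F, 10)
        assert len(keep) == 10
        assert 0 in keep and 199 in keep


class TestRunCampaign:
    def test_representatives_are_globally_non_dominated(self, small_campaign):
        F = np.array([i.objectives for i in small_campaign.representative])
        from formopt.moea.core import non_dominated_mask

        assert non_dominated_mask(F).all()
        assert len(small_campaign.representative) <= TINY.n_searches

    def test_campaign_is_reproducible(self, problem, small_campaign):
        objective, _, bounds = problem
        again = run_campaign("nsga2", objective, bounds, TINY, seeds=[0, 1, 2])
        assert np.array_equal(
            np.array([i.x for i in again.representative]),
            np.array([i.x for i in small_campaign.representative]),
        )

    def test_single_seed_campaign_reduces_to_that_run(self, problem):
        objective, _, bounds = problem
        campaign = run_campaign("nsga2", objective, bounds, TINY, seeds=[4])
        run_front = campaign.runs[0].front_objectives
        reps = np.array([i.objectives for i in campaign.representative])
        as_set = set(map(tuple, run_front))
        assert all(tuple(f) in as_set for f in reps)

    def test_duplicate_seeds_rejected(self, problem):
        objective, _, bounds = problem
        with pytest.raises(ValueError, match="distinct"):
            run_campaign("nsga2", objective, bounds, TINY, seeds=[1, 1])

    def test_unknown_algorithm_rejected(self, problem):
        objective, _, bounds = problem
        with pytest.raises(KeyError):
            run_campaign("spea2", objective, bounds, TINY, seeds=[1])

    def test_no_solution_beats_the_grid_oracle(self, problem, small_campaign):
        objective, _, bounds = problem
        _, F_oracle = grid_pareto_oracle(objective, bounds, steps=(21, 41, 21))
        reps = np.array([i.objectives for i in small_campaign.representative])
        assert reps[:, 0].max() <= F_oracle[:, 0].max() + 1e-9
        assert reps[:, 1].max() <= F_oracle[:, 1].max() + 1e-9


def _campaign_of(points: list[tuple]) -> CampaignResult:
    inds = [
        Individual(x=np.array(x), objectives=np.array(f), rank=1) for x, f in points
    ]
    return CampaignResult("manual", [], inds, [], GAParams())


class TestSelectIdeal:
    def test_single_solution_is_chosen(self):
        campaign = _campaign_of([((0.7, 1.0, 0.75), (0.15, 0.7))])
        choice = select_ideal(campaign)
        assert len(choice.chosen) == 1

    def test_near_tie_prefers_lower_surfactant(self):
        campaign = _campaign_of(
            [
                ((0.75, 1.0, 0.75), (0.150, 0.70)),  # surfactant 15.0
                ((0.65, 1.0, 0.75), (0.145, 0.70)),  # surfactant 13.0, within 0.01
            ]
        )
        choice = select_ideal(campaign)
        assert choice.chosen[0].x[0] == pytest.approx(0.65)

    def test_flags_max_of_each_objective_at_the_water_bound(self):
        campaign = _campaign_of(
            [
                ((0.75, 0.35, 0.75), (0.17, 0.74)),
                ((0.68, 1.42, 0.75), (0.14, 0.80)),
                ((0.80, 0.96, 0.73), (0.15, 0.49)),  # off the water bound
            ]
        )
        choice = select_ideal(campaign)
        xs = {tuple(np.round(ind.x, 2)) for ind in choice.chosen}
        assert xs == {(0.75, 0.35, 0.75), (0.68, 1.42, 0.75)}


class TestSummaries:
    def test_quartiles_of_one_to_five(self):
        campaign = _campaign_of(
            [((0.6 + 0.04 * v, float(v), 0.7), (v, v)) for v in (1, 2, 3, 4, 5)]
        )
        summary = summarize_campaign(campaign).set_index("variable")
        row = summary.loc["x2"]
        assert (row["median"], row["p25"], row["p75"], row["iqr"]) == (3, 2, 4, 2)

    def test_invariant_to_solution_order(self, small_campaign, rng):
        s1 = summarize_campaign(small_campaign)
        shuffled = CampaignResult(
            small_campaign.algorithm,
            small_campaign.runs,
            [small_campaign.representative[i]
             for i in rng.permutation(len(small_campaign.representative))],
            small_campaign.convergence,
            small_campaign.params,
        )
        s2 = summarize_campaign(shuffled)
        pd.testing.assert_frame_equal(s1, s2)

    def test_constant_variable_reports_missing_normality(self):
        campaign = _campaign_of(
            [((0.6 + 0.01 * v, 1.0, 0.75), (v, v)) for v in range(5)]
        )
        summary = summarize_campaign(campaign).set_index("variable")
        assert pd.isna(summary.loc["x3_pct", "shapiro_w"])

    def test_shapiro_has_nominal_level_on_gaussian_samples(self, rng):
        hits = sum(
            sps.shapiro(rng.normal(size=30)).pvalue > 0.05 for _ in range(100)
        )
        assert hits >= 90


class TestGridOracle:
    def test_conflicting_linear_objectives_keep_the_whole_line(self):
        def line(X):
            X = np.atleast_2d(X)
            t = X[:, 0]
            return np.column_stack([t, 1 - t])

        X, F = grid_pareto_oracle(
            line, (np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, 1.0])), steps=(9, 2, 2)
        )
        assert len(np.unique(F[:, 0])) == 9  # every grid value of t survives

    def test_single_objective_degenerates_to_argmax(self):
        def mono(X):
            X = np.atleast_2d(X)
            return np.column_stack([X[:, 0], X[:, 0]])

        X, F = grid_pareto_oracle(
            mono, (np.zeros(3), np.ones(3)), steps=(5, 3, 3)
        )
        assert np.unique(F[:, 0]) == pytest.approx([1.0])

    def test_memory_guard(self, problem):
        objective, _, bounds = problem
        with pytest.raises(ValueError, match="guard"):
            grid_pareto_oracle(objective, bounds, steps=(300, 300, 300))


class TestHypervolume:
    def test_single_point_rectangle(self):
        assert hypervolume_2d(np.array([[1.0, 1.0]]), np.array([0.0, 0.0])) == 1.0

    def test_two_point_staircase(self):
        F = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert hypervolume_2d(F, np.array([0.0, 0.0])) == pytest.approx(3.0)

    def test_dominated_points_do_not_add_volume(self):
        F = np.array([[2.0, 1.0], [1.0, 2.0], [0.5, 0.5]])
        assert hypervolume_2d(F, np.array([0.0, 0.0])) == pytest.approx(3.0)

    def test_points_below_reference_contribute_nothing(self):
        F = np.array([[-1.0, -1.0]])
        assert hypervolume_2d(F, np.array([0.0, 0.0])) == 0.0
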