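"""Unit and property tests for the cohort-propagation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eldercea.model_core import (
    CohortDistribution,
    DependencyState,
    DiscountSpec,
    PayoffTable,
    STATE_LABELS,
    Trajectory,
    TransitionMatrix,
    ValidationError,
    accumulate_outcomes,
    occupancy_report,
    round_half_up,
    simulate_trajectory,
    step_cohort,
    validate_matrix,
)
from eldercea.synthetic_trials import generate_random_matrix


def identity_matrix():
    return TransitionMatrix(np.eye(5))


class TestValidateMatrix:
    def test_published_matrix_accepted(self, matrix):
        assert validate_matrix(matrix) is matrix

    def test_identity_accepted(self):
        validate_matrix(identity_matrix())

    def test_non_stochastic_row_named_with_sum(self, matrix):
        bad = matrix.with_row(DependencyState.MILD, [0.79, 0.14, 0.03, 0.02, 0.03])
        with pytest.raises(ValidationError, match=r"non-stochastic row: mild, sum 1.01"):
            validate_matrix(bad)

    def test_death_must_be_absorbing(self, matrix):
        bad = matrix.with_row(DependencyState.DEAD, [0.1, 0, 0, 0, 0.9])
        with pytest.raises(ValidationError, match="death not absorbing"):
            validate_matrix(bad)

    def test_negative_probability_rejected(self, matrix):
        bad = matrix.with_row(DependencyState.MODERATE, [-0.02, 0.92, 0.03, 0.01, 0.06])
        with pytest.raises(ValidationError, match="negative probability"):
            validate_matrix(bad)

    def test_recovery_from_total_to_mild_disallowed(self, matrix):
        bad = matrix.with_row(DependencyState.TOTAL, [0.01, 0.03, 0.18, 0.62, 0.16])
        with pytest.raises(ValidationError, match="disallowed transition"):
            validate_matrix(bad)


class TestStepCohort:
    def test_one_year_from_all_mild_is_the_mild_row(self, matrix, all_mild):
        stepped = step_cohort(all_mild, matrix)
        np.testing.assert_allclose(stepped.shares, [0.79, 0.13, 0.03, 0.02, 0.03])

    def test_identity_leaves_distribution_unchanged(self, matrix, all_mild):
        d = step_cohort(all_mild, matrix)
        np.testing.assert_array_equal(step_cohort(d, identity_matrix()).shares, d.shares)

    def test_two_year_mild_share_matches_path_enumeration(self, matrix, all_mild):
        # all 2-step paths ending mild: mild→mild→mild, mild→moderate→mild,
        # mild→severe→mild (total→mild is structurally impossible)
        expected = 0.79 * 0.79 + 0.13 * 0.08 + 0.03 * 0.02  # = 0.6351
        d = step_cohort(step_cohort(all_mild, matrix), matrix)
        assert d.shares[DependencyState.MILD] == pytest.approx(expected, abs=1e-12)


class TestSimulateTrajectory:
    def test_control_trajectory_matches_published_count_table(self, matrix, all_mild):
        """Counts per 100 persons over four years reproduce the published
        control column after round-half-up."""
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        report = occupancy_report(traj, 100).set_index("year")
        assert list(report.loc[1:4, "mild"]) == [79, 64, 52, 43]
        assert list(report.loc[1:4, "moderate"]) == [13, 21, 26, 29]

    def test_year4_shares_match_matrix_power_oracle(self, matrix, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        oracle = np.linalg.matrix_power(matrix.probs, 4)[0]
        np.testing.assert_allclose(traj.occupancy[4], oracle, atol=1e-12)
        assert traj.occupancy[4][2:].sum() == pytest.approx(0.273823, abs=5e-7)

    def test_horizon_one_identity_returns_start(self, all_mild):
        traj = simulate_trajectory(all_mild, [identity_matrix()])
        np.testing.assert_array_equal(traj.occupancy[1], all_mild.shares)

    def test_horizon_must_be_positive(self, all_mild):
        with pytest.raises(ValidationError, match="horizon"):
            simulate_trajectory(all_mild, [], horizon=0)

    def test_matrix_count_must_match_horizon(self, matrix, all_mild):
        with pytest.raises(ValidationError, match="one matrix per cycle"):
            simulate_trajectory(all_mild, [matrix] * 2, horizon=3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), horizon=st.integers(1, 10))
    def test_equals_matrix_power_for_random_matrices(self, seed, horizon):
        m = generate_random_matrix(seed)
        start = CohortDistribution.all_mild()
        traj = simulate_trajectory(start, [m] * horizon)
        oracle = np.linalg.matrix_power(m.probs, horizon)[0]
        np.testing.assert_allclose(traj.occupancy[horizon], oracle, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), horizon=st.integers(1, 10))
    def test_mass_conserved_and_death_monotone(self, seed, horizon):
        m = generate_random_matrix(seed)
        traj = simulate_trajectory(CohortDistribution.all_mild(), [m] * horizon)
        sums = traj.occupancy.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        dead = traj.occupancy[:, DependencyState.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_long_run_absorption_into_death(self, matrix, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 300)
        assert traj.occupancy[-1, DependencyState.DEAD] == pytest.approx(1.0, abs=1e-6)


class TestAccumulateOutcomes:
    def test_single_cycle_qaly_hand_oracle(self, matrix, payoffs, all_mild):
        # end-of-cycle occupancy (.79,.13,.03,.02,.03) dotted with utilities,
        # discounted one year at 3%
        expected = (0.79 * 0.77 + 0.13 * 0.60 + 0.03 * 0.47 + 0.02 * 0.41) / 1.03
        traj = simulate_trajectory(all_mild, [matrix])
        qalys, _ = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03))
        assert qalys == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.68796, abs=5e-6)

    def test_control_four_year_outcomes_match_published_within_1pct(
        self, matrix, payoffs, all_mild
    ):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        qalys, costs = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03))
        assert qalys == pytest.approx(2.355, rel=0.01)
        assert costs == pytest.approx(24291, rel=0.01)

    def test_zero_utilities_give_zero_qalys(self, matrix, all_mild):
        dead_payoffs = PayoffTable(np.zeros(5), np.zeros(5))
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        qalys, costs = accumulate_outcomes(traj, dead_payoffs, DiscountSpec(0.03))
        assert qalys == 0.0 and costs == 0.0

    def test_discounting_reduces_outcomes_iff_rate_positive(self, matrix, payoffs, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        q0, c0 = accumulate_outcomes(traj, payoffs, DiscountSpec(0.0))
        q3, c3 = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03))
        assert q3 < q0 and c3 < c0

    def test_cycle1_extra_cost_charged_undiscounted(self, matrix, payoffs, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        _, base = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03))
        _, with_up = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03), [160, 0, 0, 0])
        assert with_up - base == pytest.approx(160.0, abs=1e-9)

    def test_later_extra_costs_discounted_from_cycle_start(self, matrix, payoffs, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        _, base = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03))
        _, with_boost = accumulate_outcomes(traj, payoffs, DiscountSpec(0.03), [0, 100, 0, 0])
        assert with_boost - base == pytest.approx(100 / 1.03, abs=1e-9)

    def test_negative_extra_cost_rejected(self, matrix, payoffs, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        with pytest.raises(ValidationError, match="non-negative"):
            accumulate_outcomes(traj, payoffs, DiscountSpec(0.03), [-1, 0, 0, 0])

    def test_extra_cost_length_must_match_horizon(self, matrix, payoffs, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        with pytest.raises(ValidationError, match="per cycle"):
            accumulate_outcomes(traj, payoffs, DiscountSpec(0.03), [0, 0])


class TestOccupancyReport:
    def test_year1_row_is_scaled_mild_row(self, matrix, all_mild):
        traj = simulate_trajectory(all_mild, [matrix] * 4)
        row = occupancy_report(traj, 100).set_index("year").loc[1]
        assert list(row[list(STATE_LABELS)]) == [79, 13, 3, 2, 3]

    def test_year3_mild_rounds_matrix_power_value(self, matrix, all_mild):
        # 3-step matrix power gives 51.98 per 100 → 52
        traj = simulate_trajectory(all_mild, [matrix] * 3)
        assert occupancy_report(traj, 100).set_index("year").loc[3, "mild"] == 52

    def test_cohort_of_one_yields_indicator_cells(self, matrix, all_mild):
        traj = simulate_trajectory(all_mild, [matrix])
        cells = occupancy_report(traj, 1).drop(columns="year").to_numpy()
        assert set(cells.ravel()) <= {0, 1}

    def test_round_half_up_behaviour(self):
        assert round_half_up(63.5) == 64
        assert round_half_up(63.49) == 63
        assert round_half_up(14.2) == 14


class TestDomainTypes:
    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            CohortDistribution(np.array([0.5, 0.2, 0.1, 0.1, 0.05]))

    def test_negative_discount_rate_rejected(self):
        with pytest.raises(ValidationError, match="≥ 0"):
            DiscountSpec(-0.01)

    def test_payoff_table_requires_zero_payoffs_for_death(self):
        with pytest.raises(ValidationError, match="death"):
            PayoffTable(np.array([0.77, 0.6, 0.47, 0.41, 0.1]), np.zeros(5))
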