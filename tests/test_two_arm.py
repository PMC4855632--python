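"""Two-arm designs: fixed-sample sizing, rho-family spending, boundary
construction and stopping probabilities, including a Monte Carlo oracle for
the recursive numerical integration."""

import math

import numpy as np
import pytest

from devplan import (
    FixedTwoArmDesign,
    TwoArmHypotheses,
    ValidationError,
    derive_error_spending_design,
    drift_at,
    fixed_reject_probability,
    fixed_sample_size,
    gs_expected_sample_size,
    spending_value,
    stage_probabilities,
)

HYP_STAGE = TwoArmHypotheses(0.15, 0.3, 0.05, 0.2)
HYP_FULL = TwoArmHypotheses(0.15, 0.3, 0.0025, 0.36)


class TestFixedDesign:
    def test_tabulated_sample_sizes(self):
        assert fixed_sample_size(HYP_STAGE).total_n == 186
        assert fixed_sample_size(HYP_FULL).total_n == 302

    def test_degenerate_effect_rejected(self):
        with pytest.raises(ValidationError):
            TwoArmHypotheses(0.3, 0.3, 0.05, 0.2)

    def test_size_monotone_in_inverse_squared_effect(self):
        wide = fixed_sample_size(TwoArmHypotheses(0.4, 0.6, 0.05, 0.2))
        narrow = fixed_sample_size(TwoArmHypotheses(0.45, 0.55, 0.05, 0.2))
        assert narrow.n_per_arm > wide.n_per_arm

    def test_reject_probability_is_alpha_on_diagonal(self):
        design = fixed_sample_size(HYP_FULL)
        assert fixed_reject_probability(design, 0.15, 0.15) == pytest.approx(
            0.0025, abs=1e-12
        )

    def test_degenerate_variance_corners(self):
        design = fixed_sample_size(HYP_FULL)
        assert fixed_reject_probability(design, 0.0, 1.0) == 1.0
        assert fixed_reject_probability(design, 1.0, 0.0) == 0.0


class TestSpendingFunction:
    def test_boundary_values(self):
        assert spending_value(1.0, 0.0025, 1.0) == pytest.approx(0.0025)
        assert spending_value(1.0, 0.0025, 0.0) == 0.0
        assert spending_value(2.0, 0.05, 0.5) == pytest.approx(0.0125)

    def test_domain_checked(self):
        with pytest.raises(ValidationError):
            spending_value(1.0, 0.05, 1.2)
        with pytest.raises(ValidationError):
            spending_value(-1.0, 0.05, 0.5)


class TestErrorSpendingConstruction:
    def test_one_look_reduces_to_fixed_design(self):
        gs = derive_error_spending_design(HYP_FULL, info_fractions=[1.0])
        fixed = fixed_sample_size(HYP_FULL)
        assert gs.total_sizes == (fixed.total_n,)
        assert gs.efficacy_bounds[0] == pytest.approx(fixed.critical_z, abs=1e-9)

    def test_single_look_null_go_probability_is_alpha(self):
        gs = derive_error_spending_design(HYP_FULL, info_fractions=[1.0])
        probs = stage_probabilities(gs, 0.0)
        assert probs.total_go == pytest.approx(0.0025, abs=1e-9)

    def test_tabulated_cumulative_sizes(self):
        dp4 = derive_error_spending_design(HYP_FULL, info_fractions=[1 / 3, 2 / 3, 1])
        assert dp4.total_sizes == (120, 240, 360)
        dp5 = derive_error_spending_design(
            HYP_FULL, fixed_totals=[20, 56], n_looks=3,
            go_allowed=[False, False, True],
        )
        assert dp5.total_sizes == (20, 56, 310)
        dp6 = derive_error_spending_design(
            HYP_FULL, fixed_totals=[56], n_looks=3,
            go_allowed=[False, True, True],
        )
        assert dp6.total_sizes == (56, 202, 346)

    def test_spending_conservation_continuous_design(self):
        """On the unrounded design the type-I spend at drift 0 totals alpha
        and the type-II spend at the design alternative totals beta, to 1e-6."""
        gs = derive_error_spending_design(
            HYP_FULL, info_fractions=[1 / 3, 2 / 3, 1], round_sizes=False
        )
        drift_alt = (HYP_FULL.p1 - HYP_FULL.p0) * math.sqrt(
            (gs.solved_total / 2.0) / HYP_FULL.variance
        )
        null = stage_probabilities(gs, 0.0)
        alt = stage_probabilities(gs, drift_alt)
        assert null.total_go == pytest.approx(HYP_FULL.alpha_r, abs=1e-6)
        assert alt.total_nogo == pytest.approx(HYP_FULL.beta_r, abs=1e-6)

    def test_rounded_design_preserves_alpha_and_overpowers(self):
        gs = derive_error_spending_design(HYP_FULL, info_fractions=[1 / 3, 2 / 3, 1])
        assert stage_probabilities(gs, 0.0).total_go == pytest.approx(
            0.0025, abs=1e-8
        )
        drift_alt = drift_at(0.15, 0.30, gs.n_per_arm_max)
        power = stage_probabilities(gs, drift_alt).total_go
        assert power >= 1 - HYP_FULL.beta_r

    def test_go_disallowed_looks_have_infinite_bounds(self):
        dp5 = derive_error_spending_design(
            HYP_FULL, fixed_totals=[20, 56], n_looks=3,
            go_allowed=[False, False, True],
        )
        assert math.isinf(dp5.efficacy_bounds[0])
        assert math.isinf(dp5.efficacy_bounds[1])
        assert math.isfinite(dp5.futility_bounds[0])

    def test_schedule_validation(self):
        with pytest.raises(ValidationError):
            derive_error_spending_design(HYP_FULL, info_fractions=[0.5, 0.4, 1.0])
        with pytest.raises(ValidationError):
            derive_error_spending_design(
                HYP_FULL, info_fractions=[0.5, 1.0], go_allowed=[True, False]
            )
        with pytest.raises(ValidationError):
            derive_error_spending_design(
                HYP_FULL, info_fractions=[0.5, 1.0], fixed_totals=[20],
                n_looks=2,
            )


@pytest.fixture(scope="module")
def dp4():
    return derive_error_spending_design(HYP_FULL, info_fractions=[1 / 3, 2 / 3, 1])


class TestStoppingProbabilities:
    @pytest.mark.parametrize("drift", [-4.0, -1.0, 0.0, 1.3, 3.46, 6.0])
    def test_probabilities_partition_unity(self, dp4, drift):
        probs = stage_probabilities(dp4, drift)
        assert probs.total_go + probs.total_nogo == pytest.approx(1.0, abs=1e-6)
        assert all(0.0 <= g <= 1.0 for g in probs.go_by_stage)
        assert all(0.0 <= n <= 1.0 for n in probs.nogo_by_stage)

    def test_go_probability_monotone_in_drift(self, dp4):
        drifts = np.linspace(-3.0, 6.0, 25)
        total = [stage_probabilities(dp4, d).total_go for d in drifts]
        assert np.all(np.diff(total) >= -1e-10)

    def test_infinite_drift_limits(self, dp4):
        assert stage_probabilities(dp4, math.inf).total_go == 1.0
        assert stage_probabilities(dp4, -math.inf).total_nogo == 1.0

    def test_grid_refinement_stability(self, dp4):
        for drift in (0.0, 2.0, 3.46):
            coarse = stage_probabilities(dp4, drift, grid_points=129)
            fine = stage_probabilities(dp4, drift, grid_points=257)
            deltas = np.abs(
                np.array(coarse.go_by_stage + coarse.nogo_by_stage)
                - np.array(fine.go_by_stage + fine.nogo_by_stage)
            )
            assert deltas.max() < 1e-5

    def test_matches_monte_carlo_simulation(self, dp4):
        """Simulate the canonical joint normal sequence directly and compare
        per-look first-passage frequencies with the grid recursion."""
        rng = np.random.default_rng(20260926)
        n_sim = 400_000
        drift = 2.0
        t = np.asarray(dp4.info_fractions)
        dt = np.diff(np.concatenate(([0.0], t)))
        incr = rng.normal(drift * dt, np.sqrt(dt), size=(n_sim, len(t)))
        w = np.cumsum(incr, axis=1)
        z = w / np.sqrt(t)
        alive = np.ones(n_sim, dtype=bool)
        go_freq, nogo_freq = [], []
        for k in range(len(t)):
            up = alive & (z[:, k] >= dp4.efficacy_bounds[k])
            down = alive & (z[:, k] <= dp4.futility_bounds[k]) & ~up
            go_freq.append(up.mean())
            nogo_freq.append(down.mean())
            alive &= ~(up | down)
        probs = stage_probabilities(dp4, drift)
        np.testing.assert_allclose(probs.go_by_stage, go_freq, atol=4e-3)
        np.testing.assert_allclose(probs.nogo_by_stage, nogo_freq, atol=4e-3)

    def test_expected_size_bounded_by_schedule(self, dp4):
        en = gs_expected_sample_size(dp4, 0.15, 0.15)
        assert dp4.total_sizes[0] <= en <= dp4.total_sizes[-1]


def test_design_serialisation_round_trip():
    from devplan import GroupSequentialDesign

    dp5 = derive_error_spending_design(
        HYP_FULL, fixed_totals=[20, 56], n_looks=3,
        go_allowed=[False, False, True],
    )
    clone = GroupSequentialDesign.from_dict(dp5.to_dict())
    assert clone.total_sizes == dp5.total_sizes
    assert clone.efficacy_bounds == dp5.efficacy_bounds
    table = dp5.boundary_table()
    assert list(table["n_total_cum"]) == [20, 56, 310]


def test_fixed_design_validation():
    with pytest.raises(ValidationError):
        FixedTwoArmDesign(n_per_arm=0, critical_z=1.96)
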