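"""Optimality criteria, reference-prior fitting and usage probabilities."""

import numpy as np
import pytest
from scipy.integrate import quad

from devplan import (
    NO_PLAN,
    OptimalityCriterion,
    PLAN_IDS,
    ValidationError,
    build_optimality_map,
    fit_reference_prior,
    optimal_plan_at,
    usage_probabilities,
)
from conftest import BETA, P0, P1

FLOOR = 1 - BETA


def _metrics(**overrides):
    """Synthetic per-plan (power, expected_n) metrics for one lattice point."""
    base = {pid: (0.5, 200.0) for pid in PLAN_IDS}
    base.update(overrides)
    return base


class TestOptimalPlanAt:
    def test_oc1_minimises_expected_n(self):
        m = _metrics(DP4=(0.2, 120.0))
        assert optimal_plan_at(m, OptimalityCriterion("OC1")) == "DP4"

    def test_oc2_respects_power_floor(self):
        crit = OptimalityCriterion("OC2", power_floor=0.64)
        m = _metrics(DP4=(0.2, 120.0), DP3=(0.7, 300.0))
        assert optimal_plan_at(m, crit) == "DP3"
        assert optimal_plan_at(_metrics(), crit) == NO_PLAN

    def test_oc3_maximises_power_per_patient(self):
        m = _metrics(DP2=(0.8, 100.0), DP4=(0.9, 150.0))
        assert optimal_plan_at(m, OptimalityCriterion("OC3")) == "DP2"

    def test_oc4_floor_then_efficiency(self):
        crit = OptimalityCriterion("OC4", power_floor=0.64)
        m = _metrics(DP2=(0.5, 10.0), DP4=(0.7, 150.0), DP6=(0.65, 200.0))
        assert optimal_plan_at(m, crit) == "DP4"

    def test_ties_break_to_lowest_plan_index(self):
        m = _metrics()  # all identical
        assert optimal_plan_at(m, OptimalityCriterion("OC1")) == "DP1"
        assert optimal_plan_at(m, OptimalityCriterion("OC3")) == "DP1"

    def test_missing_plan_metric_rejected(self):
        m = _metrics()
        del m["DP5"]
        with pytest.raises(ValidationError):
            optimal_plan_at(m, OptimalityCriterion("OC1"))


class TestOptimalityMaps:
    def test_oc1_map_has_no_empty_cells(self, line_grids):
        omap = build_optimality_map(line_grids, OptimalityCriterion("OC1"))
        assert NO_PLAN not in set(omap.winners.ravel())

    def test_oc2_map_has_empty_cells(self, line_grids):
        omap = build_optimality_map(
            line_grids, OptimalityCriterion("OC2", power_floor=FLOOR)
        )
        assert NO_PLAN in set(omap.winners.ravel())

    def test_map_agrees_with_pointwise_winner(self, line_grids):
        crit = OptimalityCriterion("OC2", power_floor=FLOOR)
        omap = build_optimality_map(line_grids, crit)
        for j in (0, 15, 30, 41, 75, 100):
            metrics = {
                pid: (line_grids[pid].power[0, j], line_grids[pid].expected_n[0, j])
                for pid in PLAN_IDS
            }
            assert omap.winners[0, j] == optimal_plan_at(metrics, crit)

    def test_lattice_mismatch_rejected(self, line_grids, full_grids):
        mixed = dict(line_grids)
        mixed["DP6"] = full_grids["DP6"]
        with pytest.raises(ValidationError):
            build_optimality_map(mixed, OptimalityCriterion("OC1"))


class TestReferencePriors:
    @pytest.mark.parametrize(
        "stance,centre,edge,upper",
        [("sceptic", P0, P1, True), ("enthusiast", P1, P0, False)],
    )
    def test_fitted_constraints(self, stance, centre, edge, upper):
        """Mode sits at the stance's centre and the opposing tail holds 10%,
        verified by numerical integration of the fitted density."""
        prior = fit_reference_prior(stance, P0, P1)
        assert prior.mode == pytest.approx(centre, abs=1e-9)
        lo, hi = (edge, 1.0) if upper else (0.0, edge)
        mass, _ = quad(prior.pdf, lo, hi)
        assert mass == pytest.approx(0.10, abs=1e-6)
        total, _ = quad(prior.pdf, 0.0, 1.0)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_on_shapes(self):
        prior = fit_reference_prior("sceptic", P0, P1)
        assert (prior.shape_a - 1) / (prior.shape_a + prior.shape_b - 2) == (
            pytest.approx(P0, abs=1e-9)
        )
        assert 1 - prior.cdf(P1) == pytest.approx(0.10, abs=1e-9)

    def test_unknown_stance_rejected(self):
        with pytest.raises(ValidationError):
            fit_reference_prior("agnostic", P0, P1)


@pytest.fixture(scope="module")
def priors():
    return {s: fit_reference_prior(s, P0, P1) for s in ("sceptic", "enthusiast")}


class TestUsageProbabilities:
    @pytest.mark.parametrize("cid", ["OC1", "OC2", "OC3", "OC4"])
    @pytest.mark.parametrize("stance", ["sceptic", "enthusiast"])
    def test_partition_sums_to_one(self, line_grids, priors, cid, stance):
        omap = build_optimality_map(
            line_grids, OptimalityCriterion(cid, power_floor=FLOOR)
        )
        u = usage_probabilities(omap, priors[stance], P0)
        assert sum(u.as_tuple()) == pytest.approx(1.0, abs=1e-6)

    def test_oc2_and_oc4_share_infeasible_mass(self, line_grids, priors):
        """The feasibility set is identical for the two floored criteria, so
        the no-plan probability matches."""
        maps = {
            cid: build_optimality_map(
                line_grids, OptimalityCriterion(cid, power_floor=FLOOR)
            )
            for cid in ("OC2", "OC4")
        }
        for stance in ("sceptic", "enthusiast"):
            p2 = usage_probabilities(maps["OC2"], priors[stance], P0).p_none
            p4 = usage_probabilities(maps["OC4"], priors[stance], P0).p_none
            assert p2 == pytest.approx(p4, abs=1e-12)

    def test_lattice_refinement_stability(self, worked_example_plans, priors):
        """Halving the pE lattice step moves each class probability < 0.005."""
        from devplan import evaluate_line

        crit = OptimalityCriterion("OC1")
        results = []
        for n in (101, 201):
            pe = np.linspace(0.0, 1.0, n)
            grids = {
                pid: evaluate_line(plan, P0, pe)
                for pid, plan in worked_example_plans.items()
            }
            omap = build_optimality_map(grids, crit)
            results.append(usage_probabilities(omap, priors["sceptic"], P0))
        for a, b in zip(results[0].as_tuple(), results[1].as_tuple()):
            assert abs(a - b) < 0.005

    def test_off_lattice_line_warns(self, line_grids, priors):
        omap = build_optimality_map(line_grids, OptimalityCriterion("OC1"))
        with pytest.warns(UserWarning, match="off-lattice"):
            usage_probabilities(omap, priors["sceptic"], 0.1504)
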