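"""Composition and evaluation of the six drug development plans DP1-DP6.

DP1  Simon two-stage single-arm trial, then (on a go) a fixed two-arm trial.
DP2  As DP1 but the Simon design allows early stopping for efficacy.
DP3  A single-stage randomised two-arm trial.
DP4  A three-stage group-sequential two-arm trial, equally spaced looks,
     go/no-go stopping at every look (rho-family error spending).
DP5  A group-sequential two-arm trial with futility-only interim looks timed
     at the stage sizes of DP1's Simon design, plus a final go/no-go look.
DP6  A group-sequential two-arm trial with one futility-only look at the
     Simon total, then two further equally spaced go/no-go looks.

All plans are calibrated to a common plan-wide one-sided type-I error
``alpha`` under the global null (pC = pE = p0) and type-II error ``beta``
under the global alternative (pC = p0, pE = p1).  For DP1-DP2 the error is
split across the two trials via ``alpha_s = alpha_r = sqrt(alpha)`` and
``beta_s = beta_r = 1 - sqrt(1 - beta)``, so that the plan-wide product of
stage errors attains the targets; DP3-DP6 use ``alpha`` and ``beta``
directly.

A plan's power is the probability of a final go decision: for DP1-DP2 the
product of the single-arm rejection probability (a function of ``pE`` only)
and the randomised-stage rejection probability; for DP3-DP6 the randomised
design's rejection probability alone.  The expected sample size of DP1-DP2
counts the randomised stage only when the single-arm stage rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .single_arm import (
    SimonTwoStageDesign,
    SingleArmHypotheses,
    search_simon_optimal,
    simon_operating_characteristics,
    simon_reject_probability,
)
from .two_arm import (
    FixedTwoArmDesign,
    GroupSequentialDesign,
    TwoArmHypotheses,
    derive_error_spending_design,
    fixed_reject_probability,
    fixed_sample_size,
    gs_expected_sample_size,
    gs_reject_probability,
)

__all__ = [
    "PLAN_IDS",
    "GlobalErrorSpec",
    "PlanSpecification",
    "PerformanceGrid",
    "build_plans",
    "plan_power",
    "plan_expected_n",
    "plan_max_n",
    "evaluate_grid",
    "evaluate_line",
]

PLAN_IDS = ("DP1", "DP2", "DP3", "DP4", "DP5", "DP6")


@dataclass(frozen=True)
class GlobalErrorSpec:
    """Plan-wide one-sided type-I (``alpha``) and type-II (``beta``) error
    targets at the global null and alternative."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")

    @property
    def alpha_stage(self) -> float:
        """Per-trial type-I error for the two-trial plans DP1-DP2."""
        return math.sqrt(self.alpha)

    @property
    def beta_stage(self) -> float:
        """Per-trial type-II error for DP1-DP2 (power multiplies across the
        two trials: (1 - beta_stage)^2 = 1 - beta)."""
        return 1.0 - math.sqrt(1.0 - self.beta)


@dataclass(frozen=True)
class PlanSpecification:
    """One development plan: an optional single-arm gate plus a randomised
    design, with the decision rule described in the module docstring."""

    plan_id: str
    randomised: FixedTwoArmDesign | GroupSequentialDesign
    single_arm: SimonTwoStageDesign | None = None

    def __post_init__(self) -> None:
        if self.plan_id not in PLAN_IDS:
            raise ValidationError(f"unknown plan_id {self.plan_id!r}")
        needs_single = self.plan_id in ("DP1", "DP2")
        if needs_single != (self.single_arm is not None):
            raise ValidationError(
                f"{self.plan_id} must carry a single-arm design "
                f"{'with' if needs_single else 'without'} one"
            )
        if needs_single and not isinstance(self.randomised, FixedTwoArmDesign):
            raise ValidationError(
                f"{self.plan_id} requires a fixed randomised design"
            )
        if self.plan_id == "DP3" and not isinstance(
            self.randomised, FixedTwoArmDesign
        ):
            raise ValidationError("DP3 requires a fixed randomised design")
        if self.plan_id in ("DP4", "DP5", "DP6") and not isinstance(
            self.randomised, GroupSequentialDesign
        ):
            raise ValidationError(
                f"{self.plan_id} requires a group-sequential design"
            )

    @property
    def max_n(self) -> int:
        """Maximum total number of patients the plan can recruit."""
        if isinstance(self.randomised, FixedTwoArmDesign):
            rand = self.randomised.total_n
        else:
            rand = self.randomised.max_total
        single = self.single_arm.n if self.single_arm is not None else 0
        return single + rand

    def to_dict(self) -> dict:
        d: dict = {"plan_id": self.plan_id}
        if self.single_arm is not None:
            d["single_arm"] = self.single_arm.to_dict()
        if isinstance(self.randomised, FixedTwoArmDesign):
            d["randomised"] = {
                "kind": "fixed",
                "n_per_arm": self.randomised.n_per_arm,
                "critical_z": self.randomised.critical_z,
            }
        else:
            d["randomised"] = {"kind": "group_sequential", **self.randomised.to_dict()}
        return d


def build_plans(
    p0: float,
    p1: float,
    errors: GlobalErrorSpec,
    rho: float = 1.0,
    n_max_search: int = 100,
    grid_points: int = 129,
) -> dict[str, PlanSpecification]:
    """Construct all six development plans for the scenario ``(p0, p1)`` at
    plan-wide errors ``errors``; see the module docstring for the plan
    definitions and the error split."""
    a_s, b_s = errors.alpha_stage, errors.beta_stage
    single_hyp = SingleArmHypotheses(p0, p1, a_s, b_s)
    simon1 = search_simon_optimal(single_hyp, efficacy_stopping=False,
                                  n_max_search=n_max_search)
    simon2 = search_simon_optimal(single_hyp, efficacy_stopping=True,
                                  n_max_search=n_max_search)

    stage_two = fixed_sample_size(TwoArmHypotheses(p0, p1, a_s, b_s))
    full_hyp = TwoArmHypotheses(p0, p1, errors.alpha, errors.beta)
    dp3 = fixed_sample_size(full_hyp)
    dp4 = derive_error_spending_design(
        full_hyp, info_fractions=[1 / 3, 2 / 3, 1.0], rho=rho,
        grid_points=grid_points,
    )
    # interim looks timed by the Simon design of DP1 (whole patients per arm)
    t_interim = 2 * math.ceil(simon1.n1 / 2)
    t_total = 2 * math.ceil(simon1.n / 2)
    dp5 = derive_error_spending_design(
        full_hyp, fixed_totals=[t_interim, t_total], n_looks=3,
        go_allowed=[False, False, True], rho=rho, grid_points=grid_points,
    )
    dp6 = derive_error_spending_design(
        full_hyp, fixed_totals=[t_total], n_looks=3,
        go_allowed=[False, True, True], rho=rho, grid_points=grid_points,
    )
    return {
        "DP1": PlanSpecification("DP1", stage_two, simon1),
        "DP2": PlanSpecification("DP2", stage_two, simon2),
        "DP3": PlanSpecification("DP3", dp3),
        "DP4": PlanSpecification("DP4", dp4),
        "DP5": PlanSpecification("DP5", dp5),
        "DP6": PlanSpecification("DP6", dp6),
    }


def plan_power(
    plan: PlanSpecification, pC: float, pE: float, grid_points: int = 129
) -> float:
    """Probability of a final go decision at true rates ``(pC, pE)``."""
    if plan.single_arm is not None:
        gate = simon_reject_probability(plan.single_arm, pE)
        return gate * fixed_reject_probability(plan.randomised, pC, pE)
    if isinstance(plan.randomised, FixedTwoArmDesign):
        return fixed_reject_probability(plan.randomised, pC, pE)
    return gs_reject_probability(plan.randomised, pC, pE, grid_points)


def plan_expected_n(
    plan: PlanSpecification, pC: float, pE: float, grid_points: int = 129
) -> float:
    """Expected total number of patients recruited at true rates
    ``(pC, pE)``; for DP1-DP2 the randomised stage is only run after a
    single-arm go."""
    if plan.single_arm is not None:
        oc = simon_operating_characteristics(plan.single_arm, pE)
        return oc.expected_n + oc.reject_prob * plan.randomised.total_n
    if isinstance(plan.randomised, FixedTwoArmDesign):
        return float(plan.randomised.total_n)
    return gs_expected_sample_size(plan.randomised, pC, pE, grid_points)


def plan_max_n(plan: PlanSpecification) -> int:
    return plan.max_n


@dataclass(frozen=True)
class PerformanceGrid:
    """Power, expected sample size and power-per-patient of one plan on a
    lattice over the (pC, pE) square; arrays indexed ``[i_pC, j_pE]``."""

    plan_id: str
    pC_values: np.ndarray
    pE_values: np.ndarray
    power: np.ndarray
    expected_n: np.ndarray

    @property
    def power_per_patient(self) -> np.ndarray:
        return self.power / self.expected_n

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (plan_id, pC, pE, power, expected_n,
        power_per_patient)."""
        pc, pe = np.meshgrid(self.pC_values, self.pE_values, indexing="ij")
        return pd.DataFrame(
            {
                "plan_id": self.plan_id,
                "pC": pc.ravel(),
                "pE": pe.ravel(),
                "power": self.power.ravel(),
                "expected_n": self.expected_n.ravel(),
                "power_per_patient": self.power_per_patient.ravel(),
            }
        )


def _lattice(grid_step: float) -> np.ndarray:
    if not (0.0 < grid_step <= 0.5):
        raise ValidationError(f"grid_step must lie in (0, 0.5]; got {grid_step}")
    n = int(round(1.0 / grid_step))
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValidationError("grid_step must divide 1 evenly")
    return np.linspace(0.0, 1.0, n + 1)


def evaluate_line(
    plan: PlanSpecification,
    pC: float,
    pE_values: np.ndarray,
    grid_points: int = 129,
) -> PerformanceGrid:
    """Evaluate one plan along a fixed-``pC`` line of ``pE`` values."""
    pE_values = np.asarray(pE_values, dtype=float)
    power = np.empty(pE_values.size)
    en = np.empty(pE_values.size)
    for j, pe in enumerate(pE_values):
        power[j] = plan_power(plan, pC, pe, grid_points)
        en[j] = plan_expected_n(plan, pC, pe, grid_points)
    return PerformanceGrid(
        plan_id=plan.plan_id,
        pC_values=np.asarray([pC]),
        pE_values=pE_values,
        power=power[None, :],
        expected_n=en[None, :],
    )


def evaluate_grid(
    plans: dict[str, PlanSpecification],
    grid_step: float = 0.01,
    grid_points: int = 129,
) -> dict[str, PerformanceGrid]:
    """Evaluate every plan on the full (pC, pE) lattice with the given
    spacing.  Deterministic for fixed inputs."""
    axis = _lattice(grid_step)
    out: dict[str, PerformanceGrid] = {}
    for pid, plan in plans.items():
        power = np.empty((axis.size, axis.size))
        en = np.empty((axis.size, axis.size))
        if plan.single_arm is not None:
            gate = np.array(
                [simon_reject_probability(plan.single_arm, pe) for pe in axis]
            )
            oc = [simon_operating_characteristics(plan.single_arm, pe) for pe in axis]
            en_single = np.array([o.expected_n for o in oc])
            for i, pc in enumerate(axis):
                two_arm = np.array(
                    [fixed_reject_probability(plan.randomised, pc, pe) for pe in axis]
                )
                power[i] = gate * two_arm
                en[i] = en_single + gate * plan.randomised.total_n
        elif isinstance(plan.randomised, FixedTwoArmDesign):
            for i, pc in enumerate(axis):
                power[i] = [
                    fixed_reject_probability(plan.randomised, pc, pe) for pe in axis
                ]
            en[:] = plan.randomised.total_n
        else:
            for i, pc in enumerate(axis):
                row = evaluate_line(plan, pc, axis, grid_points)
                power[i] = row.power[0]
                en[i] = row.expected_n[0]
        out[pid] = PerformanceGrid(
            plan_id=pid, pC_values=axis, pE_values=axis, power=power, expected_n=en
        )
    return out
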