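"""Optimality criteria, optimal-plan maps and reference-prior usage
probabilities.

Four criteria rank the development plans at each pair of true response rates:

* OC1 - minimum expected sample size;
* OC2 - minimum expected sample size among plans with power above the floor
  ``1 - beta`` (no optimal plan where none qualifies);
* OC3 - maximum power per patient, ``P / E(N)``;
* OC4 - maximum power per patient among plans above the power floor.

Ties are broken by the lowest plan index, which is recorded in the exported
metadata so class probabilities remain auditable.

Two beta reference priors on the experimental response rate ``pE`` summarise
investigator opinion: a *sceptic* centred (in mode) on ``p0`` with 10%
probability that ``pE > p1``, and an *enthusiast* centred on ``p1`` with 10%
probability that ``pE < p0``.  Integrating a prior along the line
``pC = p0`` over the regions where each plan class wins yields the
probability that a single-arm-incorporating plan (DP1-DP2), a randomised-only
plan (DP3-DP6), or no plan at all should be used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .errors import InfeasibleDesignError, ValidationError
from .plans import PLAN_IDS, PerformanceGrid

__all__ = [
    "CRITERION_IDS",
    "NO_PLAN",
    "TAIL_MASS",
    "OptimalityCriterion",
    "OptimalityMap",
    "ReferencePrior",
    "PlanUsageProbabilities",
    "optimal_plan_at",
    "build_optimality_map",
    "fit_reference_prior",
    "usage_probabilities",
]

CRITERION_IDS = ("OC1", "OC2", "OC3", "OC4")
NO_PLAN = "none"
TAIL_MASS = 0.10  # tail probability beyond the opposing benchmark
SINGLE_ARM_PLANS = frozenset({"DP1", "DP2"})


@dataclass(frozen=True)
class OptimalityCriterion:
    """One of OC1-OC4; ``power_floor`` (= 1 - beta) applies to OC2/OC4."""

    criterion_id: str
    power_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.criterion_id not in CRITERION_IDS:
            raise ValidationError(f"unknown criterion {self.criterion_id!r}")
        if not (0.0 <= self.power_floor < 1.0):
            raise ValidationError("power_floor must lie in [0, 1)")

    @property
    def requires_floor(self) -> bool:
        return self.criterion_id in ("OC2", "OC4")

    @property
    def maximises_efficiency(self) -> bool:
        """True for the power-per-patient criteria OC3/OC4."""
        return self.criterion_id in ("OC3", "OC4")

    def label(self) -> str:
        return {
            "OC1": "OC1: min{E(N)}",
            "OC2": "OC2: I{P>1-beta}min{E(N)}",
            "OC3": "OC3: max{P/E(N)}",
            "OC4": "OC4: I{P>1-beta}max{P/E(N)}",
        }[self.criterion_id]


def optimal_plan_at(
    performances: dict[str, tuple[float, float]],
    criterion: OptimalityCriterion,
) -> str:
    """Winner at one lattice point given per-plan ``(power, expected_n)``
    metrics; returns ``"none"`` when the feasibility floor empties the
    candidate set (OC2/OC4 only)."""
    missing = [pid for pid in PLAN_IDS if pid not in performances]
    if missing:
        raise ValidationError(f"missing plan metrics for {missing}")
    candidates = list(PLAN_IDS)
    if criterion.requires_floor:
        candidates = [
            pid for pid in candidates
            if performances[pid][0] > criterion.power_floor
        ]
        if not candidates:
            return NO_PLAN
    if criterion.maximises_efficiency:
        key = [performances[pid][0] / performances[pid][1] for pid in candidates]
        best = max(key)
    else:
        key = [performances[pid][1] for pid in candidates]
        best = min(key)
    # lowest plan index wins ties
    return candidates[key.index(best)]


@dataclass(frozen=True)
class OptimalityMap:
    """Winning plan (or ``"none"``) at each lattice point, ``[i_pC, j_pE]``."""

    criterion: OptimalityCriterion
    pC_values: np.ndarray
    pE_values: np.ndarray
    winners: np.ndarray  # dtype object/str
    tie_break: str = "lowest plan index"

    def to_frame(self) -> pd.DataFrame:
        pc, pe = np.meshgrid(self.pC_values, self.pE_values, indexing="ij")
        return pd.DataFrame(
            {
                "pC": pc.ravel(),
                "pE": pe.ravel(),
                "criterion": self.criterion.criterion_id,
                "winner": self.winners.ravel(),
            }
        )


def build_optimality_map(
    grids: dict[str, PerformanceGrid],
    criterion: OptimalityCriterion,
) -> OptimalityMap:
    """Apply :func:`optimal_plan_at` pointwise over shared lattices."""
    ref = grids[PLAN_IDS[0]]
    for pid in PLAN_IDS:
        if pid not in grids:
            raise ValidationError(f"missing performance grid for {pid}")
        g = grids[pid]
        if not (
            np.array_equal(g.pC_values, ref.pC_values)
            and np.array_equal(g.pE_values, ref.pE_values)
        ):
            raise ValidationError("performance grids must share one lattice")

    power = np.stack([grids[pid].power for pid in PLAN_IDS])
    en = np.stack([grids[pid].expected_n for pid in PLAN_IDS])
    if criterion.maximises_efficiency:
        score = power / en
        score_best = np.nanmax
    else:
        score = -en
        score_best = np.nanmax
    if criterion.requires_floor:
        score = np.where(power > criterion.power_floor, score, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        best = score_best(score, axis=0)
    winners = np.full(best.shape, NO_PLAN, dtype=object)
    for idx in range(len(PLAN_IDS) - 1, -1, -1):  # low index wins ties
        hit = score[idx] >= best - 0.0  # exact comparison; NaN never hits
        winners[np.where(hit)] = PLAN_IDS[idx]
    return OptimalityMap(
        criterion=criterion,
        pC_values=ref.pC_values,
        pE_values=ref.pE_values,
        winners=winners,
    )


@dataclass(frozen=True)
class ReferencePrior:
    """A beta density over ``pE`` encoding the sceptic or enthusiast stance."""

    stance: str
    shape_a: float
    shape_b: float

    def __post_init__(self) -> None:
        if self.stance not in ("sceptic", "enthusiast"):
            raise ValidationError(f"unknown stance {self.stance!r}")
        if self.shape_a <= 0.0 or self.shape_b <= 0.0:
            raise ValidationError("beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.shape_a / (self.shape_a + self.shape_b)

    @property
    def mode(self) -> float:
        if self.shape_a <= 1.0 or self.shape_b <= 1.0:
            raise ValidationError("mode undefined unless both shapes exceed 1")
        return (self.shape_a - 1.0) / (self.shape_a + self.shape_b - 2.0)

    def pdf(self, x) -> np.ndarray:
        return beta_dist.pdf(x, self.shape_a, self.shape_b)

    def cdf(self, x) -> np.ndarray:
        return beta_dist.cdf(x, self.shape_a, self.shape_b)


def fit_reference_prior(stance: str, p0: float, p1: float) -> ReferencePrior:
    """Fit the two-constraint beta prior for the given stance.

    The sceptic prior is centred (mode) at ``p0`` with upper-tail mass
    ``P(pE > p1) = 0.10``; the enthusiast prior is centred at ``p1`` with
    lower-tail mass ``P(pE < p0) = 0.10``.  With the mode pinned through
    ``b = 1 + (a - 1)(1 - c)/c``, the tail mass is monotone in the first
    shape parameter, so the second constraint is solved by a bracketed root
    search in ``log(a - 1)``.
    """
    if not (0.0 < p0 < p1 < 1.0):
        raise ValidationError(f"need 0 < p0 < p1 < 1; got p0={p0}, p1={p1}")
    if stance == "sceptic":
        centre, edge, tail = p0, p1, "upper"
    elif stance == "enthusiast":
        centre, edge, tail = p1, p0, "lower"
    else:
        raise ValidationError(f"unknown stance {stance!r}")

    def shapes(log_am1: float) -> tuple[float, float]:
        a = 1.0 + math.exp(log_am1)
        return a, 1.0 + (a - 1.0) * (1.0 - centre) / centre

    def tail_mass(log_am1: float) -> float:
        a, b = shapes(log_am1)
        if tail == "upper":
            return float(beta_dist.sf(edge, a, b))
        return float(beta_dist.cdf(edge, a, b))

    lo, hi = -14.0, 14.0
    f_lo, f_hi = tail_mass(lo) - TAIL_MASS, tail_mass(hi) - TAIL_MASS
    if f_lo * f_hi > 0.0:
        raise InfeasibleDesignError(
            f"no beta prior with mode {centre} attains {tail}-tail mass "
            f"{TAIL_MASS} at {edge}"
        )
    log_am1 = brentq(lambda v: tail_mass(v) - TAIL_MASS, lo, hi, xtol=1e-13)
    a, b = shapes(log_am1)
    return ReferencePrior(stance=stance, shape_a=a, shape_b=b)


@dataclass(frozen=True)
class PlanUsageProbabilities:
    """Partition of prior mass by winning plan class along ``pC = p0``."""

    p_none: float
    p_single: float
    p_twoarm: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_none, self.p_single, self.p_twoarm)


def usage_probabilities(
    opt_map: OptimalityMap,
    prior: ReferencePrior,
    p0: float,
) -> PlanUsageProbabilities:
    """Prior probabilities that no plan, a single-arm-incorporating plan
    (DP1-DP2), or a randomised-only plan (DP3-DP6) is optimal along the line
    ``pC = p0``.

    Each lattice point ``pE_j`` represents the cell bounded by the midpoints
    to its neighbours; the prior mass per cell is the difference of the beta
    distribution function across the cell edges, so the partition is exact
    for the given winner assignment.
    """
    i = int(np.argmin(np.abs(opt_map.pC_values - p0)))
    offset = abs(float(opt_map.pC_values[i]) - p0)
    if offset > 1e-9:
        warnings.warn(
            f"p0={p0} is off-lattice; using nearest line pC="
            f"{opt_map.pC_values[i]} (offset {offset:.4g})",
            stacklevel=2,
        )
    winners = opt_map.winners[i]
    pe = opt_map.pE_values
    edges = np.concatenate(([pe[0]], (pe[:-1] + pe[1:]) / 2.0, [pe[-1]]))
    edges[0] = min(edges[0], 0.0)
    edges[-1] = max(edges[-1], 1.0)
    cdf = prior.cdf(edges)
    mass = np.diff(cdf)
    p_none = float(mass[winners == NO_PLAN].sum())
    single = np.isin(winners.astype(str), list(SINGLE_ARM_PLANS))
    p_single = float(mass[single].sum())
    p_twoarm = float(mass.sum() - p_none - p_single)
    return PlanUsageProbabilities(p_none, p_single, p_twoarm)
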