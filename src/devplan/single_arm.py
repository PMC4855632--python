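"""Simon two-stage single-arm designs with exact binomial calculations.

A Simon two-stage design recruits ``n1`` patients and stops for futility
(a "no-go") when at most ``r1`` respond.  Otherwise a further ``n - n1``
patients are recruited and the null hypothesis ``H0: pE <= p0`` is rejected
(a "go") when the total number of responses exceeds ``r``.  The optional
boundary ``e1`` additionally permits an early "go" at stage one when the
stage-one responses exceed ``e1`` (strictly, mirroring the ``r/n`` rule), a
family of designs due to Mander and Thompson.  All probabilities here are
exact binomial sums; no normal approximation is used for single-arm trials.

The search :func:`search_simon_optimal` returns the H0-optimal design: the
feasible design minimising the expected sample size under the null response
rate ``p0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import binom

from .errors import InfeasibleDesignError, ValidationError

__all__ = [
    "SingleArmHypotheses",
    "SimonTwoStageDesign",
    "SingleArmOperatingCharacteristics",
    "simon_reject_probability",
    "simon_operating_characteristics",
    "search_simon_optimal",
]


def _check_probability(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class SingleArmHypotheses:
    """Hypotheses ``H0: pE <= p0`` versus ``H1: pE >= p1`` for a single-arm
    binary-endpoint trial, with one-sided error bounds ``alpha_s``/``beta_s``."""

    p0: float
    p1: float
    alpha_s: float
    beta_s: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValidationError(
                f"need 0 < p0 < p1 < 1; got p0={self.p0}, p1={self.p1}"
            )
        for name in ("alpha_s", "beta_s"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")


@dataclass(frozen=True)
class SimonTwoStageDesign:
    """A two-stage single-arm design ``r1/n1 r/n``, optionally with an early
    efficacy boundary ``e1`` (notation ``(r1 e1)/n1 r/n``).

    Decision rules: stop no-go after stage one if responses <= r1; stop go if
    responses > e1 (when ``e1`` is set); otherwise continue to ``n`` patients
    and declare go if total responses > r.  Both ``e1`` and ``r`` are strict
    boundaries, as in the conventional tabulated notation.
    """

    r1: int
    n1: int
    r: int
    n: int
    e1: int | None = None

    def __post_init__(self) -> None:
        ok = 0 <= self.r1 < self.n1 < self.n and self.r1 <= self.r < self.n
        if self.e1 is not None:
            ok = ok and (self.r1 < self.e1 <= self.n1)
        if not ok:
            raise ValidationError(f"invalid Simon design parameters: {self}")

    @property
    def has_efficacy_stopping(self) -> bool:
        return self.e1 is not None and self.e1 < self.n1

    @property
    def n2(self) -> int:
        return self.n - self.n1

    def notation(self) -> str:
        """The conventional printed form, e.g. ``3/19 12/55`` or
        ``(3 7)/19 12/55``."""
        if self.e1 is None:
            return f"{self.r1}/{self.n1} {self.r}/{self.n}"
        return f"({self.r1} {self.e1})/{self.n1} {self.r}/{self.n}"

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.e1 is None:
            d.pop("e1")
        return d

    @classmethod
    def from_dict(cls, record: dict) -> "SimonTwoStageDesign":
        return cls(
            r1=int(record["r1"]),
            n1=int(record["n1"]),
            r=int(record["r"]),
            n=int(record["n"]),
            e1=None if record.get("e1") is None else int(record["e1"]),
        )


@dataclass(frozen=True)
class SingleArmOperatingCharacteristics:
    """Operating characteristics of a Simon design at a response rate ``p``."""

    reject_prob: float
    expected_n: float
    pet: float  # probability of early termination (either cause)


def _stage_boundaries(design: SimonTwoStageDesign) -> tuple[int, int]:
    """Continuation region at stage one is ``r1 < x1 <= hi`` with ``hi = e1``
    (or ``n1`` when no efficacy stopping)."""
    hi = design.e1 if design.e1 is not None else design.n1
    return design.r1, hi


def simon_reject_probability(design: SimonTwoStageDesign, p: float) -> float:
    """Exact probability that the design rejects H0 (declares a go) when the
    true response rate is ``p``.

    Sums, over continuation outcomes ``x1``, the stage-one binomial mass times
    the stage-two tail ``P(X2 > r - x1)``, plus the direct efficacy-stop mass
    ``P(X1 > e1)`` when early go stopping is present.
    """
    _check_probability(p, "p")
    lo, hi = _stage_boundaries(design)
    x1 = np.arange(lo + 1, hi + 1)
    mass1 = binom.pmf(x1, design.n1, p)
    tail2 = binom.sf(design.r - x1, design.n2, p)  # P(X2 > r - x1); 1 if r - x1 < 0
    prob = float(np.dot(mass1, tail2))
    if design.e1 is not None:
        prob += float(binom.sf(design.e1, design.n1, p))
    return min(1.0, prob)


def simon_operating_characteristics(
    design: SimonTwoStageDesign, p: float
) -> SingleArmOperatingCharacteristics:
    """Rejection probability, early-termination probability and expected
    sample size ``n1 + (1 - PET) * (n - n1)`` at response rate ``p``."""
    _check_probability(p, "p")
    pet = float(binom.cdf(design.r1, design.n1, p))
    if design.e1 is not None:
        pet += float(binom.sf(design.e1, design.n1, p))
    pet = min(1.0, pet)
    expected_n = design.n1 + (1.0 - pet) * design.n2
    return SingleArmOperatingCharacteristics(
        reject_prob=simon_reject_probability(design, p),
        expected_n=expected_n,
        pet=pet,
    )


def search_simon_optimal(
    hyp: SingleArmHypotheses,
    efficacy_stopping: bool = False,
    n_max_search: int = 100,
) -> SimonTwoStageDesign:
    """Exhaustive search for the H0-optimal Simon two-stage design.

    Enumerates maximum sample sizes ``n`` ascending, stage-one sizes ``n1``
    ascending and boundaries ascending; among all designs with type-I error
    at ``p0`` at most ``alpha_s`` and power at ``p1`` at least ``1 - beta_s``,
    the one minimising the expected sample size under ``p0`` is returned
    (first encountered on ties, i.e. smallest ``n``).  With
    ``efficacy_stopping`` the search additionally ranges over the early go
    boundary ``e1``, still minimising E(N | p0).

    Raises
    ------
    InfeasibleDesignError
        If no design with ``n <= n_max_search`` meets both error constraints.
    """
    if n_max_search < 2:
        raise ValidationError("n_max_search must be at least 2")
    p0, p1 = hyp.p0, hyp.p1
    alpha, beta = hyp.alpha_s, hyp.beta_s
    eps = 1e-12

    best_en = math.inf
    best: SimonTwoStageDesign | None = None

    # Stage pmf/cdf tables, indexed by sample size.
    pmf0: dict[int, np.ndarray] = {}
    pmf1: dict[int, np.ndarray] = {}

    def tables(m: int) -> tuple[np.ndarray, np.ndarray]:
        if m not in pmf0:
            k = np.arange(m + 1)
            pmf0[m] = binom.pmf(k, m, p0)
            pmf1[m] = binom.pmf(k, m, p1)
        return pmf0[m], pmf1[m]

    for n in range(2, n_max_search + 1):
        for n1 in range(1, n):
            if n1 >= best_en:  # E(N|p0) >= n1: cannot improve
                break
            n2 = n - n1
            f0_1, f1_1 = tables(n1)
            cdf0_1 = np.cumsum(f0_1)
            cdf1_1 = np.cumsum(f1_1)
            f0_2, f1_2 = tables(n2)
            # Stage-two strict tails P(X2 > k) for k = -1 .. n2 (index k+1).
            sf0_2 = np.concatenate(([1.0], 1.0 - np.cumsum(f0_2)))
            sf1_2 = np.concatenate(([1.0], 1.0 - np.cumsum(f1_2)))
            np.clip(sf0_2, 0.0, 1.0, out=sf0_2)
            np.clip(sf1_2, 0.0, 1.0, out=sf1_2)

            for r1 in range(0, n1):
                if cdf1_1[r1] > beta + eps:
                    break  # futility stop alone already exceeds beta
                # Candidate totals r range over r1 .. n - 1.
                r_vals = np.arange(r1, n)
                x1 = np.arange(r1 + 1, n1 + 1)
                if x1.size == 0:
                    continue
                # tail index r - x1 clipped into [-1, n2]
                idx = np.clip(r_vals[None, :] - x1[:, None], -1, n2) + 1
                a0 = f0_1[x1][:, None] * sf0_2[idx]
                a1 = f1_1[x1][:, None] * sf1_2[idx]
                # cum0[j, :] = sum over the first j continuation outcomes
                cum0 = np.cumsum(a0, axis=0)
                cum1 = np.cumsum(a1, axis=0)

                # Efficacy boundaries e1 in r1+1 .. n1 (e1 = n1 is vacuous,
                # matching the no-stopping design).  Continuation outcomes
                # are r1 < x1 <= e1; the first (e1 - r1) rows of cum* apply.
                if efficacy_stopping:
                    e1_vals = np.arange(r1 + 1, n1 + 1)
                else:
                    e1_vals = np.array([n1])
                ncont = e1_vals - r1
                tail0_1 = 1.0 - cdf0_1[e1_vals]
                tail1_1 = 1.0 - cdf1_1[e1_vals]

                zero = np.zeros((1, r_vals.size))
                cum0p = np.concatenate([zero, cum0], axis=0)
                cum1p = np.concatenate([zero, cum1], axis=0)
                rej0 = cum0p[ncont] + tail0_1[:, None]
                rej1 = cum1p[ncont] + tail1_1[:, None]

                feasible_r = rej0 <= alpha + eps
                any_r = feasible_r.any(axis=1)
                if not any_r.any():
                    continue
                first_r = np.argmax(feasible_r, axis=1)
                power_ok = (
                    rej1[np.arange(e1_vals.size), first_r] >= 1.0 - beta - eps
                )
                good = any_r & power_ok
                if not good.any():
                    continue

                pet0 = cdf0_1[r1] + tail0_1
                en0 = n1 + (1.0 - pet0) * n2
                en0 = np.where(good, en0, math.inf)
                j = int(np.argmin(en0))
                if en0[j] < best_en - eps:
                    best_en = float(en0[j])
                    e1 = int(e1_vals[j]) if efficacy_stopping else None
                    best = SimonTwoStageDesign(
                        r1=r1,
                        n1=n1,
                        r=int(r_vals[first_r[j]]),
                        n=n,
                        e1=e1,
                    )

    if best is None:
        raise InfeasibleDesignError(
            f"no Simon two-stage design with n <= {n_max_search} attains "
            f"alpha_s={alpha}, beta_s={beta} for p0={p0}, p1={p1}; "
            "increase n_max_search"
        )
    return best
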