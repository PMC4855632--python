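"""Fixed-sample and error-spending group-sequential two-arm designs.

The randomised trials compare an experimental response rate ``pE`` with a
control rate ``pC`` through the one-sided hypotheses ``H0: pE - pC <= 0``
versus ``H1: pE - pC >= p1 - p0``.  The fixed design uses the normal
approximation to the difference of two binomial proportions.  Group-sequential
designs are built with the Lan-DeMets error-spending approach using the
rho-family spending function ``f(t) = err * t**rho`` of the cumulative
information fraction ``t``, spending type-I error only at looks where a go
decision is permitted and type-II error at every look.  Futility boundaries
are binding.

Operating characteristics follow from the canonical joint distribution of the
sequence of standardised statistics: ``Z_k ~ N(drift * sqrt(t_k), 1)`` with
``Cov(Z_j, Z_k) = sqrt(t_j / t_k)``, where ``drift = (pE - pC) *
sqrt(I_max)`` and ``I_max = n_per_arm / (pC*(1-pC) + pE*(1-pE))`` is the
maximum Fisher information with true-rate (unpooled) variance.  First-passage
probabilities are computed by the classical recursive numerical integration of
the continuation density over a Simpson grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError, ValidationError

__all__ = [
    "TwoArmHypotheses",
    "FixedTwoArmDesign",
    "GroupSequentialDesign",
    "StageStoppingProbabilities",
    "fixed_sample_size",
    "fixed_reject_probability",
    "spending_value",
    "stage_probabilities",
    "derive_error_spending_design",
    "gs_expected_sample_size",
    "gs_reject_probability",
    "drift_at",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class TwoArmHypotheses:
    """One-sided two-arm hypotheses with design rates and error bounds."""

    p0: float
    p1: float
    alpha_r: float
    beta_r: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0 and 0.0 < self.p1 < 1.0):
            raise ValidationError("p0 and p1 must lie in (0, 1)")
        if self.p1 <= self.p0:
            raise ValidationError(
                f"degenerate effect: need p1 > p0, got p0={self.p0}, p1={self.p1}"
            )
        for name in ("alpha_r", "beta_r"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")

    @property
    def variance(self) -> float:
        """Unpooled variance term ``p0(1-p0) + p1(1-p1)`` of the difference
        in sample proportions (per patient pair)."""
        return self.p0 * (1.0 - self.p0) + self.p1 * (1.0 - self.p1)


@dataclass(frozen=True)
class FixedTwoArmDesign:
    """Single-stage design: reject H0 when the standardised difference in
    proportions exceeds ``critical_z``."""

    n_per_arm: int
    critical_z: float

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValidationError("n_per_arm must be >= 1")

    @property
    def total_n(self) -> int:
        return 2 * self.n_per_arm


def fixed_sample_size(hyp: TwoArmHypotheses) -> FixedTwoArmDesign:
    """Minimum per-arm size by the normal approximation to the difference of
    two binomial proportions:

    ``n = ceil((z_alpha + z_beta)^2 (p0 q0 + p1 q1) / (p1 - p0)^2)``.
    """
    z_a = norm.isf(hyp.alpha_r)
    z_b = norm.isf(hyp.beta_r)
    n = (z_a + z_b) ** 2 * hyp.variance / (hyp.p1 - hyp.p0) ** 2
    return FixedTwoArmDesign(n_per_arm=math.ceil(n - 1e-12), critical_z=z_a)


def _drift(pC: float, pE: float, n_per_arm: float) -> float:
    """Mean of the final standardised statistic under true rates (pC, pE),
    with unpooled true-rate variance.  Degenerate-variance corners return the
    continuous limit along the diagonal (0) or +/- infinity off it."""
    for name, v in (("pC", pC), ("pE", pE)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
    var = pC * (1.0 - pC) + pE * (1.0 - pE)
    if var <= 0.0:
        if pE > pC:
            return math.inf
        if pE < pC:
            return -math.inf
        return 0.0
    return (pE - pC) * math.sqrt(n_per_arm / var)


def drift_at(pC: float, pE: float, n_per_arm: float) -> float:
    """Public wrapper for the drift of a design of ``n_per_arm`` patients per
    arm at true rates ``(pC, pE)``."""
    return _drift(pC, pE, n_per_arm)


def fixed_reject_probability(
    design: FixedTwoArmDesign, pC: float, pE: float
) -> float:
    """Normal-approximate probability of rejecting H0 at true rates
    ``(pC, pE)``: ``Phi(drift - critical_z)``."""
    delta = _drift(pC, pE, design.n_per_arm)
    if math.isinf(delta):
        return 1.0 if delta > 0 else 0.0
    return float(norm.sf(design.critical_z - delta))


def spending_value(rho: float, err_total: float, t: float) -> float:
    """Rho-family error spending function ``err_total * t**rho``."""
    if rho <= 0.0:
        raise ValidationError(f"rho must be positive; got {rho}")
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"information fraction t must lie in [0, 1]; got {t}")
    return err_total * t**rho


@dataclass(frozen=True)
class GroupSequentialDesign:
    """A one-sided group-sequential design over ``K`` looks.

    ``efficacy_bounds`` may contain ``inf`` at looks where a go decision is
    not permitted; at the final look the efficacy and futility boundaries
    coincide so that the trial always terminates with a decision.
    """

    stage_n_per_arm: tuple[int, ...]  # cumulative per-arm sizes
    info_fractions: tuple[float, ...]
    efficacy_bounds: tuple[float, ...]
    futility_bounds: tuple[float, ...]
    rho: float
    go_allowed: tuple[bool, ...]
    alpha_r: float
    beta_r: float
    solved_total: float | None = None  # continuous maximum total, pre-rounding

    def __post_init__(self) -> None:
        k = len(self.stage_n_per_arm)
        if not (
            k
            == len(self.info_fractions)
            == len(self.efficacy_bounds)
            == len(self.futility_bounds)
            == len(self.go_allowed)
        ):
            raise ValidationError("per-look fields must have equal length")
        if k < 1:
            raise ValidationError("need at least one look")
        t = np.asarray(self.info_fractions)
        if np.any(np.diff(t) <= 0.0) or abs(t[-1] - 1.0) > 1e-9:
            raise ValidationError(
                "info_fractions must be strictly increasing with final value 1"
            )
        if np.any(np.diff(self.stage_n_per_arm) <= 0):
            raise ValidationError("stage_n_per_arm must be strictly increasing")
        for l, u in zip(self.futility_bounds[:-1], self.efficacy_bounds[:-1]):
            if l >= u:
                raise ValidationError("interim boundaries must satisfy l_k < u_k")
        if abs(self.futility_bounds[-1] - self.efficacy_bounds[-1]) > 1e-9:
            raise ValidationError("final boundaries must coincide")
        if not self.go_allowed[-1]:
            raise ValidationError("final look must allow a go decision")

    @property
    def n_looks(self) -> int:
        return len(self.stage_n_per_arm)

    @property
    def n_per_arm_max(self) -> int:
        return self.stage_n_per_arm[-1]

    @property
    def total_sizes(self) -> tuple[int, ...]:
        """Cumulative total (both-arm) sample sizes at each look."""
        return tuple(2 * n for n in self.stage_n_per_arm)

    @property
    def max_total(self) -> int:
        return 2 * self.n_per_arm_max

    def to_dict(self) -> dict:
        d = asdict(self)
        d["efficacy_bounds"] = [
            None if math.isinf(u) else u for u in self.efficacy_bounds
        ]
        return d

    @classmethod
    def from_dict(cls, record: dict) -> "GroupSequentialDesign":
        u = tuple(
            math.inf if v is None else float(v) for v in record["efficacy_bounds"]
        )
        return cls(
            stage_n_per_arm=tuple(int(v) for v in record["stage_n_per_arm"]),
            info_fractions=tuple(float(v) for v in record["info_fractions"]),
            efficacy_bounds=u,
            futility_bounds=tuple(float(v) for v in record["futility_bounds"]),
            rho=float(record["rho"]),
            go_allowed=tuple(bool(v) for v in record["go_allowed"]),
            alpha_r=float(record["alpha_r"]),
            beta_r=float(record["beta_r"]),
            solved_total=record.get("solved_total"),
        )

    def boundary_table(self) -> pd.DataFrame:
        """Human-readable boundary table (look, cumulative sizes, t_k, l_k, u_k)."""
        return pd.DataFrame(
            {
                "look": np.arange(1, self.n_looks + 1),
                "n_per_arm_cum": self.stage_n_per_arm,
                "n_total_cum": self.total_sizes,
                "info_fraction": self.info_fractions,
                "futility_z": self.futility_bounds,
                "efficacy_z": self.efficacy_bounds,
                "go_allowed": self.go_allowed,
            }
        )


@dataclass(frozen=True)
class StageStoppingProbabilities:
    """First-passage probabilities across the go and no-go boundaries."""

    go_by_stage: tuple[float, ...]
    nogo_by_stage: tuple[float, ...]

    @property
    def total_go(self) -> float:
        return float(sum(self.go_by_stage))

    @property
    def total_nogo(self) -> float:
        return float(sum(self.nogo_by_stage))


# ---------------------------------------------------------------------------
# Recursive numerical integration over the continuation region
# ---------------------------------------------------------------------------


def _simpson_grid(lo: float, hi: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Simpson nodes and weights on [lo, hi] with m nodes (m odd, >= 3)."""
    x = np.linspace(lo, hi, m)
    h = (hi - lo) / (m - 1)
    w = np.full(m, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    w *= h / 3.0
    return x, w


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / _SQRT2PI


class _GridRecursion:
    """Propagates the subdensity of the standardised statistic through the
    continuation regions of successive looks, for one drift value.

    After look ``k`` the state holds nodes/weights/values of the (defective)
    density of ``Z_k`` restricted to the continuation region, from which
    boundary-crossing probabilities at look ``k + 1`` are closed-form normal
    integrals against the transition kernel.
    """

    def __init__(self, info_fractions, drift: float, grid_points: int = 129):
        self.t = np.asarray(info_fractions, dtype=float)
        self.drift = float(drift)
        self.m = int(grid_points)
        if self.m < 9 or self.m % 2 == 0:
            raise ValidationError("grid_points must be odd and >= 9")
        self.k = 0  # looks consumed
        self.x = self.w = self.f = None

    # -- probabilities of crossing at the *next* look -----------------------
    def _next_stats(self, z: float, upper: bool) -> float:
        """P(continue through looks 1..k, cross boundary z at look k+1)."""
        tk1 = self.t[self.k]
        mean1 = self.drift * math.sqrt(tk1)
        if self.k == 0:
            return float(norm.sf(z - mean1) if upper else norm.cdf(z - mean1))
        tk = self.t[self.k - 1]
        a, b = math.sqrt(tk), math.sqrt(tk1)
        dt = tk1 - tk
        s = math.sqrt(dt)
        arg = (z * b - self.x * a - self.drift * dt) / s
        kern = norm.sf(arg) if upper else norm.cdf(arg)
        return float(np.dot(self.w * self.f, kern))

    def upper_crossing(self, z: float) -> float:
        if math.isinf(z):
            return 0.0
        return self._next_stats(z, upper=True)

    def lower_crossing(self, z: float) -> float:
        if math.isinf(z):
            return 0.0 if z < 0 else self.continuation_mass()
        return self._next_stats(z, upper=False)

    def continuation_mass(self) -> float:
        if self.k == 0:
            return 1.0
        return float(np.dot(self.w, self.f))

    # -- advance one look ---------------------------------------------------
    def step(self, lower: float, upper: float) -> None:
        """Truncate to the continuation region (lower, upper) at look k+1 and
        propagate the subdensity."""
        tk1 = self.t[self.k]
        mean1 = self.drift * math.sqrt(tk1)
        cap = max(mean1, 0.0) + 8.0
        lo = lower if math.isfinite(lower) else min(mean1, 0.0) - 8.0
        hi = min(upper, cap) if math.isfinite(upper) else cap
        hi = max(hi, lo + 1e-6)
        y, wy = _simpson_grid(lo, hi, self.m)
        if self.k == 0:
            fy = _phi(y - mean1)
        else:
            tk = self.t[self.k - 1]
            a, b = math.sqrt(tk), math.sqrt(tk1)
            dt = tk1 - tk
            s = math.sqrt(dt)
            arg = (y[:, None] * b - self.x[None, :] * a - self.drift * dt) / s
            fy = (b / s) * _phi(arg) @ (self.w * self.f)
        self.x, self.w, self.f = y, wy, fy
        self.k += 1


def stage_probabilities(
    design: GroupSequentialDesign,
    drift: float,
    grid_points: int = 129,
) -> StageStoppingProbabilities:
    """Per-look first-passage probabilities across the efficacy (go) and
    futility (no-go) boundaries at the given drift.

    Infinite drift returns the deterministic limit (all mass stops at the
    first look where the corresponding decision is permitted).
    """
    K = design.n_looks
    go = [0.0] * K
    nogo = [0.0] * K
    if math.isinf(drift):
        if drift > 0:
            k = next(i for i in range(K) if design.go_allowed[i])
            go[k] = 1.0
        else:
            nogo[0] = 1.0
        return StageStoppingProbabilities(tuple(go), tuple(nogo))

    rec = _GridRecursion(design.info_fractions, drift, grid_points)
    for k in range(K):
        u = design.efficacy_bounds[k]
        l = design.futility_bounds[k]
        go[k] = min(max(rec.upper_crossing(u), 0.0), 1.0)
        if k < K - 1:
            nogo[k] = min(max(rec.lower_crossing(l), 0.0), 1.0)
            rec.step(l, u)
        else:
            # final look: l == u, everything remaining stops
            nogo[k] = max(rec.continuation_mass() - go[k], 0.0)
    total = sum(go) + sum(nogo)
    if total > 1.0:  # integration overshoot at the 1e-12 level
        go = [g / total for g in go]
        nogo = [n / total for n in nogo]
    return StageStoppingProbabilities(tuple(go), tuple(nogo))


def gs_reject_probability(
    design: GroupSequentialDesign,
    pC: float,
    pE: float,
    grid_points: int = 129,
) -> float:
    """Total probability of a go decision at true rates ``(pC, pE)``."""
    delta = _drift(pC, pE, design.n_per_arm_max)
    return stage_probabilities(design, delta, grid_points).total_go


def gs_expected_sample_size(
    design: GroupSequentialDesign,
    pC: float,
    pE: float,
    grid_points: int = 129,
) -> float:
    """Expected total (both-arm) sample size at true rates ``(pC, pE)``."""
    delta = _drift(pC, pE, design.n_per_arm_max)
    probs = stage_probabilities(design, delta, grid_points)
    totals = design.total_sizes
    return float(
        sum(
            T * (g + n)
            for T, g, n in zip(totals, probs.go_by_stage, probs.nogo_by_stage)
        )
    )


# ---------------------------------------------------------------------------
# Error-spending boundary construction
# ---------------------------------------------------------------------------


def _spending_increments(
    total: float, t: np.ndarray, rho: float, active: np.ndarray
) -> np.ndarray:
    """Per-look increments of cumulative spend ``total * t**rho``, accruing
    only at looks flagged active (cumulative spend is flat elsewhere)."""
    inc = np.zeros(len(t))
    spent = 0.0
    for k in range(len(t)):
        if active[k]:
            target = spending_value(rho, total, float(t[k]))
            inc[k] = max(target - spent, 0.0)
            spent = target
    return inc


def _solve_boundaries(
    t: np.ndarray,
    go_allowed: np.ndarray,
    alpha: float,
    beta: float,
    rho: float,
    drift_alt: float,
    grid_points: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Solve the error-spending boundaries look by look.

    Returns interim-complete arrays (u, l) plus the *independently* solved
    final-look efficacy and futility boundaries.  During sizing these two
    should coincide; the caller closes the design with ``l_K = u_K``.
    """
    K = len(t)
    final_active = np.ones(K, dtype=bool)
    d_alpha = _spending_increments(alpha, t, rho, np.asarray(go_allowed))
    d_beta = _spending_increments(beta, t, rho, final_active)

    rec0 = _GridRecursion(t, 0.0, grid_points)
    rec1 = _GridRecursion(t, drift_alt, grid_points)
    u = np.full(K, math.inf)
    l = np.full(K, -math.inf)

    def solve(fun, target, lo, hi):
        # fun is decreasing for upper crossings, increasing for lower ones
        try:
            return brentq(lambda z: fun(z) - target, lo, hi, xtol=1e-10)
        except ValueError as exc:
            raise ConfigurationError(
                f"boundary root search failed (target={target:.3g}): {exc}"
            ) from exc

    hi_z = max(drift_alt, 0.0) + 10.0
    lo_z = min(drift_alt, 0.0) - 10.0
    for k in range(K):
        if go_allowed[k] and d_alpha[k] > 0.0:
            u[k] = solve(rec0.upper_crossing, d_alpha[k], lo_z, hi_z)
        if d_beta[k] > 0.0:
            l[k] = solve(lambda z: -rec1.lower_crossing(z), -d_beta[k], lo_z, hi_z)
        elif k == K - 1:
            l[k] = lo_z
        if k < K - 1:
            if l[k] >= u[k]:
                raise ConfigurationError(
                    f"boundaries cross at interim look {k + 1} "
                    f"(l={l[k]:.4f} >= u={u[k]:.4f}); the spending schedule "
                    "is too aggressive for this information sequence"
                )
            rec0.step(l[k], u[k])
            rec1.step(l[k], u[k])
    if not math.isfinite(u[K - 1]):
        raise ConfigurationError("no type-I error left to spend at the final look")
    return u, l, float(u[K - 1]), float(l[K - 1])


def _ceil_even(x: float) -> int:
    return 2 * math.ceil(x / 2.0 - 1e-9)


def _round_fraction_schedule(n_total_max: float, fractions: np.ndarray) -> np.ndarray:
    """Round a fraction-based look schedule up to whole patients.

    Picks the smallest total size at least the solved one for which every
    cumulative size ``fraction * total`` is an even integer (equal arms at
    every look), preserving the prescribed spacing exactly -- e.g. equally
    spaced thirds round to a multiple of 6.  If no such total exists within
    a reasonable margin, each cumulative size is rounded up to the nearest
    even integer instead.
    """
    for total in range(_ceil_even(n_total_max), _ceil_even(n_total_max) + 600, 2):
        cums = fractions * total
        if np.allclose(cums, np.round(cums), atol=1e-6) and np.all(
            np.round(cums).astype(int) % 2 == 0
        ):
            return np.round(cums)
    return np.array([_ceil_even(T) for T in fractions * n_total_max], dtype=float)


def _totals_from_schedule(
    n_total_max: float,
    info_fractions: np.ndarray | None,
    fixed_totals: tuple[float, ...] | None,
    n_looks: int,
) -> np.ndarray:
    """Cumulative total sizes at each look for a candidate maximum size."""
    if info_fractions is not None:
        return np.asarray(info_fractions) * n_total_max
    fixed = np.asarray(fixed_totals, dtype=float)
    n_free = n_looks - len(fixed)
    spaced = fixed[-1] + np.arange(1, n_free + 1) * (
        (n_total_max - fixed[-1]) / n_free
    )
    return np.concatenate([fixed, spaced])


def derive_error_spending_design(
    hyp: TwoArmHypotheses,
    info_fractions=None,
    go_allowed=None,
    rho: float = 1.0,
    fixed_totals=None,
    n_looks: int | None = None,
    grid_points: int = 129,
    round_sizes: bool = True,
) -> GroupSequentialDesign:
    """Derive a group-sequential design by rho-family error spending.

    The look schedule is given either as ``info_fractions`` (cumulative
    fractions of the maximum sample size, last equal to 1) or as
    ``fixed_totals`` -- the leading cumulative *total* sample sizes in
    patients -- with the remaining ``n_looks - len(fixed_totals)`` looks
    equally spaced up to the solved maximum.  Type-I error ``alpha_r`` is
    spent as ``alpha_r * t**rho`` across go-permitted looks, type-II error
    ``beta_r * t**rho`` across all looks, with binding futility boundaries.
    The maximum information is found by root search so that the final
    efficacy and futility boundaries coincide.

    With ``round_sizes`` (the default) the cumulative total sizes are rounded
    up to the nearest even integer (equal arms), information fractions are
    recomputed from the rounded sizes, and the boundaries re-derived at the
    attained information; the final futility boundary is then set equal to
    the final efficacy boundary, preserving the type-I error exactly.
    """
    if (info_fractions is None) == (fixed_totals is None):
        raise ValidationError(
            "give exactly one of info_fractions or fixed_totals"
        )
    if info_fractions is not None:
        t0 = np.asarray(info_fractions, dtype=float)
        K = len(t0)
        if abs(t0[-1] - 1.0) > 1e-9 or np.any(np.diff(t0) <= 0) or t0[0] <= 0:
            raise ValidationError(
                "info_fractions must be strictly increasing with final value 1"
            )
    else:
        if n_looks is None or n_looks <= len(fixed_totals):
            raise ValidationError(
                "n_looks must exceed the number of fixed interim totals"
            )
        K = int(n_looks)
        if np.any(np.asarray(fixed_totals) <= 0) or np.any(
            np.diff(fixed_totals) <= 0
        ):
            raise ValidationError("fixed_totals must be positive and increasing")
    if go_allowed is None:
        go_allowed = [True] * K
    go_allowed = np.asarray(go_allowed, dtype=bool)
    if len(go_allowed) != K or not go_allowed[-1]:
        raise ValidationError(
            "go_allowed must have one flag per look and allow go at the final look"
        )

    delta = hyp.p1 - hyp.p0
    var = hyp.variance

    def final_gap(n_total_max: float) -> float:
        totals = _totals_from_schedule(n_total_max,
                                       t0 if info_fractions is not None else None,
                                       fixed_totals, K)
        t = totals / totals[-1]
        drift_alt = delta * math.sqrt((n_total_max / 2.0) / var)
        try:
            _, _, u_K, l_K = _solve_boundaries(
                t, go_allowed, hyp.alpha_r, hyp.beta_r, rho, drift_alt,
                grid_points,
            )
        except ConfigurationError:
            # interim boundaries crossed: the candidate size is far beyond
            # what the spending schedule needs
            return 1.0
        return l_K - u_K

    n_fixed = fixed_sample_size(hyp).n_per_arm * 2
    lo = max(0.2 * n_fixed, (fixed_totals[-1] + 2.0) if fixed_totals else 2.0)
    hi = max(4.0 * n_fixed, lo * 2.0)
    try:
        g_lo = final_gap(lo)
        while final_gap(hi) < 0.0 and hi < 64.0 * n_fixed:
            hi *= 2.0
        n_solved = (
            lo if abs(g_lo) < 1e-12 else brentq(final_gap, lo, hi, xtol=1e-8)
        )
    except (ValueError, ConfigurationError) as exc:
        raise ConfigurationError(
            "maximum-information root search failed for spending schedule "
            f"(alpha={hyp.alpha_r}, beta={hyp.beta_r}, rho={rho}): {exc}"
        ) from exc

    totals = _totals_from_schedule(
        n_solved, t0 if info_fractions is not None else None, fixed_totals, K
    )
    if round_sizes:
        if info_fractions is not None:
            totals = _round_fraction_schedule(n_solved, t0)
        else:
            totals = np.array([_ceil_even(T) for T in totals], dtype=float)
    t = totals / totals[-1]
    drift_alt = delta * math.sqrt((totals[-1] / 2.0) / var)
    u, l, u_K, l_K = _solve_boundaries(
        t, go_allowed, hyp.alpha_r, hyp.beta_r, rho, drift_alt, grid_points
    )
    u[K - 1] = u_K
    l[K - 1] = u_K  # close the design; alpha is preserved exactly
    return GroupSequentialDesign(
        stage_n_per_arm=tuple(int(round(T / 2.0)) for T in totals),
        info_fractions=tuple(float(v) for v in t),
        efficacy_bounds=tuple(float(v) for v in u),
        futility_bounds=tuple(float(v) for v in l),
        rho=rho,
        go_allowed=tuple(bool(v) for v in go_allowed),
        alpha_r=hyp.alpha_r,
        beta_r=hyp.beta_r,
        solved_total=float(n_solved),
    )
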