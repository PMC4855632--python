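"""Report builders: design summaries, optimality maps and usage tables.

Builds pandas tables mirroring the layout of the published summary tables
for the worked example (design parameters with operating characteristics at
the global null H0, the global alternative H1 and a user-chosen pair of
observed rates O; and the stance-by-criterion usage probabilities), plus a
machine-readable comparison of a freshly computed scenario against the
published reference values for the non-small-cell lung cancer worked
example (p0=0.15, p1=0.3, alpha=0.0025, beta=0.36, O=(0.15, 0.41)).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optimality import (
    CRITERION_IDS,
    OptimalityCriterion,
    build_optimality_map,
    fit_reference_prior,
    usage_probabilities,
)
from .plans import (
    PLAN_IDS,
    PlanSpecification,
    evaluate_line,
    plan_expected_n,
    plan_power,
)
from .two_arm import GroupSequentialDesign

__all__ = [
    "design_notation",
    "plan_summary_table",
    "usage_table",
    "REFERENCE_PLAN_SUMMARY",
    "REFERENCE_USAGE",
    "compare_to_reference",
    "write_json",
]

# Published reference values for the worked example (per-cell; sample sizes
# to 1 d.p., probabilities to 4 d.p. in the summary, 3 d.p. in usage).
REFERENCE_PLAN_SUMMARY: dict[str, dict[str, float]] = {
    "DP1": {"max_n": 241, "en_h0": 39.2, "p_h0": 0.0024, "en_h1": 199.1,
            "p_h1": 0.6413, "en_o": 236.6, "p_o": 0.9735},
    "DP2": {"max_n": 241, "en_h0": 39.3, "p_h0": 0.0024, "en_h1": 192.7,
            "p_h1": 0.6419, "en_o": 216.9, "p_o": 0.9736},
    "DP3": {"max_n": 302, "en_h0": 302.0, "p_h0": 0.0025, "en_h1": 302.0,
            "p_h1": 0.6427, "en_o": 302.0, "p_o": 0.9929},
    "DP4": {"max_n": 360, "en_h0": 146.7, "p_h0": 0.0025, "en_h1": 252.7,
            "p_h1": 0.6479, "en_o": 176.7, "p_o": 0.9899},
    "DP5": {"max_n": 310, "en_h0": 199.8, "p_h0": 0.0025, "en_h1": 292.6,
            "p_h1": 0.6417, "en_o": 307.1, "p_o": 0.9844},
    "DP6": {"max_n": 346, "en_h0": 146.6, "p_h0": 0.0025, "en_h1": 256.8,
            "p_h1": 0.6424, "en_o": 213.2, "p_o": 0.9872},
}

REFERENCE_USAGE: dict[tuple[str, str], tuple[float, float, float]] = {
    ("OC1", "sceptic"): (0.000, 0.967, 0.033),
    ("OC2", "sceptic"): (0.898, 0.068, 0.033),
    ("OC3", "sceptic"): (0.000, 0.798, 0.202),
    ("OC4", "sceptic"): (0.898, 0.064, 0.038),
    ("OC1", "enthusiast"): (0.000, 0.557, 0.443),
    ("OC2", "enthusiast"): (0.410, 0.147, 0.443),
    ("OC3", "enthusiast"): (0.000, 0.502, 0.498),
    ("OC4", "enthusiast"): (0.410, 0.131, 0.458),
}


def design_notation(plan: PlanSpecification) -> str:
    """Compact printable description of a plan's designs."""
    parts = []
    if plan.single_arm is not None:
        parts.append(plan.single_arm.notation())
    if isinstance(plan.randomised, GroupSequentialDesign):
        parts.append("/".join(str(n) for n in plan.randomised.total_sizes))
    else:
        parts.append(str(plan.randomised.total_n))
    return " + ".join(parts)


def plan_summary_table(
    plans: dict[str, PlanSpecification],
    p0: float,
    p1: float,
    observed: tuple[float, float] = (0.15, 0.41),
) -> pd.DataFrame:
    """Design parameters, maximum size and operating characteristics of each
    plan at H0 (pC=pE=p0), H1 (pC=p0, pE=p1) and the observed rates O."""
    rows = []
    points = {"h0": (p0, p0), "h1": (p0, p1), "o": observed}
    for pid in PLAN_IDS:
        plan = plans[pid]
        if isinstance(plan.randomised, GroupSequentialDesign):
            stage_totals = list(plan.randomised.total_sizes)
        else:
            stage_totals = [plan.randomised.total_n]
        stage_totals += [np.nan] * (3 - len(stage_totals))
        row = {
            "plan": pid,
            "simon_design": plan.single_arm.notation() if plan.single_arm else "N/A",
            "n1": stage_totals[0],
            "n2": stage_totals[1],
            "n3": stage_totals[2],
            "max_n": plan.max_n,
        }
        for tag, (pc, pe) in points.items():
            row[f"en_{tag}"] = plan_expected_n(plan, pc, pe)
            row[f"p_{tag}"] = plan_power(plan, pc, pe)
        rows.append(row)
    return pd.DataFrame(rows).set_index("plan")


def usage_table(
    plans: dict[str, PlanSpecification],
    p0: float,
    p1: float,
    beta: float,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Sceptic/enthusiast usage probabilities for each criterion along the
    line pC = p0 (the published-table layout: criterion x stance -> C, S, T)."""
    n = int(round(1.0 / grid_step))
    pe = np.linspace(0.0, 1.0, n + 1)
    grids = {pid: evaluate_line(plans[pid], p0, pe) for pid in PLAN_IDS}
    priors = {
        stance: fit_reference_prior(stance, p0, p1)
        for stance in ("sceptic", "enthusiast")
    }
    rows = []
    for cid in CRITERION_IDS:
        crit = OptimalityCriterion(cid, power_floor=1.0 - beta)
        omap = build_optimality_map(grids, crit)
        row: dict[str, object] = {"criterion": crit.label()}
        for stance, prior in priors.items():
            u = usage_probabilities(omap, prior, p0)
            row[f"{stance}_C"] = u.p_none
            row[f"{stance}_S"] = u.p_single
            row[f"{stance}_T"] = u.p_twoarm
        rows.append(row)
    return pd.DataFrame(rows).set_index("criterion")


def compare_to_reference(
    summary: pd.DataFrame, usage: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell deltas between freshly computed tables and the published
    reference values of the worked example."""
    records = []
    for pid, ref in REFERENCE_PLAN_SUMMARY.items():
        for key, expected in ref.items():
            got = float(summary.loc[pid, key])
            records.append(
                {"table": "plan_summary", "cell": f"{pid}.{key}",
                 "reference": expected, "computed": got,
                 "delta": got - expected}
            )
    for (cid, stance), expected in REFERENCE_USAGE.items():
        row = usage.iloc[CRITERION_IDS.index(cid)]
        for part, exp_v in zip(("C", "S", "T"), expected):
            got = float(row[f"{stance}_{part}"])
            records.append(
                {"table": "usage", "cell": f"{cid}.{stance}.{part}",
                 "reference": exp_v, "computed": got, "delta": got - exp_v}
            )
    return pd.DataFrame(records)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
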