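"""Scenario runner and incremental cost-effectiveness analysis.

A *scenario* bundles a baseline transition matrix, an optional intervention
effect with its schedule (first year only, or repeated yearly as booster
sessions for people still in mild dependency), per-participant intervention
and booster costs, a discount specification and a starting distribution.
Running a scenario yields its 4-year discounted QALYs and societal costs;
incremental analysis differences two scenarios and classifies the result as
dominant (more QALYs, lower cost), dominated, or a trade-off with an ICER.

The booster schedule applies the effect-modified matrix in every cycle.
Because the effect only alters the mild-dependency row, this is identical to
treating exactly the people who occupy the mild state — the booster target
group — and the booster cost for cycle ``t`` is the unit cost times the
mild-state occupancy at the end of cycle ``t-1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import pandas as pd

from .costing import round_half_up
from .effects import InterventionEffect, apply_effect
from .model_core import (
    CohortDistribution,
    DependencyState,
    DiscountSpec,
    PayoffTable,
    Trajectory,
    TransitionMatrix,
    ValidationError,
    accumulate_outcomes,
    simulate_trajectory,
    validate_matrix,
)

__all__ = [
    "EffectSchedule",
    "Dominance",
    "Scenario",
    "ScenarioResult",
    "Incremental",
    "run_scenario",
    "incremental_analysis",
    "run_bundle",
    "sensitivity_suite",
    "qaly_to_days",
]


class EffectSchedule(str, enum.Enum):
    YEAR1_ONLY = "year1_only"
    BOOSTER_ALL_YEARS = "booster_all_years"


class Dominance(str, enum.Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    TRADEOFF_ICER = "tradeoff_ICER"


@dataclass(frozen=True)
class Scenario:
    """One arm of the cost-effectiveness comparison."""

    label: str
    baseline_matrix: TransitionMatrix
    effect: InterventionEffect | None = None
    effect_schedule: EffectSchedule = EffectSchedule.YEAR1_ONLY
    upfront_cost_pp: float = 0.0
    booster_cost_pp: float = 0.0
    horizon: int = 4
    discount: DiscountSpec = DiscountSpec(0.03)
    start: CohortDistribution | None = None

    def __post_init__(self) -> None:
        if self.upfront_cost_pp < 0 or self.booster_cost_pp < 0:
            raise ValidationError("intervention costs must be non-negative")
        if self.booster_cost_pp > 0 and self.effect_schedule != EffectSchedule.BOOSTER_ALL_YEARS:
            raise ValidationError("booster cost requires the booster_all_years schedule")
        if self.horizon < 1:
            raise ValidationError("horizon must be at least 1 year")


@dataclass(frozen=True)
class ScenarioResult:
    """Discounted outcomes of one scenario run."""

    label: str
    trajectory: Trajectory
    qalys: float
    costs: float
    horizon: int
    discount_rate: float


@dataclass(frozen=True)
class Incremental:
    """Difference of a scenario against its comparator."""

    delta_qalys: float
    delta_costs: float
    dominance: Dominance
    icer: float | None = None


def run_scenario(scenario: Scenario, payoffs: PayoffTable) -> ScenarioResult:
    """Simulate a scenario and accumulate its discounted QALYs and costs.

    First-year-only effects use the modified matrix for cycle 1 and the
    baseline thereafter; booster schedules use the modified matrix every
    cycle and charge the booster unit cost to the mild-state occupancy at
    the start of cycles 2..horizon.  The upfront per-participant cost is
    charged undiscounted at the start of cycle 1.
    """
    base = validate_matrix(scenario.baseline_matrix)
    start = scenario.start or CohortDistribution.all_mild()
    H = scenario.horizon

    if scenario.effect is None:
        matrices = [base] * H
    elif scenario.effect_schedule == EffectSchedule.YEAR1_ONLY:
        matrices = [apply_effect(base, scenario.effect)] + [base] * (H - 1)
    else:
        matrices = [apply_effect(base, scenario.effect)] * H

    traj = simulate_trajectory(start, matrices, H)

    extra = [0.0] * H
    extra[0] = scenario.upfront_cost_pp
    if scenario.effect_schedule == EffectSchedule.BOOSTER_ALL_YEARS:
        mild = int(DependencyState.MILD)
        for t in range(2, H + 1):
            extra[t - 1] = scenario.booster_cost_pp * float(traj.occupancy[t - 1, mild])

    qalys, costs = accumulate_outcomes(traj, payoffs, scenario.discount, extra)
    return ScenarioResult(
        label=scenario.label,
        trajectory=traj,
        qalys=qalys,
        costs=costs,
        horizon=H,
        discount_rate=scenario.discount.annual_rate,
    )


def incremental_analysis(result: ScenarioResult, comparator: ScenarioResult) -> Incremental:
    """ΔQALYs, Δcosts and the dominance classification versus a comparator.

    An ICER (Δcost/ΔQALY) is reported only in the trade-off quadrants;
    for dominant or dominated pairs the ratio is sign-confused and omitted.
    """
    if result.horizon != comparator.horizon:
        raise ValidationError("cannot compare scenarios with different horizons")
    if result.discount_rate != comparator.discount_rate:
        raise ValidationError("cannot compare scenarios with different discount rates")
    dq = result.qalys - comparator.qalys
    dc = result.costs - comparator.costs
    if dq > 0 and dc < 0:
        return Incremental(dq, dc, Dominance.DOMINANT)
    if dq < 0 and dc > 0:
        return Incremental(dq, dc, Dominance.DOMINATED)
    icer = dc / dq if dq != 0 else None
    return Incremental(dq, dc, Dominance.TRADEOFF_ICER, icer)


def run_bundle(
    scenarios: list[Scenario],
    payoffs: PayoffTable,
    comparator_label: str = "no_intervention",
) -> pd.DataFrame:
    """Run a set of scenarios and difference each against the comparator.

    Returns one row per scenario with discounted QALYs, costs, incremental
    deltas versus the comparator scenario and the dominance label (the
    comparator row has empty incrementals).
    """
    labels = [s.label for s in scenarios]
    if comparator_label not in labels:
        raise ValidationError(f"comparator {comparator_label!r} not among scenarios {labels}")
    results = {s.label: run_scenario(s, payoffs) for s in scenarios}
    comp = results[comparator_label]
    rows = []
    for s in scenarios:
        res = results[s.label]
        row = {
            "scenario": s.label,
            "qalys": res.qalys,
            "costs": res.costs,
            "incr_qalys": None,
            "incr_costs": None,
            "dominance": None,
        }
        if s.label != comparator_label:
            inc = incremental_analysis(res, comp)
            row.update(
                incr_qalys=inc.delta_qalys,
                incr_costs=inc.delta_costs,
                dominance=inc.dominance.value,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    return df


def sensitivity_suite(
    scenarios: list[Scenario],
    payoffs: PayoffTable,
    cost_multiplier: float = 1.2,
    effect_scale: float = 0.8,
    comparator_label: str = "no_intervention",
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis.

    Produces three independent analysis sets: the main analysis, a variant
    with all intervention costs (upfront and booster) multiplied by
    ``cost_multiplier``, and a variant with the intervention effect
    attenuated by ``effect_scale`` (0.8 = effective RR moved 20% of the way
    toward 1).  Each variant is differenced against its own comparator.
    """
    if cost_multiplier <= 0 or effect_scale <= 0:
        raise ValidationError("sensitivity multipliers must be positive")

    def costed(s: Scenario) -> Scenario:
        if s.effect is None:
            return s
        return replace(
            s,
            upfront_cost_pp=s.upfront_cost_pp * cost_multiplier,
            booster_cost_pp=s.booster_cost_pp * cost_multiplier,
        )

    def attenuated(s: Scenario) -> Scenario:
        if s.effect is None:
            return s
        return replace(s, effect=s.effect.with_scale(s.effect.effect_scale * effect_scale))

    frames = []
    for analysis, variant in (
        ("main", scenarios),
        ("increased_cost", [costed(s) for s in scenarios]),
        ("reduced_effect", [attenuated(s) for s in scenarios]),
    ):
        df = run_bundle(variant, payoffs, comparator_label)
        df.insert(0, "analysis", analysis)
        df.attrs = {}  # per-bundle result objects do not survive concat
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def qaly_to_days(delta_qalys: float) -> int:
    """Express a QALY difference as whole days of full health (×365,
    rounded half-up; negative differences round toward zero magnitude)."""
    days = delta_qalys * 365.0
    if days >= 0:
        return round_half_up(days)
    return -round_half_up(-days)
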