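"""Published model parameters shipped as ready-to-use fixtures.

These are the printed inputs of the evaluated decision problem: the annual
transition matrix between dependency states, per-state utilities and
societal costs, the one-year trial counts from which intervention effects
are derived, the itemised intervention cost sheets, booster unit costs, the
3%/year discount rate and the 4-year horizon.  Values are transcribed
digit-for-digit; a checksum test guards against drift.
"""

from __future__ import annotations

from .cea_engine import EffectSchedule, Scenario
from .costing import InterventionCostSheet, per_participant_cost
from .effects import EffectConvention, InterventionEffect, TrialArmCounts
from .model_core import (
    CohortDistribution,
    DiscountSpec,
    PayoffTable,
    TransitionMatrix,
    validate_matrix,
)

__all__ = [
    "DISCOUNT_RATE",
    "HORIZON_YEARS",
    "BOOSTER_UNIT_COSTS",
    "transition_matrix",
    "payoff_table",
    "trial_arms",
    "cost_sheets",
    "intervention_effect",
    "main_scenarios",
    "booster_scenarios",
]

DISCOUNT_RATE = 0.03
HORIZON_YEARS = 4

#: EUR per participant for one booster session (one extra senior meeting /
#: one extra preventive home visit).
BOOSTER_UNIT_COSTS = {"senior_meetings": 19.0, "preventive_home_visit": 71.0}

_TRANSITION_ROWS = {
    "mild": [0.79, 0.13, 0.03, 0.02, 0.03],
    "moderate": [0.08, 0.82, 0.03, 0.01, 0.06],
    "severe": [0.02, 0.12, 0.61, 0.11, 0.14],
    "total": [0.00, 0.03, 0.18, 0.63, 0.16],
    "dead": [0.00, 0.00, 0.00, 0.00, 1.00],
}

_PAYOFFS = {
    "mild": {"utility": 0.77, "annual_cost": 2600.0},
    "moderate": {"utility": 0.60, "annual_cost": 7801.0},
    "severe": {"utility": 0.47, "annual_cost": 20708.0},
    "total": {"utility": 0.41, "annual_cost": 62407.0},
    "dead": {"utility": 0.00, "annual_cost": 0.0},
}

# One-year destination counts (mild, moderate, severe, total, dead) for arms
# that all started in mild dependency.
_TRIAL_ARMS = {
    "control": (114, [87, 19, 6, 0, 2]),
    "senior_meetings": (171, [149, 11, 3, 3, 5]),
    "preventive_home_visit": (174, [150, 19, 1, 0, 4]),
}

_COST_SHEETS = {
    "senior_meetings": {
        "participants": 171,
        "items": [
            ("education", 2143.0),
            ("salaries", 21071.0),
            ("travel", 234.0),
            ("rented_rooms", 3222.0),
            ("materials", 623.0),
        ],
    },
    "preventive_home_visit": {
        "participants": 174,
        "items": [
            ("education", 2143.0),
            ("salaries", 9322.0),
            ("travel", 238.0),
            ("rented_rooms", 0.0),
            ("materials", 634.0),
        ],
    },
}


def transition_matrix() -> TransitionMatrix:
    """The published annual transition matrix (death absorbing)."""
    return validate_matrix(TransitionMatrix.from_rows(_TRANSITION_ROWS))


def payoff_table() -> PayoffTable:
    """Per-state HRQoL utilities and annual societal costs (EUR)."""
    return PayoffTable.from_mapping(_PAYOFFS)


def trial_arms() -> dict[str, TrialArmCounts]:
    """One-year trial transition counts for the control and two
    intervention arms."""
    return {
        name: TrialArmCounts(name, n, counts)
        for name, (n, counts) in _TRIAL_ARMS.items()
    }


def cost_sheets() -> dict[str, InterventionCostSheet]:
    """Itemised intervention cost sheets with booster unit costs."""
    return {
        name: InterventionCostSheet(
            label=name,
            items=tuple(spec["items"]),
            participants=spec["participants"],
            booster_unit_cost=BOOSTER_UNIT_COSTS[name],
        )
        for name, spec in _COST_SHEETS.items()
    }


def intervention_effect(
    arm: str,
    convention: EffectConvention | str = EffectConvention.OVERALL_RR_NONDEATH,
    effect_scale: float = 1.0,
) -> InterventionEffect:
    """Effect of a named intervention arm estimated against the control arm."""
    arms = trial_arms()
    return InterventionEffect.from_arms(
        arms[arm], arms["control"], convention=convention, effect_scale=effect_scale
    )


def _scenario_common() -> dict:
    return {
        "baseline_matrix": transition_matrix(),
        "horizon": HORIZON_YEARS,
        "discount": DiscountSpec(DISCOUNT_RATE),
        "start": CohortDistribution.all_mild(),
    }


def main_scenarios(
    convention: EffectConvention | str = EffectConvention.OVERALL_RR_NONDEATH,
    effect_scale: float = 1.0,
) -> list[Scenario]:
    """The main-analysis scenario set: no intervention, senior meetings,
    preventive home visit, each with a one-time first-year effect and the
    rounded per-participant intervention cost charged up front."""
    sheets = cost_sheets()
    common = _scenario_common()
    scenarios = [Scenario(label="no_intervention", **common)]
    for name in ("senior_meetings", "preventive_home_visit"):
        scenarios.append(
            Scenario(
                label=name,
                effect=intervention_effect(name, convention, effect_scale),
                effect_schedule=EffectSchedule.YEAR1_ONLY,
                upfront_cost_pp=per_participant_cost(sheets[name]),
                **common,
            )
        )
    return scenarios


def booster_scenarios(
    convention: EffectConvention | str = EffectConvention.OVERALL_RR_NONDEATH,
    effect_scale: float = 1.0,
) -> list[Scenario]:
    """Booster variant: the first-year effect and cost are repeated in
    years 2-4 for people still in mild dependency."""
    sheets = cost_sheets()
    common = _scenario_common()
    scenarios = [Scenario(label="no_intervention", **common)]
    for name in ("senior_meetings", "preventive_home_visit"):
        scenarios.append(
            Scenario(
                label=name,
                effect=intervention_effect(name, convention, effect_scale),
                effect_schedule=EffectSchedule.BOOSTER_ALL_YEARS,
                upfront_cost_pp=per_participant_cost(sheets[name]),
                booster_cost_pp=sheets[name].booster_unit_cost,
                **common,
            )
        )
    return scenarios
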