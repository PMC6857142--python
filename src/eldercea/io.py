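"""Config parsing and report writing.

Scenario bundles are YAML documents naming the transition matrix, payoffs,
trial arms and scenarios; every component is validated on load and unknown
keys are rejected with their key path.  Results are written as plain CSV
with locale-independent formatting: QALYs to 3 decimals, euros to whole
units, person counts as integers, plus ``#``-prefixed metadata header lines
(package version, convention, seed) so a report is traceable to the run
that produced it.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .cea_engine import EffectSchedule, Scenario, run_bundle, sensitivity_suite
from .effects import EffectConvention, InterventionEffect, TrialArmCounts
from .model_core import (
    CohortDistribution,
    DiscountSpec,
    PayoffTable,
    STATE_LABELS,
    Trajectory,
    TransitionMatrix,
    ValidationError,
    occupancy_report,
    validate_matrix,
)

__all__ = ["ScenarioBundle", "load_config", "dump_fixture_config", "write_reports"]

try:
    _VERSION = importlib.metadata.version("eldercea")
except importlib.metadata.PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

_TOP_KEYS = {
    "discount_rate",
    "horizon",
    "convention",
    "effect_scale",
    "comparator",
    "transition_matrix",
    "payoffs",
    "arms",
    "scenarios",
}
_SCENARIO_KEYS = {"label", "arm", "upfront_cost_pp", "booster_cost_pp", "schedule"}
_ARM_KEYS = {"n", "counts"}
_PAYOFF_KEYS = {"utility", "annual_cost"}


class ConfigError(ValidationError):
    """A scenario-bundle document violates the schema."""


@dataclass(frozen=True)
class ScenarioBundle:
    """A fully validated scenario set ready to run."""

    scenarios: list[Scenario]
    payoffs: PayoffTable
    comparator: str
    convention: EffectConvention
    matrix: TransitionMatrix
    arms: dict[str, TrialArmCounts]
    discount_rate: float
    horizon: int


def _require_keys(mapping: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} at {path}")


def load_config(path: str | Path) -> ScenarioBundle:
    """Load and validate a scenario bundle from a YAML file.

    Every referenced matrix, payoff table and trial arm passes through its
    component validator; schema violations name the offending key path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of bundle keys (file empty or malformed)")
    _require_keys(raw, _TOP_KEYS, "<top level>")
    for key in ("transition_matrix", "payoffs", "arms", "scenarios"):
        if key not in raw:
            raise ConfigError(f"missing required key {key!r} at <top level>")

    rate = float(raw.get("discount_rate", 0.03))
    discount = DiscountSpec(rate)  # raises "rate ≥ 0" violations
    horizon = int(raw.get("horizon", 4))
    convention = EffectConvention(raw.get("convention", "overall_rr_nondeath"))
    effect_scale = float(raw.get("effect_scale", 1.0))
    comparator = str(raw.get("comparator", "no_intervention"))

    matrix = validate_matrix(TransitionMatrix.from_rows(raw["transition_matrix"]))

    for state, spec in raw["payoffs"].items():
        if state not in STATE_LABELS:
            raise ConfigError(f"unknown state {state!r} at payoffs")
        _require_keys(spec, _PAYOFF_KEYS, f"payoffs.{state}")
    payoffs = PayoffTable.from_mapping(raw["payoffs"])

    arms: dict[str, TrialArmCounts] = {}
    for name, spec in raw["arms"].items():
        _require_keys(spec, _ARM_KEYS, f"arms.{name}")
        arms[name] = TrialArmCounts(name, int(spec["n"]), spec["counts"])

    scenarios: list[Scenario] = []
    for i, spec in enumerate(raw["scenarios"]):
        where = f"scenarios[{i}]"
        _require_keys(spec, _SCENARIO_KEYS, where)
        if "label" not in spec:
            raise ConfigError(f"missing 'label' at {where}")
        label = str(spec["label"])
        effect = None
        if "arm" in spec:
            arm_name = spec["arm"]
            if arm_name not in arms:
                raise ConfigError(f"unknown arm {arm_name!r} at {where}")
            if comparator == label:
                raise ConfigError(f"comparator scenario {label!r} cannot carry an effect")
            effect = InterventionEffect.from_arms(
                arms[arm_name], arms[comparator] if comparator in arms else arms["control"],
                convention=convention, effect_scale=effect_scale,
            )
        scenarios.append(
            Scenario(
                label=label,
                baseline_matrix=matrix,
                effect=effect,
                effect_schedule=EffectSchedule(spec.get("schedule", "year1_only")),
                upfront_cost_pp=float(spec.get("upfront_cost_pp", 0.0)),
                booster_cost_pp=float(spec.get("booster_cost_pp", 0.0)),
                horizon=horizon,
                discount=discount,
                start=CohortDistribution.all_mild(),
            )
        )
    if not scenarios:
        raise ConfigError("scenario list is empty")
    labels = [s.label for s in scenarios]
    if comparator not in labels:
        raise ConfigError(f"comparator {comparator!r} not among scenario labels {labels}")
    return ScenarioBundle(
        scenarios=scenarios,
        payoffs=payoffs,
        comparator=comparator,
        convention=convention,
        matrix=matrix,
        arms=arms,
        discount_rate=rate,
        horizon=horizon,
    )


def dump_fixture_config(path: str | Path) -> Path:
    """Serialize the shipped parameter fixtures as a runnable main-analysis
    config; loading it back reproduces the fixtures exactly."""
    from . import fixtures

    sheets = fixtures.cost_sheets()
    from .costing import per_participant_cost

    doc = {
        "discount_rate": fixtures.DISCOUNT_RATE,
        "horizon": fixtures.HORIZON_YEARS,
        "convention": "overall_rr_nondeath",
        "comparator": "no_intervention",
        "transition_matrix": {
            s: [float(x) for x in fixtures.transition_matrix().probs[i]]
            for i, s in enumerate(STATE_LABELS)
        },
        "payoffs": {
            s: {
                "utility": float(fixtures.payoff_table().utilities[i]),
                "annual_cost": float(fixtures.payoff_table().annual_costs[i]),
            }
            for i, s in enumerate(STATE_LABELS)
        },
        "arms": {
            name: {"n": arm.n, "counts": [int(c) for c in arm.counts]}
            for name, arm in fixtures.trial_arms().items()
        },
        "scenarios": [
            {"label": "no_intervention"},
            *[
                {
                    "label": name,
                    "arm": name,
                    "upfront_cost_pp": per_participant_cost(sheets[name]),
                    "schedule": "year1_only",
                }
                for name in ("senior_meetings", "preventive_home_visit")
            ],
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def _header_lines(metadata: Mapping[str, Any] | None) -> str:
    meta = {"generator": f"eldercea {_VERSION}"}
    if metadata:
        meta.update(metadata)
    return "".join(f"# {k}={meta[k]}\n" for k in sorted(meta))


def write_reports(
    results: pd.DataFrame,
    out_dir: str | Path,
    trajectories: Mapping[str, Trajectory] | None = None,
    cohort_size: float = 100.0,
    metadata: Mapping[str, Any] | None = None,
) -> list[Path]:
    """Write the scenario-summary CSV (and, when trajectories are given, a
    per-year occupancy-count CSV) with deterministic formatting.

    The summary table mirrors the accumulated-outcome layout (scenario,
    QALYs to 3 dp, costs in whole euros, incremental deltas, dominance); the
    occupancy table mirrors the person-count layout (year, scenario, one
    integer column per state).  Raises on an empty result set.
    """
    if results is None or len(results) == 0:
        raise ValidationError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _header_lines(metadata)
    written: list[Path] = []

    summary = results.copy()
    summary["qalys"] = summary["qalys"].map(lambda v: f"{v:.3f}")
    summary["costs"] = summary["costs"].map(lambda v: f"{v:.0f}")
    for col in ("incr_qalys", "incr_costs"):
        fmt = "{:.3f}" if col == "incr_qalys" else "{:.0f}"
        summary[col] = summary[col].map(
            lambda v, fmt=fmt: "" if pd.isna(v) else fmt.format(v)
        )
    summary["dominance"] = summary["dominance"].fillna("")
    summary_path = out_dir / "scenario_summary.csv"
    summary_path.write_text(header + summary.to_csv(index=False))
    written.append(summary_path)

    if trajectories:
        frames = []
        for label in sorted(trajectories):
            rep = occupancy_report(trajectories[label], cohort_size)
            rep.insert(1, "scenario", label)
            frames.append(rep)
        occ = pd.concat(frames, ignore_index=True)
        occ_path = out_dir / "occupancy_counts.csv"
        occ_path.write_text(header + occ.to_csv(index=False))
        written.append(occ_path)
    return written


def run_config(bundle: ScenarioBundle) -> pd.DataFrame:
    """Run a loaded bundle's main analysis (thin convenience wrapper)."""
    return run_bundle(bundle.scenarios, bundle.payoffs, bundle.comparator)
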