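"""Intervention effects derived from one-year trial transition counts.

A trial arm starts with ``n`` people in mild dependency and records where
each person is one year later.  The progression risk for a destination is
the observed proportion moving there; an intervention effect is the relative
risk (RR) of progression in a treated arm versus the control arm.  The
effect is applied to the mild-dependency row of the annual transition
matrix, redirecting the saved probability mass back to staying mild.

Because a published analysis can turn counts into a modified matrix row in
more than one defensible way, several application conventions are
first-class here (see :class:`EffectConvention`); the default pools all
non-mild destinations (death included) into a single progression RR and
applies it to the moderate/severe/total destinations, leaving the death
probability at its baseline value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_core import (
    DependencyState,
    N_STATES,
    STATE_LABELS,
    TransitionMatrix,
    ValidationError,
    validate_matrix,
)

__all__ = [
    "NO_INFORMATION",
    "TrialArmCounts",
    "EffectConvention",
    "InterventionEffect",
    "progression_risk",
    "relative_risk",
    "apply_effect",
]


class _NoInformation:
    """Marker for a relative risk that the data cannot identify (0/0)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_INFORMATION"


#: Returned by :func:`relative_risk` when the control arm has zero events
#: for the requested destination: the counts carry no information about the
#: effect there, which is not the same as evidence of no effect.
NO_INFORMATION = _NoInformation()

_PROGRESSION_STATES = (
    DependencyState.MODERATE,
    DependencyState.SEVERE,
    DependencyState.TOTAL,
)


@dataclass(frozen=True)
class TrialArmCounts:
    """Destination-state counts for one trial arm, one year after baseline.

    All participants start in mild dependency, so ``counts[MILD]`` is the
    number who remained mild and the rest progressed (or died).
    """

    arm_label: str
    n: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_STATES,):
            raise ValidationError(f"counts must have {N_STATES} entries")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        if self.n <= 0:
            raise ValidationError("arm size must be positive")
        if int(c.sum()) != self.n:
            raise ValidationError(
                f"arm {self.arm_label!r}: counts sum to {int(c.sum())}, expected n={self.n}"
            )
        object.__setattr__(self, "counts", c)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialArmCounts):
            return NotImplemented
        return (
            self.arm_label == other.arm_label
            and self.n == other.n
            and bool(np.array_equal(self.counts, other.counts))
        )


class EffectConvention(str, enum.Enum):
    """How trial counts are turned into a modified mild-row.

    ``overall_rr_nondeath``
        Pooled progression RR (all non-mild destinations, death included in
        the counts) multiplies the moderate/severe/total probabilities;
        death stays at baseline.  Default.
    ``per_destination_rr``
        Each destination's own RR multiplies its baseline probability
        (destinations with no control events are left unmodified).
    ``direct_proportions``
        The mild row is replaced by the treated arm's observed one-year
        proportions.
    ``moderate_only_rr``
        Only the mild-to-moderate probability is scaled, by the
        moderate-destination RR.
    """

    OVERALL_RR_NONDEATH = "overall_rr_nondeath"
    PER_DESTINATION_RR = "per_destination_rr"
    DIRECT_PROPORTIONS = "direct_proportions"
    MODERATE_ONLY_RR = "moderate_only_rr"


def progression_risk(
    arm: TrialArmCounts, destination: DependencyState | str = "any"
) -> float:
    """Observed one-year risk of ending in ``destination`` (or pooled
    ``"any"`` non-mild destination) for an arm that started all-mild."""
    if destination == "any":
        return float((arm.n - int(arm.counts[DependencyState.MILD])) / arm.n)
    destination = DependencyState(destination)
    if destination == DependencyState.MILD:
        raise ValidationError("progression risk is defined for non-mild destinations")
    return float(arm.counts[destination] / arm.n)


def relative_risk(
    treated: TrialArmCounts,
    control: TrialArmCounts,
    destination: DependencyState | str = "any",
    as_printed: bool = False,
) -> float | _NoInformation:
    """Relative risk of progression, treated versus control.

    Computed on unrounded proportions by default.  ``as_printed=True``
    reproduces two-decimal worked arithmetic (risks rounded to 2 decimals
    before dividing, quotient rounded to 2 decimals), the style used in
    published summaries.  When the control arm has zero events for the
    destination the RR is unidentifiable and :data:`NO_INFORMATION` is
    returned.
    """
    risk_t = progression_risk(treated, destination)
    risk_c = progression_risk(control, destination)
    if as_printed:
        risk_t, risk_c = round(risk_t, 2), round(risk_c, 2)
    if risk_c == 0:
        return NO_INFORMATION
    rr = risk_t / risk_c
    return round(rr, 2) if as_printed else rr


@dataclass(frozen=True)
class InterventionEffect:
    """A one-year intervention effect expressed as relative risks.

    ``effect_scale`` linearly attenuates the effect toward no effect
    (RR = 1): the effective RR is ``1 - effect_scale * (1 - rr)``, so
    ``effect_scale=0.8`` is a "20% reduced effect" and ``effect_scale=0``
    restores the baseline exactly.
    """

    rr_overall_progression: float
    rr_by_destination: Mapping[DependencyState, float | None] = field(default_factory=dict)
    treated_proportions: np.ndarray | None = None
    convention: EffectConvention = EffectConvention.OVERALL_RR_NONDEATH
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_scale <= 1.0):
            raise ValidationError("effect_scale must lie in [0, 1]")
        if self.rr_overall_progression < 0 or not np.isfinite(self.rr_overall_progression):
            raise ValidationError("overall progression RR must be finite and ≥ 0")
        for s, rr in self.rr_by_destination.items():
            if rr is not None and (rr < 0 or not np.isfinite(rr)):
                raise ValidationError(f"RR for {DependencyState(s).label} must be finite and ≥ 0")

    @classmethod
    def from_arms(
        cls,
        treated: TrialArmCounts,
        control: TrialArmCounts,
        convention: EffectConvention | str = EffectConvention.OVERALL_RR_NONDEATH,
        effect_scale: float = 1.0,
    ) -> "InterventionEffect":
        """Estimate the effect from one-year counts of a treated and a
        control arm (unrounded arithmetic)."""
        by_dest: dict[DependencyState, float | None] = {}
        for s in (*_PROGRESSION_STATES, DependencyState.DEAD):
            rr = relative_risk(treated, control, s)
            by_dest[s] = None if rr is NO_INFORMATION else float(rr)
        overall = relative_risk(treated, control, "any")
        if overall is NO_INFORMATION:
            overall = 1.0  # no progression in control: nothing to modify
        return cls(
            rr_overall_progression=float(overall),
            rr_by_destination=by_dest,
            treated_proportions=treated.proportions,
            convention=EffectConvention(convention),
            effect_scale=effect_scale,
        )

    def with_scale(self, effect_scale: float) -> "InterventionEffect":
        return InterventionEffect(
            self.rr_overall_progression,
            self.rr_by_destination,
            self.treated_proportions,
            self.convention,
            effect_scale,
        )

    def with_convention(self, convention: EffectConvention | str) -> "InterventionEffect":
        return InterventionEffect(
            self.rr_overall_progression,
            self.rr_by_destination,
            self.treated_proportions,
            EffectConvention(convention),
            self.effect_scale,
        )

    def _effective(self, rr: float | None) -> float:
        if rr is None:  # unidentifiable: no information is not protection
            return 1.0
        return 1.0 - self.effect_scale * (1.0 - rr)


def apply_effect(
    baseline: TransitionMatrix, effect: InterventionEffect
) -> TransitionMatrix:
    """Build the effect-modified transition matrix for an intervention year.

    Only the mild-dependency row changes; probability mass removed from
    progression destinations is added to staying mild, keeping the row
    stochastic.  The modified matrix is re-validated before being returned.
    """
    validate_matrix(baseline)
    mild = DependencyState.MILD
    row = baseline.row(mild)
    conv = effect.convention

    if conv == EffectConvention.OVERALL_RR_NONDEATH:
        eff = effect._effective(effect.rr_overall_progression)
        for s in _PROGRESSION_STATES:
            row[s] = baseline.probs[mild, s] * eff
    elif conv == EffectConvention.PER_DESTINATION_RR:
        for s in (*_PROGRESSION_STATES, DependencyState.DEAD):
            eff = effect._effective(effect.rr_by_destination.get(s))
            row[s] = baseline.probs[mild, s] * eff
    elif conv == EffectConvention.DIRECT_PROPORTIONS:
        if effect.treated_proportions is None:
            raise ValidationError("direct_proportions convention needs treated arm proportions")
        target = np.asarray(effect.treated_proportions, dtype=float)
        row = row + effect.effect_scale * (target - row)
    elif conv == EffectConvention.MODERATE_ONLY_RR:
        eff = effect._effective(effect.rr_by_destination.get(DependencyState.MODERATE))
        row[DependencyState.MODERATE] = baseline.probs[mild, DependencyState.MODERATE] * eff
    else:  # pragma: no cover - enum is exhaustive
        raise ValidationError(f"unknown convention {conv!r}")

    if conv != EffectConvention.DIRECT_PROPORTIONS:
        non_mild = float(row[1:].sum())
        row[mild] = 1.0 - non_mild
    if np.any(row < 0) or np.any(row > 1):
        raise ValidationError("effect pushed a mild-row probability outside [0, 1]")
    return validate_matrix(baseline.with_row(mild, row))
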