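"""Markov cohort model over five dependency states.

The model describes community-dwelling older people moving yearly between
five levels of dependency in activities of daily living: *mild*, *moderate*,
*severe* and *total* dependency, plus an absorbing *dead* state.  A cohort is
represented by the proportion of people in each state; an annual
row-stochastic transition matrix moves the cohort forward one cycle at a
time.  Health outcomes are valued with per-state utility weights (QALYs) and
annual societal costs, both discounted to present values.

Conventions
-----------
* The cycle length is one year; state occupancy is measured at the *end* of
  each cycle, so cycle-``t`` outcomes are discounted by ``(1+r)**(-t)`` for
  ``t = 1..horizon``.
* Extra per-cycle costs (an upfront intervention cost, booster sessions) are
  charged at the *start* of their cycle: the cost attached to cycle ``t`` is
  discounted by ``(1+r)**(-(t-1))``, so a cycle-1 upfront cost is not
  discounted at all.
* Person-count reports round half-up for display only; propagation always
  uses unrounded proportions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DependencyState",
    "STATE_LABELS",
    "N_STATES",
    "ValidationError",
    "TransitionMatrix",
    "PayoffTable",
    "CohortDistribution",
    "DiscountSpec",
    "Trajectory",
    "validate_matrix",
    "step_cohort",
    "simulate_trajectory",
    "accumulate_outcomes",
    "occupancy_report",
    "round_half_up",
]

ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a model component violates its invariants."""


class DependencyState(enum.IntEnum):
    """Canonical state order: mild < moderate < severe < total < dead."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2
    TOTAL = 3
    DEAD = 4

    @property
    def label(self) -> str:
        return self.name.lower()


STATE_LABELS: tuple[str, ...] = tuple(s.label for s in DependencyState)
N_STATES = len(STATE_LABELS)

#: Transitions that are structurally impossible (probability exactly 0):
#: recovery from total dependency back to mild, and any exit from death.
DISALLOWED_TRANSITIONS: tuple[tuple[DependencyState, DependencyState], ...] = (
    (DependencyState.TOTAL, DependencyState.MILD),
)


def round_half_up(x: float) -> int:
    """Round a non-negative number half-up to the nearest integer.

    Python's built-in ``round`` uses banker's rounding; person-count tables
    in health-economic reporting conventionally round 0.5 upward.
    """
    return int(math.floor(x + 0.5))


def _as_prob_vector(values: Sequence[float], what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (N_STATES,):
        raise ValidationError(f"{what} must have {N_STATES} entries, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class TransitionMatrix:
    """Annual transition probabilities between dependency states.

    ``probs[i, j]`` is the probability of moving from state ``i`` to state
    ``j`` over one year.  Rows follow the canonical state order.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ValidationError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got shape {p.shape}"
            )
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_rows(cls, rows: dict[str, Sequence[float]]) -> "TransitionMatrix":
        """Build a matrix from a mapping of state label to row."""
        missing = [s for s in STATE_LABELS if s not in rows]
        if missing:
            raise ValidationError(f"missing transition rows: {missing}")
        extra = [k for k in rows if k not in STATE_LABELS]
        if extra:
            raise ValidationError(f"unknown transition rows: {extra}")
        p = np.array([_as_prob_vector(rows[s], f"row {s!r}") for s in STATE_LABELS])
        return cls(p)

    def row(self, state: DependencyState) -> np.ndarray:
        return self.probs[int(state)].copy()

    def with_row(self, state: DependencyState, row: Sequence[float]) -> "TransitionMatrix":
        p = self.probs.copy()
        p[int(state)] = _as_prob_vector(row, f"row {state.label!r}")
        return TransitionMatrix(p)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=STATE_LABELS, columns=STATE_LABELS)

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return bool(np.array_equal(self.probs, other.probs))


def validate_matrix(matrix: TransitionMatrix) -> TransitionMatrix:
    """Check all transition-matrix invariants, returning the matrix if valid.

    Raises :class:`ValidationError` naming the offending row for:
    negative probabilities, rows not summing to 1 (within 1e-9), a
    non-absorbing death state, and structurally disallowed transitions.
    """
    p = matrix.probs
    if np.any(p < 0):
        i = int(np.argwhere(p < 0)[0][0])
        raise ValidationError(f"negative probability in row {STATE_LABELS[i]!r}")
    sums = p.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValidationError(f"non-stochastic row: {STATE_LABELS[i]}, sum {sums[i]:.6g}")
    dead = int(DependencyState.DEAD)
    unit = np.zeros(N_STATES)
    unit[dead] = 1.0
    if not np.array_equal(p[dead], unit):
        raise ValidationError("death not absorbing")
    for src, dst in DISALLOWED_TRANSITIONS:
        if p[int(src), int(dst)] != 0.0:
            raise ValidationError(
                f"disallowed transition: {src.label}->{dst.label} must be exactly 0"
            )
    return matrix


@dataclass(frozen=True)
class PayoffTable:
    """Per-state HRQoL utility weights (0-1) and annual societal costs (EUR).

    Societal costs cover health care, home help, informal care and special
    accommodation for one person-year in the state.  Death carries zero
    utility and zero cost.
    """

    utilities: np.ndarray
    annual_costs: np.ndarray

    def __post_init__(self) -> None:
        u = _as_prob_vector(self.utilities, "utilities")
        c = np.asarray(self.annual_costs, dtype=float)
        if c.shape != (N_STATES,):
            raise ValidationError(f"annual_costs must have {N_STATES} entries")
        if np.any(u < 0) or np.any(u > 1):
            raise ValidationError("utilities must lie in [0, 1]")
        if np.any(c < 0):
            raise ValidationError("annual costs must be non-negative")
        dead = int(DependencyState.DEAD)
        if u[dead] != 0.0 or c[dead] != 0.0:
            raise ValidationError("death must have zero utility and zero cost")
        object.__setattr__(self, "utilities", u)
        object.__setattr__(self, "annual_costs", c)

    @classmethod
    def from_mapping(cls, payoffs: dict[str, dict[str, float]]) -> "PayoffTable":
        u = np.array([payoffs[s]["utility"] for s in STATE_LABELS], dtype=float)
        c = np.array([payoffs[s]["annual_cost"] for s in STATE_LABELS], dtype=float)
        return cls(u, c)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PayoffTable):
            return NotImplemented
        return bool(
            np.array_equal(self.utilities, other.utilities)
            and np.array_equal(self.annual_costs, other.annual_costs)
        )


@dataclass(frozen=True)
class CohortDistribution:
    """Proportion of the cohort in each state; shares sum to 1."""

    shares: np.ndarray
    cohort_size: float = 1.0

    def __post_init__(self) -> None:
        s = _as_prob_vector(self.shares, "shares")
        if np.any(s < -ROW_SUM_TOL):
            raise ValidationError("cohort shares must be non-negative")
        if abs(s.sum() - 1.0) > ROW_SUM_TOL:
            raise ValidationError(f"cohort shares must sum to 1, got {s.sum():.6g}")
        if self.cohort_size <= 0:
            raise ValidationError("cohort size must be positive")
        object.__setattr__(self, "shares", np.clip(s, 0.0, None))

    @classmethod
    def all_mild(cls, cohort_size: float = 1.0) -> "CohortDistribution":
        s = np.zeros(N_STATES)
        s[int(DependencyState.MILD)] = 1.0
        return cls(s, cohort_size)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of outcomes; end-of-cycle convention.

    The factor for outcomes observed at the end of cycle ``t`` is
    ``(1 + annual_rate) ** (-t)``.
    """

    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValidationError("discount rate must be ≥ 0")

    def factor(self, t: int) -> float:
        return (1.0 + self.annual_rate) ** (-t)


@dataclass(frozen=True)
class Trajectory:
    """Cohort occupancy over time: row ``t`` is the distribution after
    ``t`` cycles (row 0 is the initial distribution)."""

    occupancy: np.ndarray
    cohort_size: float = 1.0

    def __post_init__(self) -> None:
        o = np.asarray(self.occupancy, dtype=float)
        if o.ndim != 2 or o.shape[1] != N_STATES or o.shape[0] < 1:
            raise ValidationError("occupancy must be a (horizon+1, 5) array")
        object.__setattr__(self, "occupancy", o)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def distribution(self, t: int) -> CohortDistribution:
        return CohortDistribution(self.occupancy[t], self.cohort_size)


def step_cohort(dist: CohortDistribution, matrix: TransitionMatrix) -> CohortDistribution:
    """Advance a cohort distribution by one annual cycle.

    The new share of each destination state is the matrix-weighted sum of
    origin shares; total mass is conserved.
    """
    new = dist.shares @ matrix.probs
    return CohortDistribution(new, dist.cohort_size)


def simulate_trajectory(
    start: CohortDistribution,
    matrices: Sequence[TransitionMatrix],
    horizon: int | None = None,
) -> Trajectory:
    """Propagate a cohort through one transition matrix per cycle.

    ``matrices`` supplies a (possibly different) matrix for each cycle; this
    is how a first-year-only intervention effect or yearly boosters enter the
    model.  ``horizon`` defaults to ``len(matrices)`` and must match it.
    """
    if horizon is None:
        horizon = len(matrices)
    if horizon < 1:
        raise ValidationError("horizon must be at least 1 cycle")
    if len(matrices) != horizon:
        raise ValidationError(
            f"need one matrix per cycle: horizon {horizon}, got {len(matrices)} matrices"
        )
    occ = np.empty((horizon + 1, N_STATES))
    occ[0] = start.shares
    dist = start
    for t in range(1, horizon + 1):
        dist = step_cohort(dist, matrices[t - 1])
        occ[t] = dist.shares
    return Trajectory(occ, start.cohort_size)


def accumulate_outcomes(
    traj: Trajectory,
    payoffs: PayoffTable,
    discount: DiscountSpec,
    extra_costs: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Discounted QALYs and societal costs accumulated over a trajectory.

    QALYs for cycle ``t`` are the utility-weighted end-of-cycle occupancy
    discounted by ``(1+r)**(-t)``; state costs are valued the same way.
    ``extra_costs[t-1]`` is an additional cost attached to cycle ``t``
    (intervention delivery, booster sessions), charged at the start of the
    cycle and therefore discounted by ``(1+r)**(-(t-1))`` — the cycle-1
    upfront cost is undiscounted.

    Returns ``(qalys, costs)`` for one person (scale by cohort size outside
    if needed).
    """
    H = traj.horizon
    if extra_costs is None:
        extra_costs = [0.0] * H
    if len(extra_costs) != H:
        raise ValidationError(
            f"extra_costs must have one entry per cycle ({H}), got {len(extra_costs)}"
        )
    if any(c < 0 for c in extra_costs):
        raise ValidationError("extra costs must be non-negative")
    qalys = 0.0
    costs = 0.0
    for t in range(1, H + 1):
        occ = traj.occupancy[t]
        qalys += discount.factor(t) * float(occ @ payoffs.utilities)
        costs += discount.factor(t) * float(occ @ payoffs.annual_costs)
        costs += discount.factor(t - 1) * float(extra_costs[t - 1])
    return qalys, costs


def occupancy_report(traj: Trajectory, cohort_size: float = 100.0) -> pd.DataFrame:
    """Integer person-count table: one row per year, one column per state.

    Counts are ``round_half_up(share * cohort_size)``; rounding is for
    display only and never feeds back into the propagation.
    """
    if cohort_size <= 0:
        raise ValidationError("cohort size must be positive")
    counts = [
        [round_half_up(share * cohort_size) for share in row] for row in traj.occupancy
    ]
    df = pd.DataFrame(counts, columns=STATE_LABELS)
    df.insert(0, "year", range(traj.horizon + 1))
    return df
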