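"""Synthetic trial arms and random model parameters.

Emulates the statistical structure of a one-year prevention trial among
older people in the mild-dependency "risk zone": every participant starts
mild, and one year later falls into one of the five dependency states.  Arm
counts are therefore a single multinomial draw from a true transition row.
The module also samples random valid transition matrices for property
testing of the cohort machinery.

All randomness flows through one :class:`numpy.random.Generator` keyed by a
single seed, so every synthetic dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effects import TrialArmCounts
from .model_core import (
    DISALLOWED_TRANSITIONS,
    DependencyState,
    N_STATES,
    TransitionMatrix,
    ValidationError,
    validate_matrix,
)

__all__ = [
    "ArmGenerator",
    "generate_arm",
    "generate_random_matrix",
    "scaled_row",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ArmGenerator:
    """Specification of a synthetic trial arm: a true one-year destination
    distribution for a mild-dependency cohort, the arm size, and a seed."""

    true_row: np.ndarray
    n: int
    seed: int
    arm_label: str = "synthetic"

    def __post_init__(self) -> None:
        row = np.asarray(self.true_row, dtype=float)
        if row.shape != (N_STATES,):
            raise ValidationError(f"true_row must have {N_STATES} entries")
        if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
            raise ValidationError("true_row must be a probability vector summing to 1")
        if self.n <= 0:
            raise ValidationError("arm size must be positive")
        object.__setattr__(self, "true_row", row)


def generate_arm(gen: ArmGenerator) -> TrialArmCounts:
    """Draw one multinomial realisation of an arm's destination counts."""
    counts = _rng(gen.seed).multinomial(gen.n, gen.true_row)
    return TrialArmCounts(gen.arm_label, gen.n, counts)


def scaled_row(base_row: Sequence[float], rr: float) -> np.ndarray:
    """True destination row for an arm with pooled progression RR ``rr``.

    Every non-mild destination probability of ``base_row`` is multiplied by
    ``rr`` and the saved mass stays mild — the generating process whose
    pooled progression relative risk versus ``base_row`` is exactly ``rr``.
    """
    row = np.asarray(base_row, dtype=float).copy()
    if rr < 0:
        raise ValidationError("relative risk must be non-negative")
    row[1:] *= rr
    row[0] = 1.0 - row[1:].sum()
    if row[0] < 0:
        raise ValidationError("rr too large: mild probability would be negative")
    return row


def generate_random_matrix(seed: int | np.random.Generator) -> TransitionMatrix:
    """Sample a random valid transition matrix.

    Non-absorbing rows are drawn from a flat Dirichlet on the simplex, the
    death row is forced absorbing and structural zeros (no recovery from
    total dependency to mild) are honoured; the result always passes
    :func:`~eldercea.model_core.validate_matrix`.
    """
    rng = _rng(seed)
    probs = np.zeros((N_STATES, N_STATES))
    blocked = {int(src): int(dst) for src, dst in DISALLOWED_TRANSITIONS}
    for i in range(N_STATES - 1):
        if i in blocked:
            allowed = [j for j in range(N_STATES) if j != blocked[i]]
            probs[i, allowed] = rng.dirichlet(np.ones(len(allowed)))
        else:
            probs[i] = rng.dirichlet(np.ones(N_STATES))
        probs[i] /= probs[i].sum()  # guard rounding drift
    probs[int(DependencyState.DEAD), int(DependencyState.DEAD)] = 1.0
    return validate_matrix(TransitionMatrix(probs))
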