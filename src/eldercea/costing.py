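"""Intervention cost sheets: itemised totals and per-participant costs.

Cost sheets hold pre-computed item amounts in euros (education of
interveners, salaries including planning time, travel, rented rooms,
materials).  The sheet total is the exact sum of items; dividing by the
number of trial participants gives the per-participant cost charged to an
intervention scenario.  Booster sessions (a yearly repeat for people still
in mild dependency) have their own per-participant unit cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .model_core import ValidationError, round_half_up

__all__ = ["InterventionCostSheet", "total_cost", "per_participant_cost"]


@dataclass(frozen=True)
class InterventionCostSheet:
    """Itemised cost sheet for one intervention format."""

    label: str
    items: tuple[tuple[str, float], ...]
    participants: int
    booster_unit_cost: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple((str(k), float(v)) for k, v in self.items))
        for name, amount in self.items:
            if amount < 0:
                raise ValidationError(f"negative cost item {name!r}: {amount}")
        if self.participants <= 0:
            raise ValidationError("participants must be positive")
        if self.booster_unit_cost < 0:
            raise ValidationError("booster unit cost must be non-negative")


def total_cost(sheet: InterventionCostSheet) -> float:
    """Exact sum of the sheet's item amounts in euros.

    Uses compensated summation so the total is independent of item order.
    """
    return math.fsum(amount for _, amount in sheet.items)


def per_participant_cost(
    sheet: InterventionCostSheet, rounding: str = "nearest_int"
) -> float:
    """Total cost divided by the number of participants.

    ``rounding="nearest_int"`` rounds half-up to whole euros (the form in
    which per-participant costs are quoted and fed to scenarios);
    ``rounding="none"`` returns the unrounded quotient.
    """
    raw = total_cost(sheet) / sheet.participants
    if rounding == "nearest_int":
        return float(round_half_up(raw))
    if rounding == "none":
        return raw
    raise ValidationError(f"unknown rounding mode {rounding!r}")
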