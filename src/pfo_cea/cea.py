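"""Incremental cost-effectiveness: ICER, net monetary benefit, dominance.

Deltas are intervention minus comparator.  Dollar figures are truncated
toward zero to whole dollars.  A negative ICER is reported, but only ever
alongside the dominance flag, because negative ratios are not rankable on
their own (a large negative ICER can mean either large savings or tiny
QALY gains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .engine import StrategyResult


class Dominance(str, Enum):
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # costlier and less effective
    TRADEOFF_COST_EFFECTIVE = "tradeoff_cost_effective"
    TRADEOFF_NOT_COST_EFFECTIVE = "tradeoff_not_cost_effective"


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float
    delta_qaly: float
    icer: int | None  # USD/QALY truncated toward zero; None when undefined
    icer_defined: bool
    nmb: int  # USD at `wtp`, truncated toward zero
    dominance: Dominance
    wtp: float

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "icer_defined": self.icer_defined,
            "nmb": self.nmb,
            "dominance": self.dominance.value,
            "wtp": self.wtp,
        }


def icer(delta_cost: float, delta_qaly: float) -> int | None:
    """Incremental cost per QALY, truncated toward zero; None if dQALY=0."""
    if delta_qaly == 0:
        return None
    return math.trunc(delta_cost / delta_qaly)


def nmb(wtp: float, delta_qaly: float, delta_cost: float) -> int:
    """Net monetary benefit wtp*dQALY - dCost, truncated toward zero."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return math.trunc(wtp * delta_qaly - delta_cost)


def classify(delta_cost: float, delta_qaly: float, wtp: float) -> Dominance:
    """Exhaustive, exclusive partition of the cost-effectiveness plane."""
    if delta_cost < 0 and delta_qaly > 0:
        return Dominance.DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return Dominance.DOMINATED
    if wtp * delta_qaly - delta_cost >= 0:
        return Dominance.TRADEOFF_COST_EFFECTIVE
    return Dominance.TRADEOFF_NOT_COST_EFFECTIVE


def evaluate(delta_cost: float, delta_qaly: float, wtp: float) -> CEAResult:
    ratio = icer(delta_cost, delta_qaly)
    return CEAResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=ratio,
        icer_defined=ratio is not None,
        nmb=nmb(wtp, delta_qaly, delta_cost),
        dominance=classify(delta_cost, delta_qaly, wtp),
        wtp=wtp,
    )


def compare_strategies(
    intervention: StrategyResult, comparator: StrategyResult, wtp: float
) -> CEAResult:
    """Compare two arms run under identical settings."""
    if (intervention.settings_key and comparator.settings_key
            and intervention.settings_key != comparator.settings_key):
        raise ValueError(
            "cannot compare strategies run under different settings: "
            f"{intervention.settings_key} vs {comparator.settings_key}"
        )
    return evaluate(
        intervention.total_cost - comparator.total_cost,
        intervention.total_qaly - comparator.total_qaly,
        wtp,
    )
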