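"""Incremental cost-effectiveness metrics.

Combines per-arm lifetime totals into incremental cost, incremental
effect, the ICER, net monetary benefit, and the dominance / WHO
willingness-to-pay classifications used to interpret them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CEResult", "icer", "dominance", "nmb", "who_class"]


@dataclass(frozen=True)
class CEResult:
    """Two-arm cost-effectiveness comparison (A vs comparator B)."""

    cost_A: float
    cost_B: float
    qaly_A: float
    qaly_B: float

    @property
    def d_cost(self) -> float:
        return self.cost_A - self.cost_B

    @property
    def d_qaly(self) -> float:
        return self.qaly_A - self.qaly_B

    @property
    def icer(self) -> float:
        return icer(self.d_cost, self.d_qaly)

    @property
    def dominance(self) -> str:
        return dominance(self.d_cost, self.d_qaly)

    def nmb(self, wtp: float) -> float:
        return nmb(self.d_cost, self.d_qaly, wtp)

    def summary(self) -> dict:
        v = self.icer
        return {
            "cost_A": round(self.cost_A, 2),
            "cost_B": round(self.cost_B, 2),
            "qaly_A": round(self.qaly_A, 4),
            "qaly_B": round(self.qaly_B, 4),
            "d_cost": round(self.d_cost, 2),
            "d_qaly": round(self.d_qaly, 4),
            "icer": round(v, 2) if math.isfinite(v) else None,
            "dominance": self.dominance,
        }


def dominance(d_cost: float, d_qaly: float) -> str:
    """Quadrant classification of an incremental (cost, effect) pair.

    ``A_dominant``: cheaper and at least as effective (or equally cheap and
    more effective); ``B_dominant`` the mirror image; ``tradeoff_NE`` more
    costly and more effective; ``tradeoff_SW`` cheaper and less effective;
    ``tie`` when both increments vanish.
    """
    if d_cost == 0 and d_qaly == 0:
        return "tie"
    if d_cost <= 0 and d_qaly >= 0:
        return "A_dominant"
    if d_cost >= 0 and d_qaly <= 0:
        return "B_dominant"
    return "tradeoff_NE" if d_qaly > 0 else "tradeoff_SW"


def icer(d_cost: float, d_qaly: float) -> float:
    """Incremental cost-effectiveness ratio, CNY per QALY gained.

    Defined only on the trade-off quadrants; on the dominance quadrants a
    ratio is meaningless and NaN is returned (report the dominance class
    instead).  A zero effect difference also yields NaN.
    """
    if d_qaly == 0:
        return math.nan
    if (d_cost < 0) == (d_qaly < 0):  # trade-off quadrants share the sign
        return d_cost / d_qaly
    return math.nan


def nmb(d_cost: float, d_qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * d_qaly - d_cost


def who_class(icer_value: float, gdp: float) -> str:
    """WHO value-for-money band of an ICER against per-capita GDP.

    Below 1x GDP per QALY the added cost is considered completely
    worthwhile, between 1x and 3x acceptable, above 3x not worthwhile.
    Boundaries fall in the inclusive middle band.
    """
    if gdp <= 0:
        raise ValueError("gdp must be > 0")
    if icer_value < gdp:
        return "highly_cost_effective"
    if icer_value <= 3 * gdp:
        return "acceptable"
    return "not_worthwhile"
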