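"""Decision-analytic outputs: incremental cost-effectiveness and net benefit.

The comparison of interest is intervention (arm 1) versus comparator
(arm 0): incremental cost dC = C1 - C0, incremental effect dE = E1 - E0,
and their ratio ICER = dC / dE in IRR per QALY gained. When the
intervention is cheaper and more effective it *dominates* (no ratio is
reported); more costly and less effective, it is *dominated*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost, effect and their ratio for arm 1 vs arm 0."""

    delta_cost: float
    delta_effect: float
    icer: Optional[float]     # IRR per QALY; None when dE == 0 or dominance applies
    label: Optional[str]      # "dominant", "dominated", or "undefined" (dE=0, dC!=0)

    def to_json_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "label": self.label,
        }


def incremental(c1: float, c0: float, e1: float, e0: float) -> IncrementalResult:
    """Incremental comparison of (c1, e1) against (c0, e0).

    The ICER is defined only for a trade-off (one arm costlier, the other
    more effective); dominance and zero-effect cases carry a label instead.
    """
    for v in (c1, c0, e1, e0):
        if not math.isfinite(v):
            raise ValueError("incremental: inputs must be finite")
    dc = c1 - c0
    de = e1 - e0
    if de == 0.0:
        return IncrementalResult(dc, de, None, None if dc == 0.0 else "undefined")
    if dc < 0.0 and de > 0.0:
        return IncrementalResult(dc, de, None, "dominant")
    if dc > 0.0 and de < 0.0:
        return IncrementalResult(dc, de, None, "dominated")
    return IncrementalResult(dc, de, dc / de, None)


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * effect - cost`` at willingness-to-pay
    ``wtp`` (IRR per QALY). The strategy with the higher NMB is
    cost-effective at that threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * effect - cost


def cost_effectiveness_label(
    result: IncrementalResult, gdp_per_capita: float
) -> str:
    """Classify against the 2x and 3x GDP/capita willingness-to-pay
    thresholds, the convention used for reporting the scenario battery."""
    if result.label == "dominant":
        return "dominant"
    if result.label == "dominated":
        return "dominated"
    if result.icer is None:
        return "undefined"
    if result.delta_effect > 0:
        if result.icer <= 2 * gdp_per_capita:
            return "cost-effective at 2 GDP/capita"
        if result.icer <= 3 * gdp_per_capita:
            return "cost-effective at 3 GDP/capita"
        return "not cost-effective"
    # less effective and cheaper: cost-effective only if savings per QALY
    # forgone exceed the threshold
    if result.icer >= 3 * gdp_per_capita:
        return "cost-effective at 3 GDP/capita (south-west)"
    return "not cost-effective"
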