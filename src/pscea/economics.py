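"""Incremental cost-effectiveness comparison and willingness-to-pay rules.

The decision quantity is the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY between intervention and comparator, judged against a
willingness-to-pay (WTP) band built from multiples (here 1× and 3×) of
per-capita GDP, following the usual WHO-style convention.  Net monetary
benefit NMB(λ) = λ·QALY − Cost underlies the acceptability curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["CEComparison", "WTPBand", "compare", "wtp_thresholds", "nmb", "interpret"]

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADE_OFF = "trade-off"


@dataclass(frozen=True)
class CEComparison:
    """Incremental cost, incremental QALYs, and the resulting ICER.

    ``icer`` is defined only for trade-off comparisons; dominance makes a
    ratio meaningless.  ΔQALY = 0 with ΔCost ≠ 0 yields a signed-infinite
    ICER marker.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str


@dataclass(frozen=True)
class WTPBand:
    gdp_per_capita: float
    multipliers: tuple
    thresholds: tuple

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


def _cost_qaly(result) -> tuple:
    if hasattr(result, "total_cost"):
        return float(result.total_cost), float(result.total_qaly)
    cost, qaly = result
    return float(cost), float(qaly)


def compare(intervention, comparator) -> CEComparison:
    """Incremental comparison of two arm results (ArmResult or (cost, qaly)).

    Dominant: cheaper and more effective.  Dominated: costlier and less
    effective.  Otherwise a trade-off with ICER = ΔC/ΔE.
    """
    ci, qi = _cost_qaly(intervention)
    cc, qc = _cost_qaly(comparator)
    if not all(map(math.isfinite, (ci, qi, cc, qc))):
        raise ValueError("arm results must be finite")
    dc, dq = ci - cc, qi - qc
    if dc < 0 and dq > 0:
        return CEComparison(dc, dq, None, DOMINANT)
    if dc > 0 and dq < 0:
        return CEComparison(dc, dq, None, DOMINATED)
    if dq == 0:
        icer = 0.0 if dc == 0 else math.copysign(math.inf, dc)
    else:
        icer = dc / dq
    return CEComparison(dc, dq, icer, TRADE_OFF)


def wtp_thresholds(gdp_per_capita: float, multipliers: Sequence[float] = (1.0, 3.0)) -> WTPBand:
    """WTP thresholds as exact (unrounded) GDP multiples."""
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    mults = tuple(float(m) for m in multipliers)
    if any(m <= 0 for m in mults):
        raise ValueError("multipliers must be positive")
    return WTPBand(
        gdp_per_capita=float(gdp_per_capita),
        multipliers=mults,
        thresholds=tuple(gdp_per_capita * m for m in mults),
    )


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit λ·QALY − Cost at willingness-to-pay λ."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


def interpret(comparison: CEComparison, band: WTPBand) -> str:
    """Classify a comparison against the WTP band.

    Trade-off ICERs at or below the lowest threshold are "cost-effective",
    between the lowest and highest "acceptable", above the highest "not
    cost-effective" (an ICER exactly at a boundary falls in the more
    favorable category).  Dominance statuses map through directly.
    """
    if comparison.status == DOMINANT:
        return DOMINANT
    if comparison.status == DOMINATED:
        return DOMINATED
    icer = comparison.icer
    if icer is None:
        raise ValueError("trade-off comparison without an ICER")
    if comparison.delta_qaly < 0:
        # cheaper-and-less-effective trade-off: savings per QALY forgone;
        # acceptable when the ICER exceeds the top threshold
        return "cost-effective" if icer >= band.thresholds[-1] else "not cost-effective"
    if icer <= band.thresholds[0]:
        return "cost-effective"
    if icer <= band.thresholds[-1]:
        return "acceptable"
    return "not cost-effective"
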