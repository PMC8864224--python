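"""Incremental cost-effectiveness computation and the decision rule.

The incremental cost-effectiveness ratio (ICER) is the extra cost per extra
unit of effect of the intervention over the comparator, ICER = dC / dE.  When
the incremental effect is non-positive the ratio is not a meaningful summary
and the comparison is reported as a dominance classification instead; net
monetary benefit NMB = dE * WTP - dC is always defined and is the quantity
the decision rule uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

__all__ = ["ArmTotals", "CEResult", "icer", "decide"]

_TOL = 1e-12


@dataclass(frozen=True)
class ArmTotals:
    """Discounted totals for one strategy."""

    name: str
    cost: float
    ly: float
    qaly: float


@dataclass(frozen=True)
class CEResult:
    """Pairwise cost-effectiveness comparison (intervention vs comparator)."""

    intervention: ArmTotals
    comparator: ArmTotals
    wtp_per_qaly: float
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    nmb_at_wtp: float
    dominance: str  # "none", "dominant", "dominated", "undefined"

    def to_dict(self) -> dict:
        return {
            "arms": {
                a.name: {"cost": a.cost, "ly": a.ly, "qaly": a.qaly}
                for a in (self.comparator, self.intervention)
            },
            "incremental": {
                "cost": self.incremental_cost,
                "ly": self.incremental_ly,
                "qaly": self.incremental_qaly,
            },
            "icer": {"per_ly": self.icer_per_ly, "per_qaly": self.icer_per_qaly},
            "nmb_at_wtp": self.nmb_at_wtp,
            "wtp_per_qaly": self.wtp_per_qaly,
            "dominance": self.dominance,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def icer(
    intervention: ArmTotals,
    comparator: ArmTotals,
    wtp_per_qaly: float,
) -> CEResult:
    """Compare two strategies; ICERs only where the incremental effect is > 0.

    Dominance labels: "dominant" when the intervention is cheaper and more
    effective, "dominated" when dearer and less effective, "undefined" when
    the incremental QALYs are (numerically) zero, else "none".
    """
    for totals in (intervention, comparator):
        if not all(map(math.isfinite, (totals.cost, totals.ly, totals.qaly))):
            raise ValueError(f"non-finite totals for arm {totals.name!r}")
    d_cost = intervention.cost - comparator.cost
    d_ly = intervention.ly - comparator.ly
    d_qaly = intervention.qaly - comparator.qaly
    nmb = d_qaly * wtp_per_qaly - d_cost

    if abs(d_qaly) <= _TOL:
        dominance = "undefined"
    elif d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "dominated"
    else:
        dominance = "none"

    icer_q = d_cost / d_qaly if d_qaly > _TOL else None
    icer_l = d_cost / d_ly if d_ly > _TOL else None
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        wtp_per_qaly=wtp_per_qaly,
        incremental_cost=d_cost,
        incremental_ly=d_ly,
        incremental_qaly=d_qaly,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_l,
        nmb_at_wtp=nmb,
        dominance=dominance,
    )


def decide(result: CEResult, wtp: Optional[float] = None) -> bool:
    """Is the intervention cost-effective at ``wtp`` (default: result's WTP)?

    True iff the net monetary benefit at ``wtp`` is strictly positive; with a
    positive incremental effect this is exactly "ICER strictly below WTP", so
    an ICER equal to the threshold is *not* cost-effective.
    """
    if wtp is None:
        wtp = result.wtp_per_qaly
    return result.incremental_qaly * wtp - result.incremental_cost > 0.0
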