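"""Two-strategy cost-effectiveness comparison.

Incremental quantities are intervention minus comparator.  Alongside the
ICER (per QALY and per LY) the comparison reports the incremental net health
benefit ``INHB = dQALY - dCost / WTP`` (in QALYs) and the incremental net
monetary benefit ``NMB = WTP * dQALY - dCost``; the two always share a sign
and satisfy ``INHB * WTP = NMB`` exactly.  When the QALY difference is
numerically zero the ICER is undefined and a dominance label is reported
instead of a ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .markov import ArmTotals

#: |dQALY| below which the ICER is treated as undefined
QALY_TIE_EPS = 1e-9


@dataclass(frozen=True)
class CEAComparison:
    """Totals for two strategies plus every incremental summary measure."""

    intervention: str
    comparator: str
    cost_intervention: float
    cost_comparator: float
    ly_intervention: float
    ly_comparator: float
    qaly_intervention: float
    qaly_comparator: float
    wtp: float
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float  # nan when undefined
    icer_per_ly: float
    inhb_qaly: float
    nmb_delta: float
    dominance: str  # "trade-off", "dominant", "dominated", "equivalent"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        """One row per strategy, mirroring a base-case results table."""
        rows = [
            {"treatment": self.comparator, "total_cost": round(self.cost_comparator),
             "ly": round(self.ly_comparator, 2), "qaly": round(self.qaly_comparator, 2),
             "icer_per_ly": "Reference", "icer_per_qaly": "Reference",
             "inhb_qaly": "Reference"},
            {"treatment": self.intervention, "total_cost": round(self.cost_intervention),
             "ly": round(self.ly_intervention, 2), "qaly": round(self.qaly_intervention, 2),
             "icer_per_ly": round(self.icer_per_ly) if math.isfinite(self.icer_per_ly) else self.dominance,
             "icer_per_qaly": round(self.icer_per_qaly) if math.isfinite(self.icer_per_qaly) else self.dominance,
             "inhb_qaly": round(self.inhb_qaly, 2)},
        ]
        return pd.DataFrame(rows)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if abs(den) > QALY_TIE_EPS else math.nan


def compare(intervention: ArmTotals, comparator: ArmTotals, wtp: float,
            intervention_name: str = "intervention",
            comparator_name: str = "comparator") -> CEAComparison:
    """Build the full incremental comparison of two strategies at a WTP."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    d_cost = intervention.cost - comparator.cost
    d_ly = intervention.ly - comparator.ly
    d_qaly = intervention.qaly - comparator.qaly

    if abs(d_qaly) <= QALY_TIE_EPS and abs(d_cost) <= 1e-9:
        dominance = "equivalent"
    elif d_qaly >= -QALY_TIE_EPS and d_cost <= 0 and (d_qaly > QALY_TIE_EPS or d_cost < 0):
        dominance = "dominant"
    elif d_qaly <= QALY_TIE_EPS and d_cost >= 0 and (d_qaly < -QALY_TIE_EPS or d_cost > 0):
        dominance = "dominated"
    else:
        dominance = "trade-off"

    return CEAComparison(
        intervention=intervention_name,
        comparator=comparator_name,
        cost_intervention=float(intervention.cost),
        cost_comparator=float(comparator.cost),
        ly_intervention=float(intervention.ly),
        ly_comparator=float(comparator.ly),
        qaly_intervention=float(intervention.qaly),
        qaly_comparator=float(comparator.qaly),
        wtp=float(wtp),
        delta_cost=float(d_cost),
        delta_ly=float(d_ly),
        delta_qaly=float(d_qaly),
        icer_per_qaly=_safe_ratio(d_cost, d_qaly),
        icer_per_ly=_safe_ratio(d_cost, d_ly),
        inhb_qaly=float(d_qaly - d_cost / wtp),
        nmb_delta=float(wtp * d_qaly - d_cost),
        dominance=dominance,
    )


def is_cost_effective(comparison: CEAComparison, wtp: float | None = None) -> bool:
    """True iff the intervention's incremental NMB is strictly positive.

    At ``wtp`` exactly equal to the ICER the NMB is zero and the answer is
    False (strict inequality, documented boundary).  Passing a different
    ``wtp`` re-evaluates the decision at that threshold.
    """
    if wtp is None:
        return comparison.nmb_delta > 0
    return wtp * comparison.delta_qaly - comparison.delta_cost > 0
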