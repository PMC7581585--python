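"""Incremental cost-effectiveness comparison of the two treatment arms.

Increments are person-centred care minus usual care, reported per
``settings.cohort_scale`` patients (1000 by default).  Three costing
perspectives are carried throughout: direct healthcare costs only, direct
plus sick-leave indirect costs, and the societal perspective that adds
mortality-related productivity losses.  Decision rules (threshold search,
CEAC) are evaluated on net monetary benefit rather than raw ICERs, which is
quadrant-safe when the intervention dominates (negative ICER).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .engine import CostBreakdown, accumulate_outcomes, run_cohort
from .parameters import ModelParameters

__all__ = ["PERSPECTIVES", "ICERValue", "CEResult", "icer", "nmb", "compare_arms"]

PERSPECTIVES = ("direct_only", "direct_plus_sick_leave", "societal")


@dataclass(frozen=True)
class ICERValue:
    """An ICER together with its cost-effectiveness-plane quadrant.

    ``value`` is delta-cost / delta-effect (None when the effect increment
    is zero).  ``label`` is one of ``dominant`` (more effect, less cost),
    ``dominated`` (less effect, more cost), ``trade-off NE``, ``trade-off
    SW`` or ``undefined``.
    """

    value: Optional[float]
    label: str

    def __str__(self) -> str:
        if self.value is None:
            return self.label
        return f"{self.value:,.0f} ({self.label})"


def icer(delta_cost: float, delta_effect: float) -> ICERValue:
    """ICER with dominance semantics; never divides by a zero effect."""
    if delta_effect == 0:
        return ICERValue(None, "undefined")
    value = delta_cost / delta_effect
    if delta_effect > 0:
        label = "dominant" if delta_cost <= 0 else "trade-off NE"
    else:
        label = "dominated" if delta_cost >= 0 else "trade-off SW"
    return ICERValue(value, label)


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Net monetary benefit wtp * delta_effect - delta_cost (SEK)."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_effect - delta_cost


@dataclass(frozen=True)
class CEResult:
    """Incremental outcomes of PCC versus usual care.

    All increments are scaled to ``cohort_scale`` patients.  Per-arm
    absolute (per-patient) outcomes are retained for inspection.
    """

    delta_qalys: float
    delta_life_years: float
    delta_costs: CostBreakdown
    cohort_scale: float
    wtp_threshold: float
    qalys_usual_care: float
    qalys_pcc: float
    life_years_usual_care: float
    life_years_pcc: float
    costs_usual_care: CostBreakdown
    costs_pcc: CostBreakdown

    def delta_cost_for(self, perspective: str) -> float:
        d = self.delta_costs
        if perspective == "direct_only":
            return d.direct
        if perspective == "direct_plus_sick_leave":
            return d.direct + d.sick_leave
        if perspective == "societal":
            return d.total
        raise ValueError(f"unknown perspective {perspective!r}")

    @property
    def icer_by_perspective(self) -> dict[str, ICERValue]:
        return {
            p: icer(self.delta_cost_for(p), self.delta_qalys) for p in PERSPECTIVES
        }

    def nmb_at(self, wtp: float, perspective: str = "societal") -> float:
        return nmb(self.delta_cost_for(perspective), self.delta_qalys, wtp)

    @property
    def nmb_at_wtp(self) -> float:
        """NMB at the configured willingness-to-pay, societal perspective."""
        return self.nmb_at(self.wtp_threshold)


def compare_arms(params: ModelParameters) -> CEResult:
    """Run both arms under identical settings and form the increments."""
    s = params.settings
    out = {}
    for name, arm in (("usual_care", params.usual_care), ("pcc", params.pcc)):
        trace = run_cohort(arm, s)
        out[name] = accumulate_outcomes(trace, arm, s)
    (q_uc, ly_uc, c_uc), (q_pc, ly_pc, c_pc) = out["usual_care"], out["pcc"]
    k = s.cohort_scale
    return CEResult(
        delta_qalys=(q_pc - q_uc) * k,
        delta_life_years=(ly_pc - ly_uc) * k,
        delta_costs=(c_pc - c_uc) * k,
        cohort_scale=k,
        wtp_threshold=s.wtp_threshold,
        qalys_usual_care=q_uc,
        qalys_pcc=q_pc,
        life_years_usual_care=ly_uc,
        life_years_pcc=ly_pc,
        costs_usual_care=c_uc,
        costs_pcc=c_pc,
    )
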