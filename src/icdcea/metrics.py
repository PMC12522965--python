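"""Cost-effectiveness metrics: ICER, ACER, net monetary benefit, dominance."""

from __future__ import annotations

from dataclasses import dataclass

from .engine import ArmResult

__all__ = ["CEAResult", "IndeterminateError", "icer", "acer", "nmb"]


class IndeterminateError(ValueError):
    """Both incremental cost and effect are zero; no comparison is possible."""


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison of an intervention against a comparator."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    icer_label: str | None  # "dominant" | "dominated" | None
    quadrant: str  # NE | NW | SE | SW
    acer_intervention: float
    acer_comparator: float
    nmb_intervention: float
    nmb_comparator: float
    wtp: float
    cost_effective: bool

    @property
    def icer_display(self) -> str:
        if self.icer_label is not None:
            return self.icer_label
        label = f"{self.icer:,.0f}"
        return f"{label} (SW)" if self.quadrant == "SW" else label


def acer(result: ArmResult) -> float:
    """Average cost-effectiveness ratio: total cost per total QALY."""
    if result.discounted_qaly <= 0.0:
        raise ZeroDivisionError("ACER undefined for non-positive QALY total")
    return result.discounted_cost / result.discounted_qaly


def nmb(result: ArmResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``: wtp*E - C."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.discounted_qaly - result.discounted_cost


def icer(
    intervention: ArmResult, comparator: ArmResult, wtp: float = 13_002.0
) -> CEAResult:
    """Incremental comparison with dominance and CE-plane classification.

    The ratio is reported only where it is meaningful: in the NE quadrant
    (costlier and more effective) and, tagged, in the SW quadrant.  A
    cheaper-and-no-worse intervention is ``dominant``; a
    costlier-and-no-better one is ``dominated``.
    """
    d_cost = intervention.discounted_cost - comparator.discounted_cost
    d_eff = intervention.discounted_qaly - comparator.discounted_qaly
    if d_cost == 0.0 and d_eff == 0.0:
        raise IndeterminateError("arms have identical cost and effect")

    ratio: float | None = None
    label: str | None = None
    if d_cost > 0.0 and d_eff > 0.0:
        quadrant = "NE"
        ratio = d_cost / d_eff
    elif d_cost <= 0.0 and d_eff >= 0.0:
        quadrant = "SE"
        label = "dominant"
    elif d_cost >= 0.0 and d_eff <= 0.0:
        quadrant = "NW"
        label = "dominated"
    else:  # cheaper and less effective
        quadrant = "SW"
        ratio = d_cost / d_eff

    nmb_i = nmb(intervention, wtp)
    nmb_c = nmb(comparator, wtp)
    return CEAResult(
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=ratio,
        icer_label=label,
        quadrant=quadrant,
        acer_intervention=acer(intervention),
        acer_comparator=acer(comparator),
        nmb_intervention=nmb_i,
        nmb_comparator=nmb_c,
        wtp=wtp,
        cost_effective=nmb_i > nmb_c,
    )
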