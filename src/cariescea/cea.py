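"""Incremental cost-effectiveness analysis between the two arms.

Outcomes per arm are expected discounted cost, QALYs and caries-lesion
counts, scaled to the cohort.  The incremental comparison reports Δcost,
ΔQALYs, prevented lesions, the ICER (Δcost / ΔQALYs) and per-person net
monetary benefit (NMB = WTP × QALYs − cost) for each arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import accrue, build_transition_matrix, initial_distribution, run_cohort, state_costs
from .params import ModelParameters

__all__ = ["ArmResult", "IncrementalResult", "CeaResult", "evaluate_arm", "incremental", "run_cea"]


@dataclass(frozen=True)
class ArmResult:
    """Cohort-scaled and per-person outcomes for one arm."""

    arm: str
    cost: float
    qalys: float
    lesions: float
    cost_pp: float
    qalys_pp: float
    lesions_pp: float


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention-minus-comparison increments and decision metrics."""

    delta_cost: float
    delta_qalys: float
    prevented_caries: float
    icer: float | None  # None when undefined (ΔQALYs == 0)
    dominance: str | None  # 'dominant', 'dominated' or None
    nmb_per_person: dict[str, float]
    wtp: float

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None


@dataclass(frozen=True)
class CeaResult:
    intervention: ArmResult
    comparison: ArmResult
    incremental: IncrementalResult

    def to_frame(self) -> pd.DataFrame:
        """Cohort-scale results table with an increments row."""
        inc = self.incremental
        rows = [
            {
                "arm": a.arm,
                "cost": a.cost,
                "qalys": a.qalys,
                "caries_lesions": a.lesions,
                "nmb_per_person": inc.nmb_per_person[a.arm],
            }
            for a in (self.comparison, self.intervention)
        ]
        rows.append(
            {
                "arm": "increment",
                "cost": inc.delta_cost,
                "qalys": inc.delta_qalys,
                "caries_lesions": -inc.prevented_caries,
                "icer": inc.icer,
            }
        )
        return pd.DataFrame(rows)


def evaluate_arm(params: ModelParameters, arm: str) -> ArmResult:
    """Run the full per-arm pipeline: matrix → trace → payoffs → accrual."""
    matrix = build_transition_matrix(params, arm)
    init = initial_distribution(params, arm)
    trace = run_cohort(matrix, init, params.settings.horizon_cycles, arm=arm)
    payoffs = state_costs(params, arm)
    acc = accrue(trace, payoffs, params.settings)
    n = params.settings.cohort_size
    return ArmResult(
        arm=arm,
        cost=acc.cost * n,
        qalys=acc.qalys * n,
        lesions=acc.caries_events * n,
        cost_pp=acc.cost,
        qalys_pp=acc.qalys,
        lesions_pp=acc.caries_events,
    )


def incremental(
    intervention: ArmResult, comparison: ArmResult, wtp: float
) -> IncrementalResult:
    """Incremental comparison (intervention − comparison) at a WTP threshold."""
    d_cost = intervention.cost - comparison.cost
    d_qalys = intervention.qalys - comparison.qalys
    prevented = comparison.lesions - intervention.lesions
    if d_qalys == 0.0:
        icer = None
        dominance = "dominant" if d_cost < 0 else None
    else:
        icer = d_cost / d_qalys
        if d_qalys > 0 and d_cost < 0:
            dominance = "dominant"
        elif d_qalys < 0 and d_cost > 0:
            dominance = "dominated"
        else:
            dominance = None
    nmb = {
        a.arm: wtp * a.qalys_pp - a.cost_pp for a in (intervention, comparison)
    }
    return IncrementalResult(
        delta_cost=d_cost,
        delta_qalys=d_qalys,
        prevented_caries=prevented,
        icer=icer,
        dominance=dominance,
        nmb_per_person=nmb,
        wtp=wtp,
    )


def run_cea(params: ModelParameters) -> CeaResult:
    """Base-case cost-utility analysis for both arms."""
    inter = evaluate_arm(params, "intervention")
    comp = evaluate_arm(params, "comparison")
    return CeaResult(
        intervention=inter,
        comparison=comp,
        incremental=incremental(inter, comp, params.settings.wtp),
    )
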