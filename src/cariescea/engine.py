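"""Markov cohort engine: transition matrices, cohort trace, payoffs, accrual.

Three health states describe a child's caries status in any model year:

* ``HEALTHY`` — no active dental caries;
* ``ACTIVE_CARIES`` — at least one new established (cavitated) lesion this
  cycle;
* ``UNTREATED`` — carious lesions present but never treated.

New caries arise annually from both the healthy and the untreated state with
the same arm-specific annual probability.  A child with active caries who
seeks and receives treatment (restoration, extraction or pulp therapy)
returns to the healthy state; otherwise they fall into the untreated state,
from which there is no route back to health except via a new active lesion
that does get treated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import (
    ModelParameters,
    ModelSettings,
    interval_to_annual_probability,
    proportion_as_rate_probability,
)

__all__ = [
    "HealthState",
    "CohortTrace",
    "CyclePayoffs",
    "Accrual",
    "annual_new_caries_probability",
    "build_transition_matrix",
    "initial_distribution",
    "run_cohort",
    "state_costs",
    "accrue",
]


class HealthState(IntEnum):
    """Model health states; the value fixes the matrix index."""

    HEALTHY = 0
    ACTIVE_CARIES = 1
    UNTREATED = 2


N_STATES = len(HealthState)


class ModelConstructionError(ValueError):
    """A derived transition probability or cost fell outside its domain."""


def annual_new_caries_probability(
    params: ModelParameters, arm: str, p_observed: float | None = None
) -> float:
    """Annual new-caries probability for an arm.

    The config stores the probability on the scale it was observed on
    (2-year follow-up); conversion to the annual cycle length follows the
    convention in ``settings.probability_conversion``.  ``p_observed``
    optionally substitutes a different observed-scale value (used by the
    sensitivity and probabilistic analyses, which perturb the measured
    quantity and re-convert).
    """
    pv = params.arms[arm]["p_new_caries"]
    p = pv.base if p_observed is None else p_observed
    interval = pv.interval_years / params.settings.cycle_length_years
    if params.settings.probability_conversion == "constant_hazard":
        return interval_to_annual_probability(p, interval)
    return proportion_as_rate_probability(p, interval)


def _treated_return_probability(
    p_seek: float, p_mix_total: float, convention: str
) -> float:
    if convention == "seek_times_mix":
        return p_seek * p_mix_total
    if convention == "seek_only":
        return p_seek
    return p_mix_total  # mix_only


def build_transition_matrix(params: ModelParameters, arm: str) -> np.ndarray:
    """Annual 3x3 transition matrix for one arm (rows = from-state)."""
    if arm not in params.arms:
        raise KeyError(f"unknown arm {arm!r}")
    s = params.settings
    p_c = annual_new_caries_probability(params, arm)
    p_seek = params.value(f"{arm}.p_seek_treatment")
    p_mix = (
        params.value("shared.p_restoration")
        + params.value("shared.p_extraction")
        + params.value("shared.p_pulp_therapy")
    )
    p_return = _treated_return_probability(p_seek, p_mix, s.treated_return_convention)
    m = np.array(
        [
            [1.0 - p_c, p_c, 0.0],
            [p_return, 0.0, 1.0 - p_return],
            [0.0, p_c, 1.0 - p_c],
        ]
    )
    if (m < -1e-12).any() or (m > 1.0 + 1e-12).any():
        raise ModelConstructionError(
            f"{arm}: transition probability outside [0, 1]:\n{m}"
        )
    return m


def initial_distribution(params: ModelParameters, arm: str) -> np.ndarray:
    """Cycle-0 occupancy: baseline caries prevalence starts in ACTIVE_CARIES."""
    p0 = params.value(f"{arm}.p_caries_baseline")
    return np.array([1.0 - p0, p0, 0.0])


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle for one arm.

    ``occupancy`` has shape (n_cycles + 1, 3); row 0 is the initial
    distribution.
    """

    arm: str
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles+1, {N_STATES})")
        if (occ < -1e-12).any():
            raise ValueError("negative occupancy")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("cycle occupancies do not sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace: (cycle, arm, state, occupancy)."""
        rows = [
            (t, self.arm, state.name, float(self.occupancy[t, state]))
            for t in range(self.occupancy.shape[0])
            for state in HealthState
        ]
        return pd.DataFrame(rows, columns=["cycle", "arm", "state", "occupancy"])


def run_cohort(matrix: np.ndarray, init: np.ndarray, n_cycles: int, arm: str = "") -> CohortTrace:
    """Propagate the cohort through ``n_cycles`` annual transitions."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STATES, N_STATES):
        raise ValueError(f"matrix must be {N_STATES}x{N_STATES}")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("matrix rows must sum to 1")
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = init
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ matrix
    return CohortTrace(arm=arm, occupancy=occ)


@dataclass(frozen=True)
class CyclePayoffs:
    """Per person-cycle cost (AUD) and utility by state for one arm."""

    arm: str
    costs: np.ndarray  # shape (3,)
    utilities: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        if (self.costs < 0).any():
            raise ModelConstructionError(f"{self.arm}: negative state cost")
        if ((self.utilities < 0) | (self.utilities > 1)).any():
            raise ModelConstructionError(f"{self.arm}: utility outside [0, 1]")


def state_costs(params: ModelParameters, arm: str) -> CyclePayoffs:
    """Assemble per-state cost and utility payoffs for one arm.

    The intervention arm pays the annual prevention bundle (examination,
    radiography, fissure sealant, varnish) for every healthy child; usual
    care incurs nothing in the healthy state.  A child with active caries
    who presents for treatment incurs clinic costs (examination,
    radiography, a share of plaque/calculus removal and of hygiene/dietary
    advice) plus the expected treatment-mix cost; non-presenters and the
    untreated state cost nothing.
    """
    s = params.settings
    v = params.value
    if arm == "intervention":
        healthy_cost = (
            v("shared.cost_examination")
            + v("shared.cost_radiography")
            + s.fraction_sealant * v("shared.cost_fissure_sealant")
            + v("shared.cost_varnish")
        )
    else:
        healthy_cost = 0.0
    p_seek = v(f"{arm}.p_seek_treatment")
    active_cost = p_seek * (
        v("shared.cost_examination")
        + v("shared.cost_radiography")
        + s.fraction_plaque_calculus
        * (v("shared.cost_plaque_removal") + v("shared.cost_calculus_removal"))
        + s.fraction_ohi_diet
        * (v("shared.cost_oral_hygiene_instructions") + v("shared.cost_dietary_advice"))
        + v("shared.p_restoration") * v("shared.cost_restoration")
        + v("shared.p_extraction") * v("shared.cost_extraction")
        + v("shared.p_pulp_therapy") * v("shared.cost_pulp_therapy")
    )
    u_healthy = v("shared.utility_healthy")
    u_caries = v("shared.utility_caries")
    return CyclePayoffs(
        arm=arm,
        costs=np.array([healthy_cost, active_cost, 0.0]),
        utilities=np.array([u_healthy, u_caries, u_caries]),
    )


@dataclass(frozen=True)
class Accrual:
    """Discounted per-person outcomes for one arm over the horizon."""

    arm: str
    cost: float  # discounted AUD per person
    qalys: float  # discounted QALYs per person
    caries_events: float  # undiscounted active-caries person-cycles per person


def accrue(trace: CohortTrace, payoffs: CyclePayoffs, settings: ModelSettings) -> Accrual:
    """Accumulate discounted cost, QALYs and caries events per person.

    Under the default ``cycle_end`` timing, cycle t (t = 1..H) rewards the
    post-transition occupancy with discount factor (1 + r)^-(t-1): the first
    cycle is undiscounted.  ``cycle_start`` rewards the pre-transition
    occupancy (t = 0..H-1) with factor (1 + r)^-t.  Caries events are the
    undiscounted sum of ACTIVE_CARIES occupancy, optionally including the
    cycle-0 prevalent fraction.
    """
    h = trace.n_cycles
    occ = trace.occupancy
    if settings.accrual_timing == "cycle_end":
        idx = np.arange(1, h + 1)
        exponents = idx - 1
    else:
        idx = np.arange(0, h)
        exponents = idx
    disc_c = (1.0 + settings.discount_rate_costs) ** -exponents.astype(float)
    disc_q = (1.0 + settings.discount_rate_qalys) ** -exponents.astype(float)
    cost = float(disc_c @ (occ[idx] @ payoffs.costs))
    qalys = float(disc_q @ (occ[idx] @ payoffs.utilities))
    events = float(occ[idx, HealthState.ACTIVE_CARIES].sum())
    if settings.include_initial_lesions and settings.accrual_timing == "cycle_end":
        events += float(occ[0, HealthState.ACTIVE_CARIES])
    return Accrual(arm=trace.arm, cost=cost, qalys=qalys, caries_events=events)
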