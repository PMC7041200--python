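"""Deterministic sensitivity analysis: one-way DSA, tornado, scenarios,
and a two-way null/extreme validation grid.

One-way analysis substitutes a single parameter with its low or high bound
(all else at base) and re-runs the full cost-utility analysis; probabilities
stored on the observed 2-year scale are re-converted to annual after
substitution because the substitution happens on the measured quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cea import IncrementalResult, run_cea
from .params import ModelParameters

__all__ = [
    "DsaRow",
    "Scenario",
    "one_way_dsa",
    "tornado",
    "scenario_analysis",
    "two_way_validation",
]


@dataclass(frozen=True)
class DsaRow:
    """Cohort-scaled CEA outcomes with one parameter at one bound."""

    parameter: str
    direction: str  # 'low' or 'high'
    value: float
    delta_cost: float
    delta_qalys: float
    prevented_caries: float
    icer: float | None


@dataclass(frozen=True)
class Scenario:
    """Named set of parameter overrides applied before evaluation."""

    name: str
    overrides: Mapping[str, float]


def _row(params: ModelParameters, qname: str, direction: str, value: float) -> DsaRow:
    res = run_cea(params.with_overrides({qname: value}))
    inc = res.incremental
    return DsaRow(
        parameter=qname,
        direction=direction,
        value=value,
        delta_cost=inc.delta_cost,
        delta_qalys=inc.delta_qalys,
        prevented_caries=inc.prevented_caries,
        icer=inc.icer,
    )


def one_way_dsa(
    params: ModelParameters, param_names: Sequence[str] | None = None
) -> list[DsaRow]:
    """Low/high substitution for each named parameter, all else at base.

    Parameters without both bounds are skipped with a warning.  Defaults to
    the config's ``dsa.parameters`` selection, or every bounded parameter if
    the config lists none.
    """
    if param_names is None:
        param_names = list(params.dsa_parameters) or [
            q for q in params.names() if params.get(q).has_bounds
        ]
    rows: list[DsaRow] = []
    for qname in param_names:
        pv = params.get(qname)
        if not pv.has_bounds:
            warnings.warn(f"{qname} has no low/high bounds; skipped", stacklevel=2)
            continue
        rows.append(_row(params, qname, "low", pv.low))
        rows.append(_row(params, qname, "high", pv.high))
    return rows


def dsa_frame(rows: Iterable[DsaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "direction": r.direction,
                "value": r.value,
                "delta_cost": r.delta_cost,
                "delta_qalys": r.delta_qalys,
                "prevented_caries": r.prevented_caries,
                "icer": r.icer,
            }
            for r in rows
        ]
    )


def tornado(rows: Sequence[DsaRow], base_icer: float) -> pd.DataFrame:
    """Order parameters by descending |ICER range|; ties break alphabetically.

    Returns one row per parameter with the low/high ICER bar endpoints
    relative to ``base_icer``.
    """
    by_param: dict[str, dict[str, DsaRow]] = {}
    for r in rows:
        by_param.setdefault(r.parameter, {})[r.direction] = r
    records = []
    for name, pair in by_param.items():
        if set(pair) != {"low", "high"}:
            raise ValueError(f"tornado needs paired low/high rows for {name!r}")
        icer_low, icer_high = pair["low"].icer, pair["high"].icer
        if icer_low is None or icer_high is None:
            raise ValueError(f"undefined ICER in tornado input for {name!r}")
        records.append(
            {
                "parameter": name,
                "icer_low": icer_low,
                "icer_high": icer_high,
                "icer_range": abs(icer_high - icer_low),
                "base_icer": base_icer,
            }
        )
    df = pd.DataFrame(records)
    return df.sort_values(
        ["icer_range", "parameter"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def scenario_analysis(params: ModelParameters, scenario: Scenario) -> IncrementalResult:
    """Apply a scenario's overrides and run the full cost-utility analysis."""
    return run_cea(params.with_overrides(dict(scenario.overrides))).incremental


def two_way_validation(
    params: ModelParameters,
    p1: str,
    p2: str,
    grid1: Sequence[float],
    grid2: Sequence[float],
) -> pd.DataFrame:
    """Cross-grid of CEA results over two parameters (model validation).

    Returns a long-format frame with one row per (v1, v2) grid cell
    carrying Δcost, ΔQALYs and the ICER (NaN where undefined, e.g. at the
    null cell where the caries utility equals the healthy utility).
    """
    params.get(p1)
    params.get(p2)
    records = []
    for v1 in grid1:
        for v2 in grid2:
            inc = run_cea(params.with_overrides({p1: v1, p2: v2})).incremental
            records.append(
                {
                    p1: v1,
                    p2: v2,
                    "delta_cost": inc.delta_cost,
                    "delta_qalys": inc.delta_qalys,
                    "icer": float("nan") if inc.icer is None else inc.icer,
                }
            )
    return pd.DataFrame(records)
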