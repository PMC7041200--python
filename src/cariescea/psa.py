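"""Probabilistic sensitivity analysis.

Each uncertain parameter gets a distribution fitted from its (base, low,
high) triple: beta for probabilities and utilities, gamma for costs, both
moment-matched so the mean equals the base value and the standard deviation
equals (high − low) / 3.92 (bounds read as a 95% interval); triangular
(low, base, high) where only the three values are known.  Draws are joint
and independent across parameters; each draw re-runs the full cost-utility
analysis, with observed-scale probabilities re-converted to annual after
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import run_cea
from .params import ModelParameters, ParameterValue

__all__ = [
    "DistributionSpec",
    "PsaResult",
    "fit_from_bounds",
    "sample_parameter",
    "run_psa",
    "ce_plane_summary",
    "ceac",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Fitted sampling distribution for one parameter."""

    name: str
    family: str  # 'beta' | 'gamma' | 'triangular' | 'fixed'
    args: Mapping[str, float]

    def mean(self) -> float:
        a = self.args
        if self.family == "beta":
            return a["alpha"] / (a["alpha"] + a["beta"])
        if self.family == "gamma":
            return a["shape"] * a["scale"]
        if self.family == "triangular":
            return (a["left"] + a["mode"] + a["right"]) / 3.0
        return a["value"]


def fit_from_bounds(p: ParameterValue) -> DistributionSpec:
    """Fit the parameter's tagged family from its (base, low, high) triple."""
    if p.dist == "fixed" or not p.has_bounds:
        return DistributionSpec(p.name, "fixed", {"value": p.base})
    if p.high <= p.low:
        raise ValueError(f"{p.name}: high bound must exceed low bound")
    if p.dist == "triangular":
        return DistributionSpec(
            p.name, "triangular", {"left": p.low, "mode": p.base, "right": p.high}
        )
    sd = (p.high - p.low) / 3.92
    if sd == 0.0:
        return DistributionSpec(p.name, "fixed", {"value": p.base})
    var = sd * sd
    m = p.base
    if p.dist == "beta":
        if not 0.0 < m < 1.0:
            return DistributionSpec(p.name, "fixed", {"value": m})
        common = m * (1.0 - m) / var - 1.0
        if common <= 0:
            raise ValueError(f"{p.name}: variance too large for a beta fit")
        return DistributionSpec(
            p.name, "beta", {"alpha": m * common, "beta": (1.0 - m) * common}
        )
    if p.dist == "gamma":
        if m <= 0:
            return DistributionSpec(p.name, "fixed", {"value": m})
        return DistributionSpec(p.name, "gamma", {"shape": m * m / var, "scale": var / m})
    raise ValueError(f"{p.name}: no sampling rule for dist {p.dist!r}")


def sample_parameter(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int,
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Draw ``size`` values; resample any outside ``bounds``.

    Returns the draws and the number of resampled values.
    """

    def draw(n: int) -> np.ndarray:
        a = spec.args
        if spec.family == "beta":
            return rng.beta(a["alpha"], a["beta"], n)
        if spec.family == "gamma":
            return rng.gamma(a["shape"], a["scale"], n)
        if spec.family == "triangular":
            return rng.triangular(a["left"], a["mode"], a["right"], n)
        return np.full(n, a["value"])

    out = draw(size)
    n_resampled = 0
    if bounds is not None:
        lo, hi = bounds
        for _ in range(100):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                break
            n_resampled += int(bad.sum())
            out[bad] = draw(int(bad.sum()))
    return out, n_resampled


@dataclass(frozen=True)
class PsaResult:
    """Paired incremental draws with the specs and seed that produced them."""

    n_draws: int
    seed: int
    draws: pd.DataFrame  # columns: draw, delta_cost, delta_qaly
    specs: tuple[DistributionSpec, ...]
    n_resampled: int = 0


def psa_parameter_names(params: ModelParameters) -> list[str]:
    """Parameters entering the PSA: every one tagged with a distribution."""
    return [q for q in params.names() if params.get(q).dist != "fixed"]


def run_psa(
    params: ModelParameters,
    n_draws: int,
    seed: int,
    param_names: Sequence[str] | None = None,
) -> PsaResult:
    """Joint resampling of all distribution-tagged parameters.

    Each draw substitutes the sampled values (observed-scale probabilities
    included — annual conversion happens inside the engine) and reruns the
    two-arm cost-utility analysis.  Deterministic for a given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    names = list(param_names) if param_names is not None else psa_parameter_names(params)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    n_resampled = 0
    for qname in names:
        pv = params.get(qname)
        spec = fit_from_bounds(pv)
        if pv.scale in ("probability", "utility"):
            # keep strictly below 1 so rate conversion stays finite
            bounds = (0.0, math.nextafter(1.0, 0.0))
        else:
            bounds = (0.0, math.inf)
        samples[qname], bad = sample_parameter(spec, rng, n_draws, bounds)
        n_resampled += bad
    specs = tuple(fit_from_bounds(params.get(q)) for q in names)

    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    for i in range(n_draws):
        overrides = {q: float(samples[q][i]) for q in names}
        inc = run_cea(params.with_overrides(overrides)).incremental
        d_cost[i] = inc.delta_cost
        d_qaly[i] = inc.delta_qalys
    draws = pd.DataFrame(
        {"draw": np.arange(n_draws), "delta_cost": d_cost, "delta_qaly": d_qaly}
    )
    return PsaResult(
        n_draws=n_draws, seed=seed, draws=draws, specs=specs, n_resampled=n_resampled
    )


def ce_plane_summary(result: PsaResult, wtp: float) -> dict:
    """Cost-effectiveness plane summary at one WTP threshold.

    A draw is cost-effective when its incremental net monetary benefit
    wtp·ΔQALY − Δcost is positive.  Quadrants are counted anticlockwise
    from NE (ΔQALY ≥ 0, Δcost ≥ 0).
    """
    dc = result.draws["delta_cost"].to_numpy()
    dq = result.draws["delta_qaly"].to_numpy()
    inmb = wtp * dq - dc
    quadrants = {
        "NE": int(((dq >= 0) & (dc >= 0)).sum()),
        "NW": int(((dq < 0) & (dc >= 0)).sum()),
        "SW": int(((dq < 0) & (dc < 0)).sum()),
        "SE": int(((dq >= 0) & (dc < 0)).sum()),
    }
    return {
        "wtp": wtp,
        "fraction_cost_effective": float((inmb > 0).mean()),
        "mean_delta_cost": float(dc.mean()),
        "mean_delta_qaly": float(dq.mean()),
        "quadrants": quadrants,
    }


def ceac(result: PsaResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    rows = [
        {
            "wtp": w,
            "probability_cost_effective": ce_plane_summary(result, w)[
                "fraction_cost_effective"
            ],
        }
        for w in wtp_grid
    ]
    return pd.DataFrame(rows)
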