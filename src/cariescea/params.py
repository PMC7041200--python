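"""Model parameters: data model, config loading/validation, estimation formulas.

The model is driven by a single configuration describing, for each study arm
(``intervention`` — annual school-based prevention; ``comparison`` — usual
care), the baseline caries prevalence, the observed 2-year new-caries
probability, and the probability of seeking treatment, plus arm-shared
treatment-mix probabilities, fee-schedule costs (AUD, 2018) and health-state
utilities.  Two small estimation formulas used to turn raw study data into
model inputs live here as well: the constant-hazard interval-to-annual
probability conversion and the normal-approximation confidence interval for
a proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "ParameterValue",
    "ModelSettings",
    "ModelParameters",
    "ConfigError",
    "ValidationError",
    "load_parameters",
    "load_parameters_csv",
    "default_config_path",
    "load_default_parameters",
    "interval_to_annual_probability",
    "proportion_as_rate_probability",
    "proportion_ci",
    "ARMS",
]

ARMS = ("intervention", "comparison")

_DISTS = {"beta", "gamma", "triangular", "fixed"}
_SCALES = {"probability", "currency", "utility"}

_CONVERSIONS = {"proportion_as_rate", "constant_hazard"}
_RETURN_CONVENTIONS = {"seek_times_mix", "seek_only", "mix_only"}
_TIMINGS = {"cycle_end", "cycle_start"}


class ConfigError(ValueError):
    """A configuration file is missing required content or has unknown keys."""


class ValidationError(ValueError):
    """A parameter value violates one of its invariants."""


# ---------------------------------------------------------------------------
# estimation formulas


def interval_to_annual_probability(p_interval: float, interval_years: float) -> float:
    """Convert a probability observed over ``interval_years`` to an annual one.

    Assumes a constant hazard: r = -ln(1 - p) / interval, p_annual =
    1 - exp(-r), which reduces to the closed form 1 - (1 - p)^(1/interval).

    Raises
    ------
    ValueError
        If ``p_interval`` is 1 (infinite hazard) or outside [0, 1).
    """
    if not 0.0 <= p_interval < 1.0:
        raise ValueError(
            f"interval probability must lie in [0, 1), got {p_interval}"
        )
    if interval_years <= 0:
        raise ValueError(f"interval_years must be positive, got {interval_years}")
    return 1.0 - (1.0 - p_interval) ** (1.0 / interval_years)


def proportion_as_rate_probability(p_interval: float, interval_years: float) -> float:
    """Annual probability when the observed proportion is treated as a rate.

    This mirrors feeding an observed cumulative proportion straight into a
    rate-to-probability transform: r = p_interval / interval, p_annual =
    1 - exp(-r).  It understates the true constant-hazard conversion but is
    the transform decision-analysis software applies when handed a
    proportion in the rate slot; it is the shipped default because it
    reproduces the reference cohort output (see docs/methods.md).
    """
    if not 0.0 <= p_interval < 1.0:
        raise ValueError(
            f"interval probability must lie in [0, 1), got {p_interval}"
        )
    if interval_years <= 0:
        raise ValueError(f"interval_years must be positive, got {interval_years}")
    return 1.0 - math.exp(-p_interval / interval_years)


def proportion_ci(p_hat: float, n: int) -> tuple[float, float]:
    """95% Wald (normal-approximation) interval for a proportion.

    p ± 1.96 * sqrt(p (1 - p) / n), truncated to [0, 1].
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p_hat}")
    half = 1.96 * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return max(0.0, p_hat - half), min(1.0, p_hat + half)


# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class ParameterValue:
    """One model input with base value, uncertainty bounds and provenance."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    dist: str = "fixed"
    scale: str = "probability"
    source: str = ""
    interval_years: float = 1.0  # observation interval for probabilities

    def __post_init__(self) -> None:
        if self.dist not in _DISTS:
            raise ValidationError(f"{self.name}: unknown dist {self.dist!r}")
        if self.scale not in _SCALES:
            raise ValidationError(f"{self.name}: unknown scale {self.scale!r}")
        for label, v in (("base", self.base), ("low", self.low), ("high", self.high)):
            if v is None:
                continue
            if self.scale in ("probability", "utility") and not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.name}: {label}={v} outside [0, 1] for scale {self.scale}"
                )
            if self.scale == "currency" and v < 0:
                raise ValidationError(f"{self.name}: {label}={v} negative cost")
        if self.low is not None and self.base < self.low:
            raise ValidationError(
                f"{self.name}: base {self.base} below low bound {self.low}"
            )
        if self.high is not None and self.base > self.high:
            raise ValidationError(
                f"{self.name}: base {self.base} above high bound {self.high}"
            )
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValidationError(
                f"{self.name}: low {self.low} above high {self.high}"
            )

    @property
    def has_bounds(self) -> bool:
        return self.low is not None and self.high is not None


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings: horizon, discounting, cohort and conventions."""

    horizon_cycles: int = 10
    cycle_length_years: float = 1.0
    discount_rate_costs: float = 0.05
    discount_rate_qalys: float = 0.0
    cohort_size: int = 500
    wtp: float = 50_000.0
    fraction_plaque_calculus: float = 0.50
    fraction_ohi_diet: float = 0.25
    fraction_sealant: float = 1.0
    treated_return_convention: str = "seek_times_mix"
    probability_conversion: str = "proportion_as_rate"
    accrual_timing: str = "cycle_end"
    include_initial_lesions: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        for name in ("discount_rate_costs", "discount_rate_qalys"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"{name}={r} outside [0, 1)")
        for name in ("fraction_plaque_calculus", "fraction_ohi_diet", "fraction_sealant"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{name}={f} outside [0, 1]")
        if self.treated_return_convention not in _RETURN_CONVENTIONS:
            raise ValidationError(
                f"treated_return_convention {self.treated_return_convention!r} "
                f"not one of {sorted(_RETURN_CONVENTIONS)}"
            )
        if self.probability_conversion not in _CONVERSIONS:
            raise ValidationError(
                f"probability_conversion {self.probability_conversion!r} "
                f"not one of {sorted(_CONVERSIONS)}"
            )
        if self.accrual_timing not in _TIMINGS:
            raise ValidationError(
                f"accrual_timing {self.accrual_timing!r} not one of {sorted(_TIMINGS)}"
            )


_ARM_REQUIRED = ("p_caries_baseline", "p_new_caries", "p_seek_treatment")
_SHARED_REQUIRED = (
    "p_restoration",
    "p_extraction",
    "p_pulp_therapy",
    "cost_examination",
    "cost_restoration",
    "cost_extraction",
    "cost_pulp_therapy",
    "cost_fissure_sealant",
    "cost_radiography",
    "cost_varnish",
    "cost_plaque_removal",
    "cost_calculus_removal",
    "cost_oral_hygiene_instructions",
    "cost_dietary_advice",
    "utility_caries",
    "utility_healthy",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full validated input set: shared and per-arm parameters plus settings.

    Parameters are addressed by qualified name: ``shared.<name>``,
    ``intervention.<name>`` or ``comparison.<name>``.
    """

    shared: Mapping[str, ParameterValue]
    arms: Mapping[str, Mapping[str, ParameterValue]]
    settings: ModelSettings = field(default_factory=ModelSettings)
    dsa_parameters: tuple[str, ...] = ()
    scenarios: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _SHARED_REQUIRED:
            if name not in self.shared:
                raise ConfigError(f"missing required shared parameter {name!r}")
        for arm in ARMS:
            if arm not in self.arms:
                raise ConfigError(f"missing arm block {arm!r}")
            for name in _ARM_REQUIRED:
                if name not in self.arms[arm]:
                    raise ConfigError(f"missing required parameter {arm}.{name}")
        for qname in self.dsa_parameters:
            self.get(qname)  # raises on unknown names
        for sc_name, overrides in self.scenarios.items():
            for qname in overrides:
                try:
                    self.get(qname)
                except KeyError as exc:
                    raise ConfigError(
                        f"scenario {sc_name!r} overrides unknown parameter {qname!r}"
                    ) from exc

    # -- lookup ------------------------------------------------------------

    def get(self, qualified_name: str) -> ParameterValue:
        """Look up a parameter by ``block.name`` qualified name."""
        try:
            block, name = qualified_name.split(".", 1)
        except ValueError:
            raise KeyError(
                f"parameter name {qualified_name!r} is not of the form 'block.name'"
            ) from None
        if block == "shared":
            pool: Mapping[str, ParameterValue] = self.shared
        elif block in self.arms:
            pool = self.arms[block]
        else:
            raise KeyError(f"unknown parameter block {block!r}")
        if name not in pool:
            raise KeyError(f"unknown parameter {qualified_name!r}")
        return pool[name]

    def value(self, qualified_name: str) -> float:
        return self.get(qualified_name).base

    def names(self) -> list[str]:
        out = [f"shared.{n}" for n in self.shared]
        for arm in ARMS:
            out.extend(f"{arm}.{n}" for n in self.arms[arm])
        return out

    # -- functional updates -------------------------------------------------

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with the given base values replaced.

        Bounds are dropped on overridden parameters so that an override can
        move outside the original low/high range (scale invariants still
        apply).
        """
        shared = dict(self.shared)
        arms = {arm: dict(block) for arm, block in self.arms.items()}
        for qname, value in overrides.items():
            pv = self.get(qname)  # KeyError on unknown names
            new = replace(pv, base=float(value), low=None, high=None)
            block, name = qname.split(".", 1)
            if block == "shared":
                shared[name] = new
            else:
                arms[block][name] = new
        return replace(self, shared=shared, arms=arms)

    def with_settings(self, **changes) -> "ModelParameters":
        return replace(self, settings=replace(self.settings, **changes))

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def pv_dict(pv: ParameterValue) -> dict:
            d: dict = {"base": pv.base, "dist": pv.dist, "scale": pv.scale}
            if pv.low is not None:
                d["low"] = pv.low
            if pv.high is not None:
                d["high"] = pv.high
            if pv.source:
                d["source"] = pv.source
            if pv.interval_years != 1.0:
                d["interval_years"] = pv.interval_years
            return d

        out: dict = {
            "settings": {
                k: getattr(self.settings, k)
                for k in ModelSettings.__dataclass_fields__
            },
            "shared": {n: pv_dict(pv) for n, pv in self.shared.items()},
            "arms": {
                arm: {n: pv_dict(pv) for n, pv in block.items()}
                for arm, block in self.arms.items()
            },
        }
        if self.dsa_parameters:
            out["dsa"] = {"parameters": list(self.dsa_parameters)}
        if self.scenarios:
            out["scenarios"] = {k: dict(v) for k, v in self.scenarios.items()}
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# loading

_PV_KEYS = {"base", "low", "high", "dist", "scale", "source", "interval_years", "rel_bound"}


def _parse_pv(name: str, raw: Mapping, default_scale: str) -> ParameterValue:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"parameter {name!r} must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _PV_KEYS
    if unknown:
        raise ConfigError(f"parameter {name!r}: unknown keys {sorted(unknown)}")
    if "base" not in raw:
        raise ConfigError(f"parameter {name!r}: missing required key 'base'")
    base = float(raw["base"])
    low = raw.get("low")
    high = raw.get("high")
    if "rel_bound" in raw:
        # symmetric relative bounds, e.g. ±15% of base, computed at load time
        if low is not None or high is not None:
            raise ConfigError(f"parameter {name!r}: rel_bound conflicts with low/high")
        rb = float(raw["rel_bound"])
        low, high = base * (1.0 - rb), base * (1.0 + rb)
    try:
        return ParameterValue(
            name=name,
            base=base,
            low=None if low is None else float(low),
            high=None if high is None else float(high),
            dist=raw.get("dist", "fixed"),
            scale=raw.get("scale", default_scale),
            source=raw.get("source", ""),
            interval_years=float(raw.get("interval_years", 1.0)),
        )
    except ValidationError as exc:
        raise ValidationError(str(exc)) from None


def _default_scale(name: str) -> str:
    if name.startswith("cost_"):
        return "currency"
    if name.startswith("utility_"):
        return "utility"
    return "probability"


def _build_from_raw(raw: Mapping) -> ModelParameters:
    if not isinstance(raw, Mapping):
        raise ConfigError("top-level config must be a mapping")
    unknown = set(raw) - {"settings", "shared", "arms", "dsa", "scenarios"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")

    settings_raw = dict(raw.get("settings", {}))
    unknown = set(settings_raw) - set(ModelSettings.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"settings: unknown keys {sorted(unknown)}")
    settings = ModelSettings(**settings_raw)

    shared = {
        name: _parse_pv(f"shared.{name}", pv, _default_scale(name))
        for name, pv in dict(raw.get("shared", {})).items()
    }
    arms = {}
    for arm, block in dict(raw.get("arms", {})).items():
        if arm not in ARMS:
            raise ConfigError(f"unknown arm {arm!r}; expected one of {ARMS}")
        arms[arm] = {
            name: _parse_pv(f"{arm}.{name}", pv, _default_scale(name))
            for name, pv in dict(block).items()
        }

    dsa_raw = dict(raw.get("dsa", {}))
    unknown = set(dsa_raw) - {"parameters"}
    if unknown:
        raise ConfigError(f"dsa: unknown keys {sorted(unknown)}")
    dsa_parameters = tuple(dsa_raw.get("parameters", ()))

    scenarios = {
        name: {str(k): float(v) for k, v in dict(ov).items()}
        for name, ov in dict(raw.get("scenarios", {})).items()
    }
    return ModelParameters(
        shared=shared,
        arms=arms,
        settings=settings,
        dsa_parameters=dsa_parameters,
        scenarios=scenarios,
    )


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a YAML or JSON model configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())  # JSON is a YAML subset
    return _build_from_raw(raw)


def load_parameters_csv(
    path: str | Path, settings: ModelSettings | None = None
) -> ModelParameters:
    """Load parameters from a flat CSV with columns
    (name, arm, base, low, high, dist, scale).

    ``arm`` is ``shared`` or an arm label.  Settings are not representable in
    the flat form and may be passed separately.
    """
    df = pd.read_csv(path)
    required = {"name", "arm", "base"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"CSV missing required columns {sorted(missing)}")
    raw: dict = {"shared": {}, "arms": {arm: {} for arm in ARMS}}
    for _, row in df.iterrows():
        entry = {"base": row["base"]}
        for key in ("low", "high"):
            if key in df.columns and pd.notna(row.get(key)):
                entry[key] = row[key]
        for key in ("dist", "scale", "source"):
            if key in df.columns and pd.notna(row.get(key)):
                entry[key] = row[key]
        if "interval_years" in df.columns and pd.notna(row.get("interval_years")):
            entry["interval_years"] = row["interval_years"]
        block = str(row["arm"])
        if block == "shared":
            raw["shared"][str(row["name"])] = entry
        elif block in ARMS:
            raw["arms"][block][str(row["name"])] = entry
        else:
            raise ConfigError(f"unknown arm {block!r} in CSV row {row['name']!r}")
    if settings is not None:
        raw["settings"] = {
            k: getattr(settings, k) for k in ModelSettings.__dataclass_fields__
        }
    return _build_from_raw(raw)


def default_config_path() -> Path:
    """Path of the shipped base-case configuration."""
    return Path(resources.files("cariescea").joinpath("data/default_config.yaml"))


def load_default_parameters() -> ModelParameters:
    return load_parameters(default_config_path())
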