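"""Synthetic individual-level study data and input re-estimation.

The original field study followed two school cohorts (one receiving an
annual preventive intervention, one under usual care) for two years,
recording baseline caries status, new established lesions by the 2-year
visit and any treatment received.  Access to the raw records is
restricted, so this module emulates that design: independent Bernoulli
draws per child for baseline caries and 2-year incidence, a Bernoulli
treatment-seeking draw for children with caries, and a categorical
treatment draw (restoration / extraction / pulp therapy / none) among
seekers.  ``estimate_inputs`` then re-derives model inputs — per-arm
baseline prevalence and 2-year incidence with normal-approximation 95%
intervals — the same way the study turned its follow-up data into model
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ARMS, ModelParameters, proportion_ci

__all__ = [
    "TREATMENTS",
    "SyntheticTruth",
    "ArmEstimates",
    "InputEstimates",
    "simulate_cohort",
    "estimate_inputs",
    "merge_fragment",
]

TREATMENTS = ("restoration", "extraction", "pulp_therapy")

# study conditions: arm sizes, baseline established-lesion prevalence,
# observed 2-year incidence, assumed seeking probability, treatment mix
_STUDY_DEFAULTS = {
    "intervention": dict(n=196, prevalence=141 / 196, incidence=0.479, seek=0.90),
    "comparison": dict(n=212, prevalence=168 / 212, incidence=0.637, seek=0.68),
}
_STUDY_MIX = {"restoration": 0.40, "extraction": 0.06, "pulp_therapy": 0.04}


@dataclass(frozen=True)
class SyntheticTruth:
    """True per-arm generating parameters for a synthetic cohort."""

    n: dict[str, int]
    prevalence: dict[str, float]
    incidence_2y: dict[str, float]
    seek: dict[str, float]
    mix: dict[str, float] = field(default_factory=lambda: dict(_STUDY_MIX))
    seed: int = 20180101

    def __post_init__(self) -> None:
        for arm in ARMS:
            for container, label in (
                (self.prevalence, "prevalence"),
                (self.incidence_2y, "incidence_2y"),
                (self.seek, "seek"),
            ):
                p = container[arm]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{label}[{arm}]={p} outside [0, 1]")
            if self.n[arm] < 1:
                raise ValueError(f"n[{arm}] must be >= 1")
        if sum(self.mix.values()) > 1.0 + 1e-12:
            raise ValueError("treatment-mix proportions must sum to <= 1")

    @classmethod
    def study_like(cls, seed: int = 20180101) -> "SyntheticTruth":
        """Truth mirroring the study conditions (n = 196/212 etc.)."""
        d = _STUDY_DEFAULTS
        return cls(
            n={a: d[a]["n"] for a in ARMS},
            prevalence={a: d[a]["prevalence"] for a in ARMS},
            incidence_2y={a: d[a]["incidence"] for a in ARMS},
            seek={a: d[a]["seek"] for a in ARMS},
            seed=seed,
        )


def simulate_cohort(truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """Simulate one follow-up dataset.

    Returns a frame with one row per child and columns ``child_id``,
    ``arm``, ``baseline_caries``, ``new_caries_2y``, ``treatment``
    (``none`` unless the child has caries, sought care and received one of
    the three treatment types).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    frames = []
    mix_names = list(truth.mix) + ["none"]
    mix_probs = np.array(list(truth.mix.values()) + [1.0 - sum(truth.mix.values())])
    offset = 0
    for arm in ARMS:
        n = truth.n[arm]
        baseline = rng.random(n) < truth.prevalence[arm]
        new2y = rng.random(n) < truth.incidence_2y[arm]
        any_caries = baseline | new2y
        seeks = (rng.random(n) < truth.seek[arm]) & any_caries
        treat_idx = rng.choice(len(mix_names), size=n, p=mix_probs)
        treatment = np.where(
            seeks, np.array(mix_names, dtype=object)[treat_idx], "none"
        )
        frames.append(
            pd.DataFrame(
                {
                    "child_id": np.arange(offset, offset + n),
                    "arm": arm,
                    "baseline_caries": baseline.astype(int),
                    "new_caries_2y": new2y.astype(int),
                    "treatment": treatment,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ArmEstimates:
    """Estimated inputs for one arm, with 95% Wald intervals."""

    arm: str
    n: int
    prevalence: float
    prevalence_ci: tuple[float, float]
    incidence_2y: float
    incidence_2y_ci: tuple[float, float]
    treated_share: float  # P(any treatment | any caries)
    treatment_mix: dict[str, float]  # P(treatment = k | any caries)


@dataclass(frozen=True)
class InputEstimates:
    """Per-arm estimates plus a config fragment for the model."""

    arms: dict[str, ArmEstimates]

    def to_config_fragment(self) -> dict:
        """Arm-block fragment mergeable into a full model configuration.

        Covers the quantities the follow-up design identifies: baseline
        prevalence and 2-year incidence with their intervals.  Seeking
        probability and the treatment mix are not written — in the study
        those came from external sources, and the records only identify
        their product.
        """
        out: dict = {"arms": {}}
        for arm, est in self.arms.items():
            out["arms"][arm] = {
                "p_caries_baseline": {
                    "base": est.prevalence,
                    "low": est.prevalence_ci[0],
                    "high": est.prevalence_ci[1],
                    "dist": "beta",
                    "scale": "probability",
                    "source": "synthetic follow-up",
                },
                "p_new_caries": {
                    "base": est.incidence_2y,
                    "low": est.incidence_2y_ci[0],
                    "high": est.incidence_2y_ci[1],
                    "dist": "beta",
                    "scale": "probability",
                    "interval_years": 2,
                    "source": "synthetic follow-up",
                },
            }
        return out


def estimate_inputs(records: pd.DataFrame) -> InputEstimates:
    """Re-derive model inputs from follow-up records.

    The 2-year incidence denominator is all followed children (not only
    those caries-free at baseline), matching how the observed proportions
    are used on the model's observed scale.
    """
    estimates = {}
    for arm in ARMS:
        sub = records[records["arm"] == arm]
        n = len(sub)
        if n == 0:
            raise ValueError(f"no records for arm {arm!r}")
        prev = float(sub["baseline_caries"].mean())
        inc = float(sub["new_caries_2y"].mean())
        caries = sub[(sub["baseline_caries"] == 1) | (sub["new_caries_2y"] == 1)]
        if len(caries):
            treated = caries["treatment"] != "none"
            treated_share = float(treated.mean())
            mix = {
                k: float((caries["treatment"] == k).mean()) for k in TREATMENTS
            }
        else:
            treated_share = 0.0
            mix = {k: 0.0 for k in TREATMENTS}
        estimates[arm] = ArmEstimates(
            arm=arm,
            n=n,
            prevalence=prev,
            prevalence_ci=proportion_ci(prev, n),
            incidence_2y=inc,
            incidence_2y_ci=proportion_ci(inc, n),
            treated_share=treated_share,
            treatment_mix=mix,
        )
    return InputEstimates(arms=estimates)


def merge_fragment(params: ModelParameters, fragment: dict) -> ModelParameters:
    """Merge an ``estimate_inputs`` fragment into a full parameter set."""
    raw = params.to_dict()
    for arm, block in fragment.get("arms", {}).items():
        raw["arms"].setdefault(arm, {}).update(block)
    from .params import _build_from_raw  # local import avoids a cycle in docs

    return _build_from_raw(raw)
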