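# Methods

## Model structure

The model is a deterministic Markov cohort (state-transition) model with
three mutually exclusive health states — no active caries (**H**), new
active caries (**A**), untreated caries (**C**) — annual cycles, a 10-year
horizon and a closed cohort of 500 children starting at age six, from a
health-system perspective. Incipient (non-cavitated) lesions are not a
separate state: the intervention is assumed to arrest them, and they are
absorbed into the probabilities of established disease.

Structural assumptions:

* New established lesions arise once per cycle from **H** and from **C**
  with the same arm-specific annual probability *p_c*; healthy children
  cannot become "untreated" without first developing a lesion, and there is
  no route from **C** back to **H** except via a new treated lesion.
* A child in **A** returns to **H** if they seek care *and* receive one of
  the three treatment types: P(A→H) = *p_s* · (*p*<sub>rest</sub> +
  *p*<sub>ext</sub> + *p*<sub>pulp</sub>). With the base treatment mix
  (0.40 + 0.06 + 0.04 = 0.50) this makes 45% of intervention-arm and 34% of
  comparison-arm active cases treated per year, i.e. roughly half of
  established lesions go untreated annually. Alternative conventions
  (`seek_only`, `mix_only`) are selectable via
  `settings.treated_return_convention`.
* The intervention's effect enters through three inputs only: a lower
  baseline prevalence (0.71 vs 0.80), a lower 2-year new-caries probability
  (0.479 vs 0.637) and a higher seek-treatment probability (0.90 vs 0.68).
  Intervention children in **A** are assumed not to receive the prevention
  bundle in that same cycle.

## Observed-scale probabilities and cycle conversion

The new-caries probabilities were measured over a 2-year follow-up and are
stored on that scale; the engine converts them to the annual cycle at
model-build time (and after every sensitivity/PSA substitution, so that the
measured quantity is what gets perturbed). Two conversions are provided:

* `constant_hazard` — the textbook conversion
  *p*₁ = 1 − (1 − *p*₂ᵧ)^(1/2), giving annual probabilities 0.3975
  (comparison) and 0.2782 (intervention);
* `proportion_as_rate` (default) — *p*₁ = 1 − exp(−*p*₂ᵧ/2), the transform
  a rate-to-probability function applies when handed a cumulative
  proportion in the rate slot, giving 0.2727 and 0.2130.

The default was chosen by validation against the reference cohort output
rather than by first principles: with it, the model's end-of-horizon state
occupancies match the reference trace to a tenth of a percentage point
(the steady-state active share is *p*₁/(1+*p*₁), which pins *p*₁ down
uniquely), and the lesion counts and scenario ICERs follow. The
constant-hazard conversion remains available and is the statistically
correct choice for de novo analyses.

## Payoffs

Costs are 2018 fee-schedule values in AUD. Intervention **H**:
examination $53 + bitewing radiography $38 + fissure sealant $47 ×
`fraction_sealant` (default 1.0; the share of children actually needing
sealant was recorded in the field but never published) + varnish $30 = $168.
Comparison **H**: $0 (no annual examination). **A** in both arms, scaled by
the arm's *p_s*: examination + radiography + 50% × (plaque $55 + calculus
$91) + 25% × (hygiene instructions $50 + dietary advice $37) + expected
treatment cost 0.40·$145 + 0.06·$195 + 0.04·$77 = $72.78, for $258.53 per
presenting case. **C**: $0. The povidone-iodine swab has no separate fee
item and is treated as bundled with varnish application. Utilities: 1.00 in
**H**; 0.87 (CHU-9D) shared by **A** and **C**, since a single caries
utility was measured.

## Accrual, discounting and event counting

Rewards accrue on post-transition occupancy for cycles *t* = 1…10 with
discount factor (1+*r*)^−(*t*−1) (first cycle undiscounted, no half-cycle
correction); `cycle_start` timing is available as a toggle. Defaults:
costs discounted at 5%/year, QALYs at 0%. The asymmetry is deliberate — the
reference results' QALY totals (9.25/child maximum vs 8.11 attainable under
5% discounting) are only consistent with undiscounted QALYs, despite the
stated intent to discount both; both rates are configurable
(`discount_rate_costs`, `discount_rate_qalys`). Caries-lesion counts are
undiscounted sums of **A** occupancy over cycles 1…10, excluding the
cycle-0 prevalent fraction (`include_initial_lesions` restores it). Because
**A**'s trajectory satisfies A(t+1) = *p_c*·(1 − A(t)), lesion counts are
invariant to the seek probability — which is why prevented caries stays at
~178 across all seek-treatment sensitivity rows.

## Sensitivity analyses

One-way DSA substitutes each selected parameter's low/high bound, all else
at base, and re-runs the full analysis; parameters without bounds are
skipped with a warning. Treatment-mix probabilities carry ±15% relative
bounds computed at load time; the caries-prevalence bounds are 95% Wald
intervals *p* ± 1.96√(*p*(1−*p*)/*n*) at the study denominators (212/196),
which reproduce the published low/high values. The tornado metric is the
absolute ICER range, ties broken alphabetically. Scenarios are named
override sets in the config; the zero-prevalence scenario applies to both
arms. The two-way validation grid crosses two parameters (by default the
caries utility and the restoration cost) and checks null/extreme behaviour,
e.g. ΔQALYs ≡ 0 when the caries utility equals 1.

## Probabilistic sensitivity analysis

Parameters with a distribution tag are sampled jointly and independently:
beta for the four caries probabilities, triangular (low, base, high) for
the two seek probabilities, gamma for the restoration cost. Beta and gamma
are moment-matched to mean = base and SD = (high − low)/3.92, reading the
bounds as a 95% interval; this parameterisation is a standard convention,
chosen here because the original fitting method is unrecorded. Observed
2-year probabilities are sampled on their measured scale and converted per
draw. Draws yielding values outside the parameter's admissible range are
resampled (counted in the result). 10,000 draws with a fixed seed; the
whole PSA runs in a few seconds.

The default PSA set follows the per-parameter distribution tags (seven
parameters). The narrative description of the original analysis suggests
utilities and possibly more costs also carried distributions; tagging
`utility_caries` as beta in the config adds it. In either configuration the
cost-effective fraction at $50,000/QALY is ≥ 99.9%.

## Synthetic data generator

`cariescea.synth` emulates the 2-year follow-up that produced the model's
probability inputs: per-arm cohorts of 196 (intervention) and 212
(comparison) children; Bernoulli baseline caries status (prevalence
0.719/0.792, the established-lesion shares at the study denominators);
Bernoulli new-caries-by-2-years (0.479/0.637, denominator = all followed
children); a Bernoulli care-seeking draw for children with caries
(0.90/0.68); and a categorical treatment draw (restoration/extraction/pulp
therapy at 0.40/0.06/0.04, remainder untreated) among seekers.
`estimate_inputs` re-derives prevalence and incidence with Wald intervals
and writes a config fragment. The records identify only the *product*
seek × mix, so the seek probability and treatment mix are reported as
conditional shares but not written into the fragment — in the original
study they came from external sources (a national survey and the consent
log).

What the generator does *not* emulate: age structure and age-specific
caries risk, clustering within schools or families, repeated lesions per
child, loss to follow-up, and any correlation between baseline status and
incidence. Passing recovery tests therefore demonstrate that the
estimation formulas are consistent and correctly propagated, not that the
design would be robust to those real-data features.

## Numerical choices and degenerate inputs

Probability/utility values are validated into [0, 1] and costs to ≥ 0 at
load; transition rows must sum to 1 within 1e−12 and traces conserve mass
within 1e−10. ICER is computed from unrounded increments and is undefined
(flagged, with NMB still reported) when ΔQALYs = 0; dominance flags cover
the sign combinations. Zero-variance or unbounded parameters degenerate to
point masses in the PSA. Tabular outputs use 6 significant digits; console
currency is rounded to whole dollars.

## Problem sizes

The deterministic analyses are closed-form small (3×3 matrices over 10
cycles) and run in milliseconds. Validation uses a 100,000-child
individual-level microsimulation as an independent oracle for the cohort
expectations (3-SE agreement), 200 replicate synthetic studies for
estimator recovery, and 10,000 PSA draws; the complete test suite runs in
well under a minute.

## Known limitations

* The treated-return and cycle-conversion conventions are reverse-engineered
  from reference outputs (see above); de novo applications should prefer
  `constant_hazard` and revisit `treated_return_convention`.
* One published one-way extreme (the seek-treatment low ICER) is not
  reproduced within tolerance under the conventions that reproduce
  everything else; it presumes a base-case QALY increment (~90 per 500
  children) about 12% above the model's (~80), and no convention examined
  closes both gaps at once.
* No heterogeneity, no tunnel states, no re-treatment costs for the same
  lesion, no correlation in the PSA, and no currency conversion or
  inflation machinery.
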