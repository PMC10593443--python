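# Methods

This note documents the models, conventions and design choices behind
`metscreen`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Index formulas and unit conventions

All formulas are computed at full precision; rounding (2 decimals for
indices and AUCs, 1 for percentages) happens only when tables are
serialised.

* **Conicity** uses the standard normalising constant k = 0.109 by
  default. Some sources print k = 0.09, which inflates the index by a
  factor of 0.109/0.09 ≈ 1.21 and is inconsistent with adult population
  means of roughly 1.2–1.35; with 0.109 a typical subject
  (WC 94 cm, 75 kg, 1.70 m) scores 1.298. The constant is an explicit
  parameter (`conicity_k`) for users who want the alternative.
* **VAI** uses the standard linear denominators 39.68 **+** 1.88·BMI
  (men) and 36.58 **+** 1.89·BMI (women). The occasionally-printed "−"
  variant gives negative denominators for any BMI above ~21 and cannot
  produce the positive population means (~1.8–3.3) the index is known
  for. On the "unity manifold" (WC equal to the denominator, TG and HDL
  at their scaling constants) VAI is exactly 1; this identity is
  asserted in the tests.
* **Units.** Conicity and BSI consume waist and height in metres; WHtR,
  RPI and VAI in centimetres. All cm→m conversions happen exactly once,
  in `compute_index_panel` / `compute_indices_df`. Glucose stays in
  mg/dL and lipids in mmol/L throughout — no silent conversions.

## MetS classification

The overall call is the harmonized ("any 3 of 5") rule; thresholds are
inclusive exactly as conventionally written (≥ for the four elevations,
strict < for the HDL deficit). Choices the rule's terse statement
leaves open:

* "≥130/85 mmHg" is read as SBP ≥ 130 **or** DBP ≥ 85 (the harmonized
  convention).
* Lipid-lowering treatment satisfies both the reduced-HDL and the
  elevated-TG component, since drug class is rarely recorded separately.
* A strict-IDF mode (elevated WC mandatory plus any two others) is
  available via `strict_idf=True` for sensitivity analysis.

Classification is pure and deterministic; a record missing any
component datum is refused (excluded with a logged reason) rather than
partially classified.

## Inferential statistics

* **t-tests** default to Welch (unequal variances, Satterthwaite df);
  the pooled-variance form is available because legacy software often
  reports it. Both are computed from sufficient statistics, which gives
  a summary-statistic entry point (`t_test_from_summary`) for checking
  printed mean ± SD tables; the raw-data route is verified against
  scipy's `ttest_ind` in the tests.
* **Proportion CIs** default to Wilson; Wald and Clopper–Pearson are
  selectable and always recorded in the output. At the cohort sizes of
  interest (~1000) all three agree to the integer percentage.
* **Pearson correlation** p-values come from t = r√(n−2)/√(1−r²);
  `pearson_pvalue_from_r` exposes the closed form for auditing printed
  (r, p) pairs without raw data.
* Two-sided p-values throughout; no multiple-testing adjustment is
  applied (a deliberate mirror of common practice in this literature —
  the report metadata carries a note saying so).

## ROC analysis

The ROC machinery is written from first principles because its exact
conventions matter for reproducibility:

* Candidate thresholds are midpoints between consecutive distinct
  scores plus ∓∞ sentinels; test-positive means score ≥ threshold.
* The trapezoidal area under this curve equals the Mann–Whitney
  statistic (ties ½) exactly; the suite asserts agreement to 1e−12 on
  200 random tied instances, plus a scikit-learn cross-check.
* **No direction auto-flip.** An index negatively associated with the
  outcome (e.g. RPI) reports AUC < 0.5 as-is; inversion is an explicit
  option. Auto-flipping would silently change the meaning of the
  reported cutoff.
* **Inference.** DeLong's nonparametric SE (midrank placement form) is
  the default; Hanley–McNeil is retained because older software reports
  that family. CIs are normal-theory, truncated to [0,1]; the AUC=0.5
  test is a two-sided z. The DeLong z-test is mildly anticonservative
  below ~50 subjects per class (rejection ~6% at 20/20 in the null
  simulations); the type-I calibration test therefore runs at 100 per
  class, inside the asymptotic regime.
* **Optimal cutoff** maximises Youden's J over the curve's full
  threshold grid (a closest-to-(0,1) criterion is selectable). Ties
  break toward the smallest cutoff, i.e. maximal sensitivity. The grid
  includes the sentinels: for an anti-associated score the best
  achievable J is 0, attained only by the degenerate classify-everyone
  thresholds, and the package reports that honestly (cutoff −∞,
  sensitivity 1) instead of a misleading finite cutoff with negative J.

## Synthetic cohort generator

The generator emulates a two-sex adult community-screening cohort and
is the package's test bed; no raw cohort ships with the package.

**Marginals.** Per sex, each variable is normal or lognormal
(lognormal for FBG and TG, giving the right-skew real lipid/glucose
panels show), truncated to physiologic ranges by rejection. Default
calibration targets are the printed study prevalences, equal across
sexes (per-sex component prevalences are not printed), so the overall
mixture prevalence is target-invariant to the sex mix:

| quantity | default | source |
|---|---|---|
| sex mix | 62.6% male | printed cohort composition |
| age | N(42.66, 12.18²) y | printed mean ± SD |
| elevated WC | 73.9% | printed prevalence (SD 11 cm assumed) |
| elevated BP | 51.1% | printed prevalence |
| reduced HDL | 49.9% | printed prevalence (SD 0.25 mmol/L) |
| elevated TG | 19.6% | printed prevalence (log-SD 0.5) |
| elevated FBG | 19.5% | printed prevalence (log-SD 0.2) |
| MetS | 32.2% | printed prevalence (dependence target) |

Heights, weights, NC, MUAC and the BP means are not printed; the
defaults (male height N(170, 7²) cm, weight N(75, 12²) kg; female
N(157, 6.5²), N(68, 12²); NC 37.8/35.6 cm; MUAC 30.7/30.8 cm;
DBP N(80, 10²), SBP SD 15 with calibrated mean) are synthetic choices
made once to land BMI (~26–28 kg/m²) and RPI (~38–41) in the printed
ranges. They are choices of this package, not study facts.

**Calibration.** Single-threshold targets are solved exactly by
quantile matching (mean = τ + sd·Φ⁻¹(q) for an exceedance target q at
threshold τ; mirrored for deficits; on the log scale for lognormal).
The compound BP criterion P(SBP≥130 or DBP≥85) is solved by bisection
on the SBP mean, with the probability evaluated exactly through the
bivariate-normal CDF at the fixed SBP–DBP latent correlation (0.6) —
deterministic, and it reduces to the inclusion–exclusion closed form
p₁+p₂−p₁p₂ when that correlation is 0.

**Dependence.** A latent Gaussian factor copula: five component
factors (waist, BP, glucose, TG, HDL) carry an exchangeable
correlation ρ; SBP/DBP load √0.6 on the shared BP factor, the four
single-variable components load 1.0, and weight/NC/MUAC load 0.5 on
the waist factor so the adiposity block clusters realistically. The
HDL latent's sign is flipped so positive ρ is positive *risk*
dependence. Consequences: every marginal prevalence is invariant to ρ;
the implied correlation matrix is PSD by construction for
ρ ∈ (−1/4, 1]; and MetS prevalence is empirically monotone increasing
in ρ, so a 1-D search (coarse grid, then bisection under common random
numbers with a fixed evaluation seed, 200k subjects per evaluation,
tolerance 0.0015) solves ρ for a target MetS prevalence. Evaluation
seeds are kept distinct from validation seeds to avoid calibration
leakage.

One structural fact worth knowing: the printed component prevalences
imply an independence (Poisson-binomial) MetS rate of 0.35418, *above*
the printed joint 32.2%, so matching all six numbers simultaneously
requires mildly negative dependence (ρ ≈ −0.16). That is a property of
the printed values, not of physiology; with a positive ρ the generator
produces the positively-clustered risk factors real cohorts show, at
the cost of a higher joint prevalence.

**Truncation.** Bounds are enforced by redrawing the whole latent row
of any out-of-range subject, which preserves the copula among accepted
rows. Floors are deliberately permissive (circumferences merely
positive; lognormal variables untruncated; height 120–210 cm, weight
30–180 kg, HDL 0.3–3.5 mmol/L, SBP 70–260, DBP 40–140, age 0–120):
because weight/NC/MUAC share the waist factor, aggressive floors would
select against low-waist-factor rows and bias the calibrated WC
exceedance upward (a ~+0.2 pp effect was measured and eliminated this
way during development). The age marginal is *not* floored at the
study's 25-year eligibility criterion — doing so would shift the mean
by ~+1.2 y off the printed 42.66; about 7% of synthetic subjects fall
below 25 and the record validator warns rather than errors on them.
Records are also required to satisfy SBP > DBP (rejection mass
~3·10⁻⁴).

**What the generator does and does not emulate.** It reproduces the
printed marginal moments, component prevalences and the joint MetS
prevalence, a plausible adiposity cluster, and right-skewed TG. It does
not reproduce the study's unprinted pairwise correlation structure
(beyond what the exchangeable factor induces), measurement error,
age–risk gradients, or any sex-specific component differences; AUCs
and cutoffs computed on synthetic cohorts are therefore *internally
valid* tests of the analysis code, not estimates of the real cohort's
screening performance. The source study's AUC and cutoff tables are
treated as output formats, not as recomputable targets — the raw
cohort is not deposited.

## Problem sizes and numerical choices

Monte-Carlo validations use 200,000 subjects where a prevalence is
checked against a 3-binomial-SE band (≈0.3 pp at these rates; a draw
takes well under a second), 10,000 replicates for the type-I-error
calibration of the t and DeLong tests, and 200 random small instances
(n ≤ 30 with ties) for the exact AUC/cutoff oracle equivalences.
Degenerate inputs error early with the offending field named: single
class for ROC, zero-variance groups for t-tests, constant vectors for
correlation, non-PSD factor correlations with the offending eigenvalue.
Analyses in the pipeline whose preconditions fail (e.g. a cohort with
no MetS cases) are reported as not-estimable cells with a reason, never
silently dropped.

## Known limitations

* The exchangeable-ρ dependence cannot represent component-specific
  correlation patterns; a per-pair latent matrix would, but the printed
  material gives no basis for calibrating one.
* DeLong/Hanley–McNeil CIs are normal-theory and degenerate at
  AUC ∈ {0, 1}; the package truncates rather than switching to exact
  small-sample intervals.
* Cutoffs are selected on the analysis sample itself (no
  cross-validation), matching standard practice in screening studies;
  reported sensitivities at the chosen cutoff are optimistically
  biased, as they are in the originals.
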