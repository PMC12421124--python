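# Methods

## Analysis unit and index-nodule reduction

All statistics are per participant. A participant with several solid
nodules is represented by a single index nodule: the malignant one if any
(at most one is allowed — participants, nodules and cancer diagnoses are
in 1:1:1 correspondence), otherwise the largest under the chosen size key.
"Largest" is resolved deterministically: larger volume first (absent
volumes rank lowest), then larger diameter, then lexicographically
smallest nodule id. Benign *retronodules* — nodules only recognised in
retrospect on a later scan — are never selected as index (had they been
the largest they would have been reported); malignant retronodules
participate fully. A participant whose only nodules are benign
retronodules is treated as having no reportable baseline nodule.

Nodules of typical perifissural (intrapulmonary lymph node) morphology are
ordinary solid nodules in every analysis; their flag exists only for the
dedicated low-risk sub-analysis.

## Size thresholds and the diameter fallback

Volumes are in mm³ (semi-automated volumetry), diameters in mm (single
long axis). Rule-out sets are strict (`size < cut-off`), rule-in sets
inclusive (`size ≥ cut-off`), matching the "<80 mm³" / "≥300 mm³"
convention of the guideline literature. Under a volumetric protocol a
nodule without reliable segmentation has no volume; it is assessed against
fallback diameter cut-offs, default 6 mm (rule-out) and 8 mm (rule-in).
The background guideline text uses a 5 mm reporting fallback while the
volumetric analysis convention uses 6 mm; both are configurable
(`ProtocolConfig.fallback_rule_out_diameter_mm`) and the default follows
the analysis convention. The protocol engine assigns exactly one action
per participant — routine recall, 3-month interval CT, or MDT referral
(rule-in size *and* Brock ≥ threshold) — with a textual trace of the rules
fired. The 200 mm³ interval-scan growth-referral constant is carried in
the config for completeness; no interval-scan logic is implemented.

## Brock (PanCan) score

The full-with-spiculation variant of the published malignancy model is
applied with its original coefficients (age centred at 62 y, nodule count
at 4, the size transform `(d/10)^(-1/2)` centred at 1.58113883); the
predicted probability is strictly increasing in diameter and higher under
spiculation, emphysema, family history, female sex and upper-lobe
location. Size input is the recorded long-axis diameter by default — also
when gating a volume-defined ≥300 mm³ nodule — with an equivalent-sphere
diameter `(6V/π)^(1/3)` available as an option. Probabilities are gated at
full precision (no rounding) with an inclusive threshold, default 10 %.
Only this variant ships as a constant because only its coefficients could
be transcribed with confidence; `BrockCoefficients` is a plain dataclass,
so any published variant can be supplied.

## Accuracy statistics

Sensitivity, specificity, PPV and NPV are the conventional ratios on the
percentage scale; a metric whose denominator is empty is reported absent,
never zero. Binomial CIs are exact Clopper–Pearson by default (validated
against published intervals, e.g. 37/4809 → 0.54–1.06 %), Wilson behind a
flag. Pearson's χ² is the classical uncorrected statistic (1 df). McNemar
defaults to the exact two-sided binomial tail `min(1, 2·P(X ≤ min(b,c)))`,
X ~ Bin(b+c, ½), because discordant counts can be small; χ² variants with
and without continuity correction are selectable. Univariable logistic
odds ratios are maximum-likelihood (IRLS) fits; perfect separation raises
an explicit error. Rendered tables round percentages half-up to one
decimal and p-values to four decimals with a `<0.0001` floor; the
machine-readable summary keeps full precision.

## ROC, DeLong and Youden

The empirical curve groups tied scores into single operating points;
AUC is the trapezoidal area, identical to the Mann–Whitney statistic with
ties counted ½. DeLong (co)variances are computed from placement values
with midranks; the paired test applies only to scores on a common subject
set, so diameter-vs-volume comparisons run on participants with reliable
segmentation. AUC CIs are DeLong-based by default. Youden's J is
maximised over the distinct observed score values, returning the smallest
threshold achieving the maximum (favouring sensitivity); thresholds are
reported as raw score values, not midpoints.

## Weighted net benefit

`NB = 100·[ΔSe + ΔSp·(1/W)·(1−p)/p]` percentage points, positive favouring
the new rule; W = 50 for rule-out comparisons and W = 5 for rule-in
comparisons by default (one cancer per 50 follow-up CTs, one per 5
referrals, under ~2 % screening prevalence). The prevalence `p` is a
mandatory, explicit choice — whole cohort, nodule participants,
size-eligible (reference-rule-positive) participants, or a fixed external
value — because reasonable analysts disagree on it and the result is
sensitive to it; every report records which was used. CIs are percentile
intervals from B = 1000 participant-level resamples (a 'basic' interval is
available); resamples that lose an outcome class are redrawn and counted.
The full-sample evaluation is the point estimate.

## Synthetic cohorts

`generate_cohort` emulates a large UK screening baseline round:
11 355 participants, 52.2 % with ≥1 solid nodule, cancer risk 3.85 % given
a nodule and 0.77 % without, 2.1 % segmentation failure. Benign and
malignant nodule volumes are log-normal — ln V ~ N(3.96, 1.06²) benign and
N(6.53, 1.92²) malignant, fitted to the cohort's cumulative size counts
(medians ≈ 52 and ≈ 690 mm³) — and the long-axis diameter is the
equivalent-sphere diameter times an elongation factor 1.39 times
log-normal noise (σ = 0.125), chosen so the implied diameter quantiles
match the cohort's diameter counts. Brock covariates use screening-typical
prevalences (male 57.7 %, emphysema 30 %, upper lobe 45 %, family history
15 %, spiculation 5 %) shifted among cancers by odds multipliers (6×
spiculation, 1.8× upper lobe, 1.5× emphysema, 1.3× family history) so the
risk score has discriminative signal. All draws descend from one seed via
named spawned sub-streams, so adding a covariate draw cannot perturb
earlier ones; fixed seed gives bitwise-identical cohorts.

What the generator does **not** emulate: the real joint dependence of
covariates, multifocality structure, interval-scan growth, reader
variability, or calibration of the Brock model to this population. Tests
passing on synthetic cohorts therefore establish the *statistical
machinery*, not clinical performance on real data.

## Exact fixture reconstruction

Published cumulative counts (participants and cancers below each
threshold, on the volume and the diameter scale) under-determine the joint
(volume, diameter) distribution. The reconstruction assigns sizes at
deterministic log-scale geometric midpoints strictly inside each bin and
couples the two scales' binned marginals **comonotonically within each
outcome class** (northwest-corner transportation for cancers and benign
participants separately). A *global* comonotone coupling does not exist in
general — and does not exist for the shipped count table, where more
cancers sit below 8 mm than below 100 mm³ although fewer participants do —
whereas the class-wise coupling exists for every internally consistent
table and reproduces every cumulative cell on both scales exactly
(`marginal_counts ∘ reconstruct_fixture = id`, the central property test).
This is a modelling choice for count-exactness, not an estimate of the
real joint. Unsegmentable nodules are emitted benign with a diameter
strictly between the fallback cut-offs (6–8 mm), so both conventions for
handling them in volume-scale counts give identical cells; their published
outcome split is unknown. Infeasible specifications (non-monotone
cumulative counts, an interval with more cancers than participants) raise
an error naming the offending bin.

## Problem sizes and numerics

Default analyses run the full 11 355-participant fixture; bootstrap CIs
use 1000 resamples in production runs and 30–300 in the test suite, where
recovery checks use generated cohorts of n = 10 000–20 000 and 3-standard-
error bands. Clopper–Pearson coverage is verified by exact summation of
binomial probabilities over the outcome space (no Monte Carlo needed).
Ties in Youden selection break toward the smallest threshold; DeLong
degenerate cases (zero variance of the difference) report p = 1.

## Known limitations

- The fixture's Brock-gated referral counts are synthetic-covariate
  outcomes; only size-threshold cells are count-exact.
- Published χ²/McNemar p-values of the source tables are not reproducible
  from their printed counts alone; the package computes them from the
  counts it is given.
- No multivariable modelling, survival analysis, multi-timepoint nodule
  tracking, subsolid-nodule terms, or decision-curve analysis over a
  threshold-probability continuum.
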