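# Methods

This note documents the statistical models behind `metinflam`, the choices
made where the design was genuinely open, and what the synthetic cohort
does and does not establish about real data.

## Index computation and units

The nine indices are simple ratios/products of glucose (mg/dL), serum
creatinine (mg/dL) and CBC counts. Two conventions exist for the
neutrophil/lymphocyte operands: absolute counts (10³/µL) or percent
differentials. The package defaults to **absolute counts** and exposes
`units_policy="percent"` as a switch; every report records the policy used.
The published fixed cutoffs (e.g. IMI 658.71 histopathological, MISI 54.81
surgical) ship as presets labelled *as published, units convention
unverified*: the magnitudes of the source descriptive statistics are most
consistent with count-scale operands, but the convention under which the
cutoffs were derived is not stated. Dichotomization is strict
(`score > cutoff` is positive; ties negative), configurable via
`strict=False`. Missing inputs propagate to missing index values; nothing
is imputed, mirroring a complete-case analysis.

## Synthetic cohort generator

The generator emulates the study conditions so every downstream stage is
testable without patient data.

* **Severity and labels.** One latent severity rank per patient drives both
  label sets. The binary splits reproduce the configured group sizes
  exactly (21/225 perforated/non-perforated; 76/170
  complicated/uncomplicated at n = 246); within each binary side the
  sub-stages follow the printed case-mix proportions (histopathological
  17.48/63.82/10.16/8.54%; surgical 1.63/29.27/36.18/32.92%,
  renormalised). Because one ranking drives both, every perforated case is
  surgically complicated — the source's two classifications are mutually
  consistent in the same direction. Note the printed surgical case-mix
  (stages III+IV ≈ 169/246) is arithmetically incompatible with the printed
  complicated group size (76); the generator treats the group sizes as
  binding, since those are what the downstream analyses use, and
  renormalises stage proportions within each side.
* **Lab marginals.** Each field is normal with the group-conditional mean
  and SD of the configured conditioning classification
  (histopathological by default), then winsorised at physiological bounds
  (concentrations and counts floored at 0.01; percentages clipped to
  [0, 100]). Normality is the minimal assumption given that only mean ± SD
  are reported. Winsorisation means fields whose printed mean sits within
  ~2 SD of a bound (notably the positive-group lymphocyte count,
  0.1 ± 0.57) realise a sample mean pulled away from the printed one; the
  law-of-large-numbers tests therefore use configurations whose means are
  far from the bounds.
* **Correlation structure.** Three latent standard-normal factors generate
  the within-group correlations: coagulation (PT, INR, aPTT),
  renal-metabolic (urea, creatinine, glucose) and immune (neutrophils
  loading +, lymphocytes −). Default within-block loadings are 0.85
  (communality ≈ 0.72), chosen to match the ~78% accumulated variance a
  3-component solution is expected to explain; all other fields are
  independent noise. Field values are `mean + sd·(λf + √(1−λ²)ε)`, so
  target moments hold by construction before truncation.
* **Flagged parameters.** Several printed descriptive entries are
  internally implausible (a percent-labelled lymphocyte row on count
  scale and vice versa; a positive-group aPTT of 17.57 ± 5.5 against
  33.45 ± 5.53; a PT group direction contradicting the running text; a
  calcium SD of 21.8 mg/dL). The defaults use these values **as printed**
  and list them in `CohortConfig.flagged_implausible` (also written to the
  `simulate` sidecar) rather than silently correcting them.
* **Missingness** is MCAR at a per-field (or global) rate, default 0,
  keeping complete-case analyses unbiased. Randomness comes from a single
  documented seed; there is no global random state.

What passing tests on this generator show: the pipeline's statistics are
correct, calibrated under the null, and able to recover a known structure
at the study's sample sizes. What they do not show: performance on real
admissions, where lab distributions are skewed, correlations extend
beyond three blocks, and missingness is not MCAR.

## Screening tests

Parametric/non-parametric selection is gated on Shapiro–Wilk at α = 0.05
per group (groups smaller than 3 or constant fail the gate). The t test
pools variances; the rank test is two-sided Mann–Whitney U. Nominal tables
use chi-square (Yates-corrected for 2×2) switching to Fisher's exact when
any expected cell is below 5; the exact fallback exists only for 2×2
tables, and larger sparse tables stay chi-square with a logged warning.
The across-stage omnibus is one-way ANOVA or Kruskal–Wallis under the same
gate. An exactly-null ANOVA (identical group means) can produce a
fractionally negative F by cancellation; the package reports the exact
null answer (statistic 0, p = 1) in that case. No multiplicity correction
is applied; reports carry the number of tests run.

## Factor analysis

KMO is computed from the inverse correlation matrix (anti-image partials);
a numerically rank-deficient matrix raises an error naming the variables
spanning the null space (relative eigenvalue tolerance 1e-10). An exactly
diagonal correlation matrix makes KMO 0/0; the package returns 0.5, its
small-correlation limit. Extraction is PCA on the Pearson correlation of
listwise-complete cases, retaining eigenvalues ≥ 1 (Kaiser) unless a fixed
component count is requested. Loadings are eigenvector·√eigenvalue, signed
so each component's dominant loading is positive; component membership is
argmax |loading|.

Rotation is off by default but **varimax is required for membership
recovery claims**: with two equal-size blocks of equal within-block
correlation the two leading population eigenvalues are exactly degenerate
(both 1 + 2r), so unrotated principal axes are arbitrary within their
2-dimensional subspace and memberships are non-identifiable. The
structure-recovery tests therefore rotate.

Recovery is asserted on the **stratified** fit (the non-perforated
subgroup, n = 225), matching the per-stage fitting the analysis supports.
On the full mixed cohort the flagged aPTT/INR group entries inject
between-group covariance of opposite sign inside the coagulation block
(aPTT shifts −2.9 SD while INR shifts +3.5 SD between groups), cancelling
the factor-driven correlation; with those printed values a full-cohort fit
yields KMO ≈ 0.55 and scrambled memberships. This is a property of the
printed parameters, not of the estimator.

Model selection fits each candidate variable set (default candidate: the
8-variable coagulation/renal-metabolic/immune set), ranks by overall KMO,
discards KMO ≤ 0.6, and tie-breaks toward the first-listed candidate. An
all-inadequate slate returns an explicit "no adequate model" result.

## ROC and cutoff diagnostics

The ROC is evaluated at every distinct score (no interpolation); AUC is the
trapezoidal integral and equals U/(n₁n₂) with ties counted ½. Inference is
Hanley–McNeil by default — it matches the classical software the field
uses and needs no resampling — with DeLong's placement-value variance
behind `ci_method="delong"`. CIs are Wald on the AUC scale, clipped to
[0, 1].

The package's positivity convention is strict (`score > cutoff`), while the
stored curve points correspond to `score ≥ threshold`; the Youden-optimal
cutoff therefore maps each curve point to the next lower distinct score, so
the returned cutoff is always an observed value and reproduces the stored
operating point exactly. Ties in J break toward higher sensitivity, then
the lower cutoff. Orientation is fixed as higher score = disease; a marker
running in the other direction must be negated explicitly — there is no
silent auto-flip.

Odds-ratio CIs use Woolf's log method; the p-value is Fisher's exact test
on the realised 2×2. A zero off-diagonal cell gives OR = +∞ with a
one-sided CI whose finite bound comes from 0.5-corrected cells;
`haldane=True` applies the 0.5 correction throughout instead. Percentages
are kept at full precision internally and rounded only at the report layer,
where p-values below 5e-4 render as "≤0.0005".

## Post-hoc power

`d = ln(OR)·√3/π` is the standard logistic-to-normal scaling. Power is the
two-tailed normal approximation for a standardized difference between
independent groups; the opposite-tail Φ term is retained so that d = 0
yields power = α exactly, although it is negligible at the magnitudes of
interest. When reproducing the published power table the inputs are the
printed (rounded) odds ratios — rounding moves the fifth decimal — and the
report notes whether ORs came in rounded or at full precision from data.

## Problem sizes and numerical choices

Test-suite simulations use the study-scale cohort (n = 246) throughout;
calibration suites run 1,000 replicates for type-I error (n = 30/group),
100 seeds for AUC-CI coverage and structure recovery, and 200,000
replicates for the Monte-Carlo power oracle, with agreement bands of
binomial 95% bounds and ±0.002 respectively. Floating-point ties in the
Youden scan are resolved with an absolute tolerance of 1e-12. All
randomness flows through explicit `numpy.random.default_rng` seeds.

## Known limitations

* Group-conditional marginals plus a 3-block factor model do not attempt
  inter-electrolyte correlations, age/sex-conditional physiology, or
  skewed lab distributions.
* Published cutoffs are reproduced as constants; their generating units
  convention is unverified, and published AUCs/ORs of the source tables
  are not reproducible without the original patient-level data — only
  their internal consistency (J = Se + Sp − 100) and the power table are
  recomputable.
* The Fisher fallback is unavailable for sparse tables larger than 2×2.
* Hanley–McNeil intervals are mildly conservative for high AUC under
  binormal scores.
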