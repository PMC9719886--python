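# Methods

## Quantities and derivations

Each ROI carries five raw DECT quantities: attenuation of the 40- and
70-keV virtual monochromatic images (HU), iodine concentration (IC) and
water concentration (WC) from two-material decomposition (mg/cm³), and the
effective atomic number (Eff-Z). Derived per ROI:

* **Spectral slope** `λHU = (att40 − att70)/30` in HU/keV. The 30-keV
  energy gap is a fixed constant of the two reconstruction energies.
* **Aorta normalization** divides IC, WC and Eff-Z by the same quantity
  measured in the patient's aorta, removing inter-patient variation in
  cardiac output and bolus timing. Normalized values are dimensionless.
* **Rate of difference (ROD)** between node and primary lesion,
  `|node − lesion| / |lesion|`, one value per parameter, zero iff the pair
  is identical on that parameter. The denominator uses the absolute lesion
  value so the statistic stays a nonnegative relative difference even for
  quantities that can be negative in other tissues (the breast/node values
  handled here are all positive, where the two definitions coincide). A
  zero lesion value raises an explicit undefined-ROD error rather than
  returning infinity.

Reporting convention: slopes to one decimal, RODs to two significant
figures; all internal computation is at full precision. When reproducing
the published per-case ROD of λHU, the one-decimal slopes are used as
inputs, because the published values are only derivable from the rounded
slopes. (One published case prints an Eff-Z ROD of 0.0086 while its printed
inputs give 0.0065; the package reports the computed value and makes no
attempt to force the printed one.)

## ROI extraction

A pixel belongs to a circular ROI iff its centre lies within Euclidean
distance `radius` of the ROI centre; there is no partial-pixel weighting
(nothing in the measurement procedure being modelled specifies one, and at
the ROI sizes involved the difference is far below measurement noise).
Coordinates are 0-based (row, col); pixel spacing is isotropic, so the
reported physical area is `n_pixels · spacing²`. Necrotic/cystic portions
are represented by a boolean exclusion mask; an ROI left empty after
exclusion is an error, not a NaN. Input is the already-chosen 2-D slice:
slice selection, registration and segmentation are out of scope, and each
site is measured once (no reader-variability model).

## Synthetic cohort generator

The generator exists because no patient-level data are deposited for this
problem; it reproduces the *published summaries* so that every downstream
stage can be exercised and calibrated.

**Joint structure.** Within each outcome group the ten spectral values
(five lesion + five node) are linked by a latent-Gaussian copula with a
single shared factor: standardized latents are
`z = sqrt(a)·F + sqrt(1−a)·ε`, giving every pair of variables latent
correlation `a = 2·sin(π·ρ_s/6)` and hence Spearman correlation `ρ_s`
exactly, by the Gaussian-copula rank-correlation identity. Defaults:
`ρ_s = 0.65` (metastasis) and `0.14` (non-metastasis), the midpoints of the
published ranges (0.609–0.692 and 0.115–0.165). A single shared factor is
the simplest structure reproducing the published pairwise lesion–node
correlations; it also induces the same correlation across parameters, which
is physiologically plausible (all five quantities track perfusion) but not
itself constrained by published data — treat cross-parameter correlations
as a modeling choice.

**Marginals.** Node marginals per group are the published means/SDs (e.g.
node attenuation at 40 keV: 247 ± 38 metastatic, 204 ± 45 non-metastatic).
Lesion marginals are not published as a table; they are anchored to the two
published worked image cases and chosen per group so the generated ROD
distributions reproduce the published group contrast and the published
ordering of ROD-marker vs raw-marker AUCs: metastasis-group lesions
(250, 100, 26.5, 1031, 9.12) ± (38, 14, 4.8, 9, 0.24) for
(att40, att70, IC, WC, Eff-Z), non-metastasis lesions
(260, 108, 27.0, 1032, 9.18) ± (45, 16, 5.6, 11, 0.29). Group membership is
Bernoulli at prevalence 39/137.

**Constraints.** Draws violating physics — non-positive concentrations,
diameters or Eff-Z, or 40-keV attenuation not exceeding 70-keV (which would
give a negative slope after iodinated contrast) — are rejected and redrawn,
never clipped, so ROD distributions carry no point masses. Rejection
slightly truncates the affected marginals (about +0.2 mm on the metastatic
shortest diameter); spectral marginals are essentially unaffected because
violations are many standard deviations out.

**Morphology and pathology** are drawn independently of the spectral block,
conditional on group: Gaussian diameters (means 7.6/3.4 mm shortest,
14.1/9.7 mm longest), hilum absence Bernoulli (24/39 vs 10/98), ER status
Bernoulli (23/39 vs 82/98), four-category nuclear grade at the published
proportions (with "NA" a real not-assessable category, not a missing
value), and Ki67 logit-normal on (0, 100)% with location/scale (−0.2, 1.1)
vs (−1.5, 1.2), giving group means near 45% and 22% and the published wide
range. Aortic IC/WC/Eff-Z are Gaussian at (51.6, 1028, 10.2), making the
normalized metastatic node IC ≈ 0.50.

**What the generator does not emulate.** The published metastasis-group ROD
means (0.05 ± 0.08 for 40-keV attenuation) are *smaller* than any Gaussian
copula can produce at rank correlation 0.65 with the published marginals:
that combination of a moderate rank correlation with very tight typical
agreement implies heavier-than-Gaussian tails in the real paired data. The
synthetic metastasis ROD means come out near 0.09–0.10. All *directions*
(metastatic RODs smaller, ROD AUCs above raw-parameter AUCs, the Spearman
contrast) are preserved, which is what the structural tests assert; passing
them says the workflow reproduces the study's qualitative structure, not
that the generator replicates the patients. The exclusion flowchart,
scanner physics, 3-D volumes and reader variability are likewise not
modelled.

## Statistical workflow

* **Group comparisons.** Continuous: Mann–Whitney U, exact by enumeration
  when both groups have n ≤ 10 with no ties, else the tie-corrected normal
  approximation with continuity correction (whose worst-case deviation from
  the exact p at n₁=n₂=8 is 0.0109, by full enumeration). Categorical:
  Fisher exact for 2×2 (two-sided by the probability-mass rule — the most
  common but not the only convention, hence documented), Pearson
  chi-squared without continuity correction for larger tables. Which
  published rows used which categorical test is unstated; the 2×2→Fisher
  rule is this package's documented choice. All p-values two-sided; missing
  values are excluded complete-case per comparison with the count reported;
  no multiplicity adjustment (none was applied in the study design being
  mirrored).
* **Screening and selection.** Univariable screen at P < 0.001 (screen
  p-values come from the same Mann–Whitney/Fisher/chi-squared tests as the
  comparison tables, not from univariable Wald tests). "Forward
  elimination", a contradictory phrase in the workflow being modelled, is
  implemented as forward selection: candidates enter in ascending
  univariable-p order and are retained iff the likelihood-ratio p of their
  addition is < 0.05; the retained-term count is capped at
  `floor(events/10)` (a standard events-per-variable rule, since no
  explicit rule is published). Every decision is recorded in a trace.
* **Logistic fits** use Newton scoring (IRLS) with step-halving, so the
  log-likelihood trace is provably non-decreasing; convergence requires
  both a stationary log-likelihood and a small score norm. Wald SEs come
  from the observed information; `OR = exp(β)`,
  `CI = exp(β ± 1.96·SE)` (profile-likelihood CIs out of scope). Exact
  collinearity raises an error naming the offending pair; separation is
  flagged as non-convergence rather than reported as garbage. ROD terms
  always enter as `10·(1 − ROD)`, which flips the association positive and
  matches the per-unit scale on which the published odds ratio (2.00) is
  interpretable.
* **ROC.** AUC is the normalized Mann–Whitney statistic with ties counted
  one half; ROD markers are oriented lower-is-positive, raw node parameters
  higher-is-positive. The operating threshold maximizes Youden's J over
  midpoints between adjacent distinct scores (plus cuts outside the
  range); J-ties are broken toward the more sensitive operating point,
  consistent with the sensitivity-leaning published operating points
  (e.g. 92.3%/56.1%); thresholds are reported in native marker units.
  AUC confidence intervals and DeLong comparisons are out of scope. The
  small-node stratum filters on shortest diameter < 5 mm (configurable).

## Numerical and interface choices

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence`; regenerating with the same seed is
  bit-identical.
* Cohorts travel as a flat CSV (one row per patient, schema in
  `dectrod.cohort.COHORT_COLUMNS`); floats round-trip at full precision and
  the missing-value token is the empty field. A non-numeric cell fails
  loudly with its row and column.
* The problem sizes used in the test suite — n = 10,000 cohorts for
  structural checks, 500 replicates at n = 5,000 for CI coverage, 200
  replicates at n = 500 for selection consistency — were chosen so Monte
  Carlo error is small relative to the asserted bands while the whole suite
  runs in about a minute.

## Known limitations

Gaussian marginals understate the tail behaviour of real paired ROD data
(see above); the copula's cross-parameter correlation structure is an
assumption; morphology is independent of the spectral block within a group,
so size-by-enhancement interactions are absent; and the generator's
defaults encode one study's population — transferring conclusions to other
scanners or populations is exactly the open question the similarity
statistic is meant to address, not something these simulations can settle.
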