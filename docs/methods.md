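# Methods

This note records the modelling choices behind `skcpipe`: what each stage
assumes, which defaults matter and why, what the synthetic generator does
and does not emulate, and the numerical decisions a maintainer would need
to revisit.

## Classification model

**Normalisation and projection.** All 21 features (20 tomographic indices
plus age, in the units of the device: mm for curvature radii and surface
indices, μm for thicknesses and elevation, % for thickness composites,
years for age) are z-scored with moments estimated on the pooled,
class-balanced training set; features constant at fit time are rejected
rather than silently dropped. PCA is fitted on the normalised pool and the
top two components retained. Pooling (rather than per-class normalisation)
keeps the projection a single linear map, which matters downstream: the
longitudinal analyses require that every scan, training or follow-up, be
projected by the same frozen transformation.

**Sign convention.** PCA loadings are sign-indeterminate; we flip PC1 so
that the keratoconus class mean has the larger PC1 coordinate. Severity
then increases to the right and every downstream monotonicity statement
(threshold curves, trajectory drift) can be phrased without case analysis.

**Class-conditional densities.** One Gaussian per class in PC1–PC2 space,
equal priors. With a single component, expectation-maximisation converges
in one iteration to the sample mean and covariance, so the implementation
uses that closed form (unbiased covariance, n−1 denominator). If a class
covariance's condition number exceeds 1e10, 1e-8 is added to its diagonal
and recorded on the model. Class balancing before the fit (patient-level
downsampling of the majority class, earliest scan per eye) exists so the
density fit cannot inherit priors from cohort composition.

**Posterior and banding.** P(KC|x) is a two-density Bayes quotient
evaluated via log-densities (numerically safe far from both means, where
both pdfs underflow). Labels: Healthy below 0.25, KC above 0.75, SKC on
the closed band [0.25, 0.75]; 0.05/0.95 delimit high-confidence tiers,
with the gaps (0.05, 0.25) and (0.75, 0.95) assigned to the more likely
class at a "likely" tier. The band endpoints are inclusive by
construction, and the tier thresholds strict — boundary cases are pinned
by tests. A one-sample t-test of paired-site PC distances against zero is
provided as the batch-effect check; note that distances are non-negative,
so the test can only fail to reject when all distances are exactly zero —
it is reported as a descriptive summary, not a calibrated test.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated. Per-group feature marginals (healthy / subclinical /
keratoconus means and SDs for all 21 features) are the package's reference
group statistics in `skcpipe.features`.

**Correlation structure.** Only marginals are specified, so inter-feature
correlation comes from a one-factor latent severity model: each eye draws
a standard-normal severity score s, and each feature's standardised value
is c·s + √(1−c²)·ε with c = ±0.7 (sign set by the direction of the
healthy→KC mean shift, age excluded). This reproduces a dominant PC1
severity axis (~70% of variance, matching the structure such cohorts
exhibit) without inventing a full covariance matrix. It is a stand-in: the
true correlation structure of tomographic indices is richer (block
structure between anterior/posterior analogues, for instance), and
passing tests say nothing about recovering it.

**Marginal families.** Unconstrained features are Gaussian.
Sign-constrained features (thicknesses, keratometry radii, RMS errors,
the notable-points radius) are moment-matched Gammas coupled through the
Gaussian copula, so their support is positive and their skew grows as the
mean approaches zero — both realistic — while the requested mean/SD are
preserved exactly. Ages are drawn from a Beta on [6, 97] solved to match
the group mean/SD exactly; a truncated normal on that range cannot attain
the healthy group's moments (the requested SD exceeds the feasible
ceiling for that mean), which is why the Beta family is used. Ages are
assigned per patient (both eyes share one age) from the patient's primary
group.

**Fellow eyes.** The fellow eye shares the index eye's group with
per-group concordance defaults 0.949 (healthy), 0.841 (KC), 0.096 (SKC);
a discordant subclinical index eye receives a keratoconic fellow with
probability 0.546/(0.546+0.425), mirroring the observed asymmetry of the
phenotype. Fellow-eye composition and concordance are treated as
independent knobs; no attempt is made to make them jointly consistent.

**Longitudinal process.** Follow-up visits arrive at exponential
inter-visit intervals with group rates 2.3/year (healthy) and 3.2/year
(subclinical and keratoconus tracks). The classification state evolves
per visit by a first-order Markov chain; the default matrix uses the
reference subclinical row (0.086 to H, 0.562 retention, 0.352 to K) and
encodes >90% retention for the extremes (H row 0.95/0.04/0.01, K row
0.01/0.04/0.95 — the off-diagonals of the extreme rows are a package
choice, since only their order of magnitude is constrained). On a state
change, features are redrawn from the new group's spec with the eye's
latent severity retained, so an S→K transition thins thicknesses and
raises elevation/RMS indices in the directions progression analyses
expect. Age advances with elapsed time.

**Artifacts.** Four tagged kinds at per-record Bernoulli rates: same-day
repeat scans with degraded coverage and extra noise; coverage forced below
the inclusion thresholds; one sign-rule feature set to an impossible value;
and gross multivariate outliers with every index displaced ≥ 6 pooled SDs
with random sign (emulating mislabeled or structurally abnormal scans —
edema, post-surgical corneas). Tags make QC recall measurable. The
generator does not emulate image-level artifacts, device calibration
drift, or treatment effects (cross-linking is out of scope).

## Quality control

Fixed stage order — coverage → same-day selection → plausibility →
isolation forest — with each record attributed to the first stage that
rejects it, so report counts reconcile exactly. (The ordering within the
pipeline is a package decision; the stages themselves and their rules are
not.)

- Coverage: kept iff OC > 65, or SC > 85 when OC is at or below its
  threshold; strict comparisons, missing coverage is its own removal
  reason.
- Same-day: composite quality = mean(OC, SC); ties broken by higher OC,
  then stable input order. The composite is the simplest symmetric choice
  consistent with "highest composite quality".
- Plausibility defaults are the sign rules only: thicknesses and
  keratometry radii strictly positive, RMS and distance metrics
  non-negative. Range-based bounds derived from published normal ranges
  are available (`widened_range_rules`) but deliberately not default:
  normal ranges describe healthy corneas, and diseased eyes legitimately
  live far outside them.
- Isolation forest: 100 trees, contamination default 0.005, fixed seed,
  scores computed on the standardised 21-feature matrix; skipped with a
  warning below 50 records. Removal never exceeds contamination·n + 1.
- Repeatability: within-subject SD per 5-point coverage bin =
  √(mean over same-day repeat groups of the per-group variance), reported
  separately under OC and SC binning. 5-point bins match the granularity
  at which coverage effects are typically reported.

## Threshold curves

The posterior is smoothed against each raw feature with lowess (locally
weighted linear regression, tricube weights, span 0.5 by default,
configurable) on a 200-point grid spanning the 1st–99th percentiles;
smoothed values are clipped to [0, 1] with the clip recorded. The severity
direction is the sign of the Spearman correlation between feature and
posterior; 25%/75% crossings are located by linear interpolation walking
the grid in that direction, reporting the first crossing and flagging
multiplicity. The smoothing family and span are package choices — only
"smoothed" behaviour is externally constrained — and tests verify that a
known logistic link is inverted to within 2%.

## Longitudinal and survival analyses

**Progression.** Criteria: anterior radius decrease > 0.1 mm (strict),
posterior radius decrease > 0.05 mm (strict), pachymetry reduction ≥ 20 μm
(inclusive); two of three required. Curvature features are radii in mm, so
decreases map directly to steepening with no diopter conversion. Default
evaluation compares baseline against every later visit and takes the worst
case (cumulative change), with a consecutive-pairs mode available; the
cumulative reading matches clinical practice of judging progression from
baseline.

**Drivers.** Progressing vs non-progressing subclinical eyes are compared
per feature on per-eye mean absolute per-visit change: signed log2 fold
change (sign from the median signed-change difference, so thinning
features carry negative fold changes), seeded 2,000-resample bootstrap 95%
CI, two-sided rank-sum p, and Benjamini–Hochberg adjustment across the 21
features. The test family is a package choice (the comparison is
rank-based elsewhere in the pipeline, and 21 simultaneous features warrant
adjustment; both raw and adjusted p are reported).

**Survival.** Event = first visit labeled KC after baseline
(first-passage; later reversion does not undo it); censoring at last
visit; single-visit eyes excluded with a count. Age matching is greedy
1:1 nearest-neighbour without replacement, processing order randomised
and seeded — greedy matching is order-dependent, and randomisation
removes the systematic bias a fixed order would introduce; no caliper by
default. Eyes are the unit of analysis; intra-patient correlation is not
modelled and the KM comparison is otherwise unadjusted. KM curves use the
product-limit estimator with Greenwood confidence bands (via lifelines);
the group comparison is the standard 1-df log-rank test.

## Staging

ABCD-style stages are computed from generic tabular inputs (steepest
anterior radius, steepest posterior radius, thinnest pachymetry, BCVA).
Stage boundaries ship as configuration with published Belin–Ambrósio
defaults (A: 7.25/7.05/6.35/6.15 mm; B: 5.90/5.70/5.15/4.95 mm; C:
490/450/400/300 μm; D: 0.0/0.3/0.7/1.3 logMAR); BCVA is logMAR by
convention here (lower is better), and both the units and the cutoffs are
configurable because grading tables are revised and device conventions
differ. The composite is the modal component stage, ties broken toward
the worse stage. External cross-linking risk scoring is a pluggable
provider interface with a deterministic logistic mock for tests; the
production calculator is an external service and out of scope.

## Problem sizes and determinism

The quantitative experiments run at desk scale on one CPU: moment
recovery at 10,000 eyes per group, Markov recovery at 5,000 transition
pairs, and the survival comparison at 337 eyes per group over an 800-day
horizon — sizes at which binomial/standard-error tolerances are tight
enough to be meaningful while the full suite stays fast. Every stochastic
component draws from `numpy.random.default_rng` seeded from an explicit
seed (configs carry one; derived streams use distinct child keys), and
byte-identical reruns are asserted by tests at the pipeline level.

## Known limitations

- The one-factor latent model understates the richness of real
  inter-index correlation; covariance-sensitive conclusions should not be
  read off the synthetic cohort.
- Group marginals are treated as exact population parameters; sampling
  uncertainty in the reference statistics is not propagated.
- The subclinical generating group is itself an idealisation — in the
  semi-supervised framing the ambiguous band is a property of the fitted
  densities, not a third population; the generator tags both views so the
  discrepancy is measurable rather than hidden.
- The batch-effect t-test is statistically degenerate (see above) and
  kept for interface fidelity.
- Visit processes are memoryless and independent of disease state beyond
  the rate constant; real surveillance intensifies after suspicious
  findings, which would bias time-to-event comparisons in ways the
  synthetic cohort cannot reveal.
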