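# Methods

This note records the optical models, the statistical procedures, the
synthetic-data design, and the numerical choices behind `iolray`, in the
spirit of a package's model documentation: enough detail to know exactly
what is computed, what is assumed, and what the simulated results do and
do not demonstrate.

## Conventions and units

Axial distances are in mm (cornea anterior vertex at z = 0, positive
toward the retina), corneal thickness input in µm, powers and
refractions in diopters. Keratometry uses the 1.3375 keratometric index
(r = 337.5/K), except where a formula historically prescribes another
(1.3315 for Haigis, 1.333 for SRK/T, 4/3 for Holladay 1). Refractions
are spherical equivalents at a 12 mm spectacle vertex. The preoperative
anterior chamber depth (ACD) is the *external* reading (epithelium to
lens front), the convention of swept-source biometers; routines needing
an endothelium-referenced depth subtract the measured corneal thickness
(0.54 mm assumed when unmeasured). Effective lens positions (ELP) are
referenced to the posterior corneal vertex; `elp_center` locates the IOL
optical center and `elp_front_vertex = elp_center − thickness/2` its
anterior vertex.

## Effective lens position

Two anatomy-driven predictors are implemented:

1. **Axial-length-scaled:** `A = 4.6·(a/23.6)^0.7 + A_m − 4.6 −
   0.5·(d − d_m)`, where 4.6 mm is the chamber depth of a 21 D reference
   IOL centered in a mean 23.6 mm eye, `A_m` the model-specific mean-eye
   depth, and `d, d_m` the central thicknesses of the implant and the
   21 D reference lens. When `A_m` is not supplied it is derived from
   the SRK/T A-constant (`0.62467·A − 68.747 − 0.54`; the epithelium-
   referenced chamber-depth constant minus an average cornea).
2. **Lens-thickness:** `A = A_p + 0.574·t_L − 0.632 − 0.5·d` on the
   endothelium-referenced preoperative ACD `A_p` and crystalline lens
   thickness `t_L`. Both formulas are read as posterior-cornea →
   IOL-center distances: their −0.5·d terms already compensate implant
   thickness, and the front-vertex position follows by subtracting d/2.

The default combination (`mode="auto"`) is the arithmetic mean of the
two predictions when ACD and LT are both present — the simplest
symmetric combiner of an axial-length-scaled and a lens-anatomy
predictor — falling back to the scaled form otherwise. The Haigis
linear ELP (`a0 + a1·ACD + a2·AL`, external ACD) is available as a
fourth mode. Scaling constants (4.6 mm, 23.6 mm, exponent 0.7) are
configuration defaults, overridable per run.

## Thin-lens formulas

SRK/T, Hoffer Q, Holladay 1, and Haigis are implemented from their
original closed forms (corneal-height ELP with long-eye axial
correction and retinal-thickness term for SRK/T; tangent-term
personalized ACD with AL clamping to [18.5, 31] mm for Hoffer Q;
corneal-height anatomical ACD plus surgeon factor and 0.2 mm retinal
thickness for Holladay 1; the linear ELP for Haigis), each composed
with one shared paraxial vergence chain. This composition is exactly
equivalent to the published refraction formulas and makes the
"ELP model + chain" structure testable: every formula must agree with
the generic vergence predictor fed its own (AL, K, ELP, P).

Chosen powers live on a 0.5 D grid; the grid power minimizing the
distance of predicted refraction to the target is selected, exact ties
resolving to the higher power (the more myopic outcome, the usual
clinical convention). If the emmetropic power falls outside the
[−10, 40] D grid entirely (possible at the 35 mm/steep-cornea corner of
the population), the nearest bound is chosen, as a surgeon limited to a
finite power range would. SRK/T's corneal-height square root can go
negative at steep-cornea/long-eye combinations; the scalar API raises
an explicit formula-domain error, while batch pipelines opt into the
standard clinical-calculator guard of capping the corneal height at the
corneal radius so cohort runs are total.

Astigmatic eyes are handled at the spherical-equivalent level: thin-lens
formulas consume the mean keratometry, which equals sphere + cylinder/2
of a meridian-by-meridian prediction in the paraxial limit.

## Ray-tracing engine

The pseudophakic eye is a chain of four conicoid surfaces — anterior
cornea (radius from the keratometric reading), posterior cornea at a
fixed 0.883 of the anterior radius (the classical anterior/posterior
ratio 6.8/7.7), and the two IOL surfaces from a per-power geometry
database — with indices 1.376 (cornea) and 1.336 (aqueous and vitreous),
an iris stop between the posterior cornea and the optic, and the retina
at the axial length. IOL geometry at non-labeled powers is interpolated
linearly in surface *curvature* (curvature, not radius, scales
near-linearly with labeled power), thickness, and asphericity.

Rays are meridional (2-D). Intersections solve the conic
`y² = 2Rs − (1+q)s²` exactly (stable quadratic, vertex branch);
refraction applies the exact vector Snell law. Tracing is per principal
meridian, built separately from K1 and K2; full 3-D skew tracing is not
needed for spherical-equivalent outputs and is out of scope, as are
chromatic dispersion, decentration/tilt, topographic corneal surfaces,
and post-refractive-surgery corneas.

**Best focus.** The refraction of an eye is the spectacle power that
focuses the zonal reference ray — pupil-plane height pupil_radius/√2,
the ray halving the encircled pupil area, with the pupil defaulting to
2.5 mm at the iris plane — exactly on the fovea. It is computed by
*reverse* tracing: the ray leaving the foveal point that attains the
reference height at the iris plane is found by bracketed root solving
on its launch slope (brentq, xtol 1e−12), traced out of the eye, and
extended to the spectacle plane, where the focusing power follows in
closed form from its height and slope (S = −1000·u/y at z = −12 mm).
By reversibility of light this is identical to searching the spectacle
power forward — verified in the tests by forward retracing, which lands
on the retina to 1e−16 mm — at a fraction of the cost. Corrections
outside ±30 D raise a non-physiologic-eye error. The mean of the two
meridian powers is reported as the spherical equivalent.

An optional multi-ray mode replaces the single zonal ray by a fan
filling 90% of the pupil, weighted by the Stiles–Crawford apodization
`10^(−0.116·y²)`, and minimizes the weighted RMS retinal spot over a
±3 D window around the single-ray solution. The single-ray criterion is
the default and the one used throughout the pipeline.

The iris stop is placed 0.5 mm in front of the IOL anterior vertex
(clamped to stay behind the cornea in shallow chambers); its exact
position only selects which physical ray is "the" reference ray and
perturbs the result at second order.

## Statistics

The prediction error of a method for an eye is PE = predicted − observed
postoperative spherical equivalent (that sign convention, predicted
minus actual, is stated explicitly because the opposite one is also
common; positive PE means the formula predicted more hyperopia than
observed). Summaries report mean/SD (n−1)/median/range of PE and |PE|
and the inclusive percentages within 0.25/0.50/1.00 D.

* **Mixed model:** |PE| ~ formula with a patient-level random intercept
  (REML, statsmodels MixedLM), absorbing both fellow-eye correlation
  and the strong within-eye correlation across formulas (all formulas
  share one observed refraction). All C(k,2) pairwise contrasts are
  reported with Bonferroni adjustment over that full family; a
  reference-vs-others table is a filtered view, not a smaller family.
  Contrast p-values use a t reference with containment degrees of
  freedom `N − #patients − rank(X) + 1`, which reduces exactly to the
  paired t-test for two formulas with one eye per patient (statsmodels
  provides no Satterthwaite df for MixedLM; the containment rule is the
  conservative classical alternative).
* **Levene:** classic mean-centered variant (one-way ANOVA F on
  absolute deviations from group means, (k−1, N−k) df), via
  scipy.stats.levene.
* **GEE:** per threshold, the binary indicator |PE| ≤ t is modeled with
  a binomial GEE (logit link, exchangeable working correlation
  clustered on patient, robust sandwich covariance); pairwise log-odds
  contrasts are Wald-tested and Bonferroni-adjusted. A formula with
  all-0 or all-1 outcomes is completely separated: its proportion is
  still reported but contrasts involving it carry undefined (null)
  p-values rather than fabricated ones.
* **Subgroups:** axial-length bins <22, [22,24), [24,26), [26,30), ≥30
  mm (half-open at interior edges, so 24.0 mm falls in 24–26). Each
  populated bin gets the full summary, its own pairwise contrasts when
  the design allows, and a PE-variability profile (SD of PE per formula
  per bin); empty bins are absent, not zero-filled.

## Synthetic cohort

The generator emulates a cataract-surgery population with a wide axial-
length range. Axial length follows a two-component normal mixture
truncated to [19, 35] mm — N(23.21, 0.90) with weight 0.76 for the bulk
and a broad N(24.0, 4.60) with weight 0.24 carrying both tails — fitted
once by least squares so that at large n the mean (23.66 mm), SD
(2.07 mm), and the five bin frequencies (≈12/59/20/7/2% for
<22/22–24/24–26/26–30/>30 mm) of the target population are met; the
achieved median (≈23.3 mm) follows without being fitted. Patients own
the axial-length draw; fellow eyes of bilateral patients (default
8/180 of patients, giving 188 eyes from 180 patients at n = 188) add
only 0.1 mm of between-eye jitter.

Correlated biometry is linear in AL with Gaussian noise and physiologic
clips: external ACD = 0.85 + 0.12·AL ± 0.25 (deeper chambers in longer
eyes), LT = 6.40 − 0.08·AL ± 0.30 (thinner crystalline lenses), mean K
~ N(43.5, 1.4) D with half-normal astigmatism (SD 0.75 D) split evenly
across K1/K2, CCT ~ N(540, 33) µm, plus corneal diameter and pupil
size. No AL–K correlation is imposed; the published population
marginals do not constrain it, and the defaults are documented,
overridable constants.

**Forward model.** Surgery implants the power chosen by the
axial-length formula rule at a plano target from a generic biconvex
hydrophilic-acrylic IOL family (n = 1.46, labeled −10…+40 D, front
surface carrying 0.5·P + 8 D, back surface solved exactly from the
thick-lens equation, thickness 0.30–1.00 mm growing with power;
A-constant 118.4 with pACD/surgeon-factor/Haigis constants by the
standard conversions). The *true* refraction is the package's own ray
tracer evaluated at the anatomy-predicted ELP plus Normal(0, 0.3 mm)
position noise — half of its variance shared at the patient level,
which is what makes fellow-eye errors positively correlated — and the
observed refraction adds Normal(0, 0.35 D) measurement noise rounded to
0.25 D phoropter steps. Noise draws are stored standardized, so setting
a noise SD to zero reproduces the noiseless value bit-exactly without
regenerating the cohort.

Because the truth model *is* the ray tracer, the ray-trace method's
superiority in any simulated comparison is a construction artifact:
zero mean error and the tightest spread for the ray-trace row validate
the plumbing (known-truth recovery), while the thin-lens rows acquire
systematic offsets of roughly ±0.6 D from the deliberate decision not
to re-optimize the generic IOL constants against the simulated truth
(mirroring a study setting without constant optimization). Passing
tests therefore demonstrate internal consistency and calibrated
population structure — not clinical accuracy claims for any method, and
no clinical effect sizes are asserted anywhere in the suite.

## Numerical choices and problem sizes

Bisection-free best-focus via reverse tracing is deterministic to well
below 1e−6 D; ray-power solving searches the 0.5 D grid by bisection on
the sign of (predicted − target), valid because predicted refraction is
strictly decreasing in power. Degenerate inputs are errors, never
silent: rays that miss a surface, exceed an aperture, hit total
internal reflection, or are clipped by the iris raise typed exceptions;
vergence singularities, invalid geometry orderings (e.g. an ELP beyond
the retina), empty statistical groups, and non-crossed designs do the
same.

Test and demonstration problem sizes are chosen so the whole suite runs
in well under a minute of optical work: calibration checks draw 20,000
eyes, known-truth recovery uses 5,000 eyes (three-standard-error bands
around the half-normal MAE 0.399 D and the 95.45% within-1-D fraction),
the end-to-end reproducibility study uses 188–200 eyes, and the
null-calibration and variance-component simulations use 100–200
replicates of small cohorts. Reports serialize to canonical sorted-key
JSON, so a fixed configuration (including its seed) yields a
byte-identical report.

## Known limitations

The corneal model is keratometric: a conicoid anterior surface from K
readings and a fixed posterior/anterior ratio, not measured topography
or a measured posterior cornea. The ELP predictors ignore capsule
fibrosis dynamics; refraction is a single postoperative snapshot. The
synthetic cohort matches the target axial-length distribution and
plausible biometry correlations but not unpublished covariances
(e.g. AL–K), per-bin keratometry, or IOL-model mix, and its noise
scales, while clinically plausible, are stipulated rather than fitted.
The IOL geometry family is generic rather than a manufacturer's
proprietary design.
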