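# Methods

`fetalgrowth` implements a normative analysis of fetal rhesus macaque brain
growth over the second half of gestation (G85–G155 days post-conception;
term ≈ 165 days), referenced to a post-pubertal adult sample. The package
covers four linked analyses: sigmoidal growth-curve modeling of regional
volumes, mixed-effects inference for sex and acquisition confounds on
trajectory residuals, mid-cortical surface morphometry from label images,
and vertex-wise mapping of cortical surface-area expansion. Synthetic
cohorts and geometric phantoms with analytic ground truth exercise every
stage.

## Growth-curve models and selection

Five families describe a measurement series V(t) (volume in mL, surface
area in cm², thickness in mm; age t in days post-conception):

- linear `V = m·t + b` and quadratic `V = c₂t² + c₁t + c₀` (the quadratic
  captures the U-shaped ventricular trajectory);
- three-parameter logistic `V = A / (1 + exp(−Rg(t − tmid)))` with
  asymptote A, inflection age tmid, and maximal rate `A·Rg/4` at tmid;
- four-parameter logistic `V = (A−B)/(1 + exp(−Rg(t − tmid))) + B`,
  which relaxes the V(0) ≈ 0 constraint to V(0) ≈ B;
- Gompertz `V = a·exp(−b·exp(−c·t))`, asymmetric around its inflection at
  `tmid_G = ln(b)/c` where the maximal rate is `Rg_G = a·c/e`.

Fits are bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`) with deterministic data-driven starts:
A₀ = 1.1·max(V), B₀ = min(V), tmid₀ = first age exceeding half the
maximum, Rg₀ = 4·range(V)/(range(t)·A₀); the Gompertz start is
moment-matched from a three-parameter-logistic pilot fit (same asymptote,
inflection age, and maximal rate, giving c₀ = Rg·e/4, b₀ = exp(c₀·tmid)).
Default bounds are generous but exclude degenerate optima: asymptotes in
(0, 10·max(V)], rate constants in (0, 1] per day, inflection ages in
[0, 400] days. Optimizer failure or degenerate data (constant values, or
fewer distinct ages than free parameters) yield `converged = False`,
never an exception.

Families are compared by a Gaussian-residual BIC,

    BIC = n·ln(RSS/n) + k·ln(n),

with k counting the free curve parameters **plus one** for the residual
variance. Whether the original analysis counted the variance parameter is
not documented; the convention is stated in every JSON report, and since
the variance term adds `ln(n)` to every family alike it never changes a
ranking. Non-converged families are excluded (recorded as +∞); near-ties
(|ΔBIC| < 1e-6) go to the family with fewer parameters. The RSS is floored
at 1e-300 before the logarithm so that interpolating fits on noiseless
data keep a finite BIC; ties between such perfect fits again resolve by
parsimony.

Percent-of-adult trajectories (100·V_fetal/V_adult) are fitted with the
three-parameter logistic constrained to asymptote at 100%, so the implied
maximal rate is 25·Rg %/day. Values above 100% are tolerated as noise; a
mean above 110% in the oldest decile of ages triggers a log warning since
it usually means a wrong adult reference.

## Two-stage mixed-effects inference

Because every region grows nonlinearly, covariate effects are tested on
the residuals of the selected population fit:
`r_i = V_i − V̂(t_i)`, modelled as

    r_i = β₀ + β₁·age_i + β₂·cov_i + β₃·age_i·cov_i + u[subject_i] + ε_i

with one Gaussian random intercept per fetus. Variance components are
REML estimates: the variance ratio λ = var_subject/var_resid is profiled
(per-subject blocks inverted analytically by Sherman–Morrison, the
residual variance solved in closed form), leaving a bounded 1-D
optimization in log λ. The zero boundary (no identifiable subject
variance) is detected by comparing against the λ = 0 criterion; there the
fit reduces exactly to OLS, which is also the exact behavior when no
subject is scanned twice.

Degrees of freedom for the coefficient t-tests use the Satterthwaite
approximation: `df_j = 2·Var(β̂_j)² / (gᵀ A g)` where g is the gradient of
the coefficient's sampling variance with respect to
(var_subject, var_resid) and A the inverse observed information of the
REML log-likelihood, both by central finite differences. On a frozen test
dataset the betas, standard errors, variance components, Satterthwaite df,
and p-values agree with `lmerTest::lmer` to at least four decimals, and
with `statsmodels.MixedLM` (which lacks Satterthwaite df) on the shared
quantities.

Sex is coded male = 1, female = 0, so a positive age-by-sex interaction
means faster male growth; the original report does not state its coding,
so signs may be flipped relative to it. Age enters uncentered, in days.
P-values are two-sided at α = 0.05 with Bonferroni correction
(`min(1, m·p)`) across the regions of the same analysis family (m = 7 for
the volume compartments, m = 3 for the surface metrics by default).
Confound screens (scanner version, reconstruction method, scan number,
in-plane resolution, pulse sequence) reuse the same model with the
confound in place of sex; multi-level categorical confounds are coded
ordinally, and single-level confounds are skipped with a warning.

## Volumetrics

Label images use the fetal template scheme (1 CSF, 2 cortical plate,
3 subplate, 4 ventricles, 5 GMAT, 6 thalamus, 7 cerebellum, 8 brainstem,
9 corpus callosum, 10/101/102/104 striatal and pallidal codes,
103 hippocampus, 106 amygdala, 107 hypothalamus). A compartment volume is
the voxel count times the voxel volume, in mL. The default aggregation
keeps only compartments identifiable at every age: all deep-gray and
striatal codes merge into subcortical gray regardless of which code an
age-specific template used, and subplate + GMAT + corpus callosum form
nascent white matter. Labels named by the scheme but absent from an image
(e.g. no caudate at G85) contribute zero with a warning. Two identities
hold exactly by construction and are tested: ICV = whole brain +
extra-axial CSF, and whole brain = the six disjoint analysis compartments.

## Mid-cortical surface extraction and morphometry

The mid-cortical surface is extracted deterministically from a label
image: (1) optional hemisphere restriction at the mid-sagittal x-midpoint;
(2) brainstem, cerebellum, and extra-axial CSF are dropped; (3) remaining
non-cortical-plate tissue forms the interior mask; (4) each cortical-plate
voxel joins the mask when its Euclidean distance to the interior is less
than or equal to its distance to the outside of the brain (ties to the
interior, biasing the boundary toward mid-plate depth); (5) the mask is
smoothed with a 5×5×5 uniform box filter; (6) marching cubes triangulates
the 0.5 level set in world (mm) coordinates; (7) the largest connected
component is kept, and a non-closed result is flagged with its boundary
edge count.

Per-vertex area is one third of the incident triangle areas (summing
exactly to the total). Mean curvature H uses the cotangent-Laplacian
mean-curvature normal with Meyer mixed-Voronoi vertex masses, signed by
the outward normal (H = 1/r on a sphere of radius r; within 2% on
icospheres and 5% on 2:1 ellipsoids away from the poles). Gaussian
curvature is the angle defect over the mixed area; its integral is a
combinatorial invariant (4π for genus 0), which doubles as a topology
check on extracted meshes.

The non-dimensionalized curvature is `K* = ⟨|H|⟩ · sqrt(SA/4π)` with an
area-weighted mean — exactly 1 for a sphere at any scale, increasing with
folding. The magnitude convention is deliberate: a signed mean cancels on
folded surfaces and could not increase with gyrification. Because
marching-cubes meshes carry voxelization noise that biases ⟨|H|⟩ upward
(≈14% on a 0.5 mm sphere phantom), the signed curvature field is smoothed
by two neighbor-averaging iterations before the magnitude is taken;
constant fields are fixed points, so analytically smooth meshes are
unaffected, and the sphere phantom lands within 1% of K* = 1. Absolute
K* values from other tool chains may differ by their discretization
convention. Thickness is cortical-plate volume over mid-surface area
(10·mL/cm² → mm), recovering a 2 mm analytic shell within 5%.

## Expansion mapping

Vertex correspondence across ages is an input (surface registration is
out of scope; synthetic sequences have exact correspondence by
construction). The expansion of vertex i between a young and an old mesh
is the ratio of its per-vertex areas; forward and reverse-direction
estimates are averaged arithmetically (geometric averaging available),
and coincide exactly under exact correspondence. Expansion relative to a
reference age (the youngest, by convention, with the reference mapping to
exactly 1) yields per-age maps; a three-parameter logistic fit through
each vertex's trajectory gives maps of asymptotic expansion A, maximal
rate Rg, and inflection age tmid. Vertices whose fit fails or pins a
parameter at a bound are masked rather than reported. The adult time
point enters the fits at t = 1770 days post-conception (165-day term plus
~4.4 years), configurable, since no abscissa for the adult sample is
documented. Mean expansion differences between maps are area-weighted by
the reference-age vertex areas.

## Synthetic data

The cohort generator mirrors the study design: 50 fetuses (28 female),
105 scans allocated to target ages {85, 97, 110, 122, 135, 147, 155} with
per-age counts (31, 5, 20, 6, 28, 6, 9), every fetus scanned 1–4 times,
never twice at the same target age, with Gaussian age jitter (SD 2.3
days, matching the reported template age spreads, truncated at ±7 days).
Region values are drawn from the published trajectory parameters
(sex-specific logistic fits for whole brain, cortical plate, and
cerebellum; a four-parameter logistic for nascent white matter; Gompertz
for subcortical gray and brainstem; a quadratic for the ventricles) plus
a per-subject random intercept and i.i.d. noise. Defaults: noise SD = 2%
of the age-specific model value, subject SD = 4% of the model value at
the median target age (G122) — large enough to make recovery nontrivial,
small enough to be stable. Two generative constants are not documented in
the source material and were fixed once: the four-parameter-logistic
offset B = 2.0 mL (a realistic nascent-white-matter value extrapolated to
conception, giving ≈2.9 mL at G85), and the ventricular quadratic
(minimum 0.35 mL at G110, 0.45 mL at G85, i.e. c₂ = 1.6e-4), matching the
qualitative U-shape with a minimum near G110 that surpasses the G85 value
after G147. An optional `sex_age_slope_delta` adds a male growth-rate
excess (e.g. 0.014 mL/day) for controlled recovery experiments.

Phantoms are concentric spheres (ventricle core 5 mm, subcortical to
10 mm, subplate to 15 mm, cortical plate 15–17 mm, CSF to 20 mm, 0.5 mm
voxels by default); the folded variant ripples the cortical-shell
boundaries with an axisymmetric cos(kθ) perturbation whose compartment
volumes and mid-surface area are computed by exact 1-D quadrature.
Growing mesh sequences displace icosphere vertices radially by the square
root of a logistic-in-time, smooth-in-space areal expansion field
(occipital-high/frontal-low by default), recording the analytic field as
truth.

What the generators do **not** emulate: image intensities, motion or
reconstruction artifacts, registration error in vertex correspondence,
segmentation noise, litter/dam structure, or age-dependent heteroscedastic
biology beyond the proportional noise model. Passing recovery tests
therefore validate the estimators under the stated design, not robustness
to those real-data effects.

## Problem sizes and numerical choices

Monte-Carlo studies use 200 simulated cohorts for parameter recovery,
100 seeds per family for BIC selection consistency at 1% noise, 1000 null
replicates for the interaction type-I error, and 300 vertices for
trajectory recovery; phantom grids are 88³ voxels at 0.5 mm. These sizes
give stable estimates (binomial SE ≈ 0.7% at 1000 replicates) while a
full test run stays interactive. Determinism: every generator and
analysis is a pure function of its seed; reports round floats to 10
decimals and sort keys so reruns are byte-identical.

## Known limitations

- The hemisphere split is a coordinate plane, appropriate for
  midline-aligned templates only; supply pre-split labels otherwise.
- Satterthwaite information uses finite differences; with variance
  estimates at the boundary the classical OLS df is substituted.
- Vertex-wise logistic fits are independent per vertex; no spatial
  regularization is applied.
- The two-stage residual approach ignores uncertainty in the first-stage
  curve fit; with ~100 observations per region this is negligible for
  the interaction test (type-I error calibrates within Monte-Carlo error)
  but matters for very small cohorts.
- Multi-level confounds are tested with a single ordinal slope, not
  factor contrasts.
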