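# Methods

This document describes the models implemented in `petkin`, the defaults and
the reasoning behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing the results.

## Study design being emulated

A dynamic brain PET study with a reversibly binding radioligand:

* 60-min dynamic acquisition, 38 frames (6 × 10 s, 6 × 30 s, 11 × 60 s,
  15 × 180 s);
* arterial sampling in a subgroup (10–180 s every 10 s, then 4, 5, 10, 20,
  30, 45, 60 min) with venous parent-fraction samples at 5, 10, 20, 30, 45,
  60 min;
* regional quantification by the reference-tissue Logan method with the
  cerebellum as reference, cross-validated against arterial Logan Vt;
* group statistics: per-region sex comparisons, VOI-level trait regressions,
  and voxel-wise trait association with (a) permutation small-volume FWE
  correction over the amygdala and (b) whole-brain uncorrected height
  thresholding with a cluster-extent filter.

Internal units are minutes for time and kBq/mL for activity.

## Kinetic model

Tissue kinetics follow the two-tissue compartment model (2TCM) with rates
K1 (mL/cm³/min), k2, k3, k4 (1/min). The impulse response is

    h(t) = K1 [ phi1 e^(−theta1 t) + phi2 e^(−theta2 t) ],

with theta1,2 the roots of s² + (k2+k3+k4)s + k2·k4 and
phi1 = (k3 + k4 − theta1)/(theta2 − theta1), phi2 = 1 − phi1. The total
distribution volume is Vt = (K1/k2)(1 + k3/k4); with a reference region that
shares K1/k2 and has no specific binding, DVR = Vt/Vt_ref = 1 + k3/k4 and
BPnd = DVR − 1 = k3/k4.

`simulate_2tcm` evaluates the convolution of h with the input *analytically*
(no ODE stepping): the input model is a linear rise to its peak followed by a
sum of three exponentials, and ramp×exponential and exponential×exponential
convolutions have closed forms. Frame values are averages of the continuous
curve over each frame (16-point trapezoid per frame). For inputs available
only as samples, an exact piecewise-linear convolution (`conv_exp_sampled`)
is used instead. Correctness is pinned by unit tests against an independently
derived one-tissue closed form (machine precision) and against a
high-accuracy `solve_ivp` oracle for the two-tissue case.

## Input function and metabolite model

The parent (unchanged-tracer) arterial input is

    Cp(t) = (t/tp)·sum(Ai)            for t <= tp,
            sum(Ai · e^(−Li (t−tp)))  for t > tp,

with defaults tp = 1.5 min, A = (20, 8, 3) kBq/mL, L = (4.0, 0.5, 0.02)
1/min — a fast distribution phase, an intermediate clearance phase, and a
slow terminal phase, continuous at the peak by construction. The parent
fraction follows a Hill function

    f(t) = 1 − a·t^b / (t^b + c),

defaults a = 0.55, b = 1.0, c = 6.6, chosen so that f(60) = 0.5045, i.e.
about half the plasma activity is unchanged tracer at 60 min — the one
quantitative anchor available for the metabolite model. Measured *total*
plasma is modelled as parent/f(t), so the analysis pipeline faces a realistic
model mismatch: it fits the rise/tri-exponential model to total plasma, fits
the Hill model to parent-fraction samples, and multiplies the two
(`ArterialInputModel`).

Fitting choices:

* `fit_plasma_triexp` pins the peak at the maximal sample (exponential sums
  cannot represent the rise), then solves amplitudes by non-negative least
  squares inside a seeded multi-start Nelder–Mead search over log decay rates
  (variable projection). Unweighted residuals are the default; a
  `weighted=True` flag divides residuals by max(sample, peak/100), which
  Monte-Carlo checks show roughly halves late-time relative error at 3 %
  sample noise.
* `fit_parent_hill` is a box-bounded least-squares fit started from three
  fixed points to avoid a local optimum in the no-metabolism limit.

## Logan quantification

* Arterial route: OLS of ∫C_T/C_T on ∫C_p/C_T for frames with midpoint
  ≥ t*; the slope is Vt.
* Reference route: OLS of ∫C_T/C_T on [∫C_ref + C_ref(t)/k2′]/C_T; the
  slope is DVR, BPnd = DVR − 1. BPnd = DVR − 1 holds *identically* in the
  returned object (BPnd is a property computed from DVR).

Defaults and rationale:

* **t\* = 20 min.** For the default kinetic parameters the Logan plot is
  linear well before 20 min; estimates change by < 1 % when t* varies over
  15–30 min (tested).
* **k2′ = 0.25 /min fallback.** Equal to the generator's reference-region
  k2, making the default self-consistent; the pipeline normally *estimates*
  k2′ as the across-subject mean of profiled one-tissue cerebellar fits on
  the arterially sampled subjects (recovered within 2 % noiselessly).
  Sensitivity is weak: ±50 % in k2′ moves BPnd by < 5 % (tested).
* Tissue integrals use the trapezoid rule on frame midpoints anchored at
  (0, 0); the input's running integral is evaluated from its analytic model
  when one is attached to the curve, otherwise from sample interpolation.
* A transient-equilibration caveat: for very slow kinetics (terminal
  eigenvalue ≪ 1/scan length) the terminal Logan segment is still curved at
  60 min and Vt is underestimated. The test suite demonstrates this
  regime explicitly against an ODE oracle rather than hiding it; the
  generator's default rates (below) are chosen so the study's own schedule
  supports linear Logan fits.

## Synthetic-data generator

`tcm_for_bpnd(bpnd)` maps a target BPnd to 2TCM parameters K1 = 0.30,
k2 = 0.25, k4 = 0.15, k3 = bpnd·k4 (cerebellum: k3 = k4 = 0). With these
rates the slow eigenvalue is ≈ 0.067 /min, so tissue curves equilibrate
within the scan and noiseless Logan recovery is accurate to < 0.3 %.

The atlas is a 24 × 28 × 24 grid of 2 mm isotropic voxels (centred affine)
with axis-aligned box parcels for: cerebellum, medulla, five thalamic
subregions (AM, AL, CM, CL, P), left/right amygdala, left/right
hypothalamus, supraoptic nucleus, and a cortex slab. Regional BPnd means
encode the qualitative pattern thalamus > medulla ≈ amygdala ≈
hypothalamus > cortex > cerebellum (= 0), with a male > female shift
everywhere except the right hypothalamus (reversed).

Cohorts (`generate_cohort`, default 10 F / 11 M) draw each subject's
regional truth as Gaussian around the per-sex mean (SD 0.15, floored at
0.01). Linked trait scores are `trait = 50 + beta·(x − mu_x) + eps` where x
is the subject's (label-averaged) regional truth; beta and the noise SD are
set from the *population* predictor moments so the population R² equals the
link's target — for multi-label regions the predictor variance is shrunk by
label averaging, and pooled-sex links add the between-sex mean-shift
variance. Default links: aggression score ↔ left amygdala (positive,
target R² 0.83, females) and cooperativeness ↔ pooled thalamus (negative,
target R² 0.71, all subjects). Calibration is verified against a
bivariate-normal Monte-Carlo oracle.

Frame noise is Gaussian with SD proportional to sqrt(activity/duration),
scaled so the *relative* SD at the last frame equals `noise_fraction`
(default 0.02) — the standard count-statistics-motivated weighting shape.
Blood samples get proportional noise (default 3 %); parent-fraction samples
get one third of that, clipped to [0, 1].

**What the phantom does not emulate:** scanner point-spread function and
partial-volume effects, attenuation/scatter/randoms, motion, anatomical
variability (parcels are identical boxes across subjects), spatial noise
correlation, reconstruction artefacts, or radioactive-decay bookkeeping
(curves are decay-corrected by construction). Consequently voxel counts and
smoothness-dependent quantities (e.g. random-field thresholds) are not
comparable to real data — which is why FWE control is implemented by
max-statistic permutation rather than random-field theory.

## Group statistics

* **Sex differences**: per-region two-sample t-tests, Welch by default,
  two-tailed, reported male-minus-female.
* **VOI trait regressions**: OLS of trait on regional BPnd
  (`scipy.stats.linregress`); R² is the squared Pearson correlation.
* **Hormone check**: per-region OLS of BPnd on a plasma hormone level with
  Bonferroni correction; regions with < 3 quantifiable values are skipped
  with a warning.
* **Voxel-wise GLM**: per-voxel OLS of BPnd on an intercept plus one trait
  covariate; t = r·sqrt(df/(1 − r²)) with df = n − 2, converted to Z through
  the probability integral transform (t.sf → norm.isf), preserving two-tailed
  p exactly.
* **Small-volume FWE**: the covariate is permuted across subjects (seeded,
  identity permutation included, 1000 permutations minimum); each voxel's
  corrected p is the fraction of permutation maxima of |t| over the VOI at
  least as large as its observed |t|; rejection at corrected p ≤ alpha. This
  is the (b+1)/(m+1) estimator, exact under exchangeability; empirical FWER
  is verified at ≤ 0.05 over 500 null replicates in the acceptance suite.
* **Cluster-extent thresholding**: height threshold at the one-sided
  critical t for P < 0.001, applied separately per sign (the convention of
  standard mapping software); connected components with 6-connectivity;
  clusters below 80 mm³ (10 voxels at 2 mm, i.e. k ≥ 10) are discarded. The
  extent comparison carries a 1e-9 relative tolerance because
  10 × det(2 mm affine) evaluates to 79.999… in floating point.
* **Sub-threshold coincidence**: clusters from different traits whose peak
  coordinates agree within a tolerance radius are grouped and reported with
  each trait's direction and peak Z.

## Numerical choices

* All stochastic code takes explicit integer seeds (`numpy.random.
  default_rng`); pipelines derive stage seeds from one master seed, so every
  artefact is bit-reproducible given the config.
* Optimizers: Nelder–Mead over log rates (positivity by construction) with
  NNLS inner solves for the plasma fit; bounded scalar minimization for the
  profiled one-tissue k2 fit; `curve_fit` with box bounds for the Hill fit.
* The permutation engine computes all permuted t statistics as one
  (permutations × voxels) matrix product, which keeps the 500 × 1000
  acceptance simulation in seconds on one CPU.
* NIfTI I/O via nibabel with a JSON sidecar carrying the frame schedule
  (NIfTI itself has no frame-timing slot); atlases carry a JSON label-name
  sidecar.

## Limitations

* Box parcels and spatially independent voxel noise make the voxel-wise
  analyses easier than on real data in some respects (no smoothing-induced
  correlation) and harder in others (no signal blur into neighbours);
  whole-brain cluster detection at n = 21 is genuinely underpowered for
  links defined on pooled-region means, because a single voxel shares only
  part of the pooled predictor's variance — the default-analysis outcome
  (strong VOI-level R², sub-threshold voxel peaks in the linked region) is
  reported as such rather than tuned away.
* The Logan estimators inherit the method's known noise-dependent negative
  bias (demonstrated, not corrected); likewise the transient
  underestimation for very slow kinetics.
* The metabolite model is shared across subjects up to sample noise; no
  subject-level metabolism differences are simulated.
* Trait scores are unbounded Gaussians, not bounded questionnaire sums.
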