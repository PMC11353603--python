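# Methods

`microtract` re-creates, on synthetic data with known ground truth, the
analysis chain used to study corpus-callosum microstructure in cerebral small
vessel disease: multi-shell diffusion-weighted MRI is fitted with five model
families (DTI, DKI, WMTI, MC-SMT, NODDI), the resulting scalar maps are
profiled along a callosal-like fiber bundle at 100 points, the central
segment (points 40–60) is reduced to one value per subject and metric, and a
cohort layer runs the group tests, correlations, and ROC/AUC evaluation used
to rank the metrics as cognitive-impairment biomarkers.

## Acquisition model

The simulated acquisition follows the clinical protocol: shells at
b = 0, 1000, 2500 s/mm² with 64 gradient directions per nonzero shell and
2 mm isotropic voxels. Directions come from a spherical Fibonacci lattice —
deterministic given the count, near-uniform, minimal pairwise angle > 10° at
n = 64 — and the same direction set is reused on both shells. b-vectors are
interpreted in the image frame (the scanner-frame alternative is not
distinguishable from synthetic data, and the whole pipeline is
rotation-equivariant, which the tests assert).

## Generative substrate

White matter voxels are simulated as

    S/S0 = f_intra · ⟨E_stick⟩_W + f_extra · ⟨E_zeppelin⟩_W + f_iso · e^(−b·d_iso)

with `E_stick = exp(−b λ∥ (g·u)²)` and an axially symmetric zeppelin whose
radial diffusivity follows the tortuosity rule
`λ⊥ = λ∥ · (1 − f_intra/(f_intra + f_extra))`. ⟨·⟩_W averages fiber
orientation u over a Watson distribution with concentration κ, evaluated by a
deterministic 300-point Fibonacci quadrature with per-point Watson weights
renormalized to sum to one (error < 1e-4 against a 20,000-point reference;
seeded Monte Carlo inside the signal model is deliberately avoided).
Defaults: λ∥ = 2.0e-3 mm²/s, d_iso = 3.0e-3 mm²/s, S0 = 1000, SNR 30 — 
conventional white-matter/CSF values; the source protocol reports no SNR, so
noise level is an explicit free parameter. Noise is Rician:
`√((S+σε₁)² + (σε₂)²)`, σ = S0/SNR.

Tying the generative zeppelin to the same tortuosity coupling that MC-SMT
and NODDI assume makes parameter recovery a well-posed test of the
estimation chain; it also means recovery tests cannot detect
model-mismatch bias that real tissue would introduce.

The bundle phantom places an arc-shaped centerline (a parasagittal arch
resembling the forceps minor) in a small grid; voxels within a radius get the
fiber substrate oriented along the local tangent, the rest get isotropic
background. Streamlines are jittered parallel copies of the centerline.
Ground-truth maps (f_intra, f_iso, ODI from κ, tortuosity diffusivities)
share the grid and affine of the signal exactly.

Cohort tables are simulated separately at the metric level: per-subject
central-segment values for the four grades (control, subjective CI, MCI,
dementia) drawn from a Gaussian copula (exchangeable correlation ρ = 0.3)
with normal marginals clipped to physical ranges, and a monotone per-grade
location shift whose sign encodes the expected disease direction
(anisotropy, kurtosis and density fall; diffusivity and free water rise).
Locations and scales are realistic callosal values, not a claim to reproduce
any specific clinical table.

## Estimators

**DTI** — two-pass weighted least squares on the log signal (OLS, then
weights = squared predicted signal), using only b ≤ 1000 s/mm² volumes: the
mono-exponential representation is invalid at b = 2500. FA/MD/AD/RD come from
the eigenvalues clipped at zero.

**DKI** — the same two-pass WLS jointly over the 6 tensor and 15 kurtosis
degrees of freedom on all shells, with the quartic coefficients fitted
linearly as MD²·W and rescaled afterwards. Apparent kurtosis
K(n) = MD²·W(n)/D(n)² is clamped to [0, 10] before scalarization. MK averages
K over a 256-direction lattice (numeric rather than the exact analytic form;
accurate to < 1e-3), AK evaluates K along the principal eigenvector, RK
averages 64 equally spaced perpendicular directions; near-degenerate tensors
(λ1 ≈ λ2) break the tie toward the eigenvector with the largest |z|.

**WMTI** — from the kurtosis fit: AWF = max_n K(n)/(K(n)+3); the directional
extra-axonal diffusivity De(n) = D(n)·[1 + √(K(n)·AWF/(3(1−AWF)))] is
tensor-fitted, giving axEAD (largest eigenvalue) and radEAD (mean of the
rest). The extra-axonal branch (De > Da) is the one exposed; the intra-axonal
diffusivity is computable from the same quantities but is not a headline
metric. Voxels with non-positive maximal kurtosis or AWF ≥ 0.999 are flagged.

**MC-SMT** — per-shell spherical means (mean of S/S0 over each shell's
directions; S0 = mean of b = 0 volumes) are fitted with the two-compartment
kernel stick + tortuosity zeppelin using the closed-form orientation averages
(√π·erf(√bλ)/(2√bλ) and its zeppelin generalization). Bounded nonlinear least
squares over INTRA ∈ [0,1], λ ∈ [1e-4, 3.05e-3] mm²/s, seeded by an 11×11
grid; EMD = λ(3−2·INTRA)/3 and ETR = λ(1−INTRA) follow. The spherical mean is
invariant to the orientation distribution, which the tests verify across
κ ∈ {0, 1, 4, 16, ∞} to < 1e-3.

**NODDI** — Watson stick + tortuosity zeppelin + isotropic ball with the
model's canonical fixed diffusivities (λ∥ = 1.7e-3, d_iso = 3.0e-3 mm²/s) and
the mean orientation pinned to the principal DTI eigenvector. (NDI, ODI, ISO)
are found by an exhaustive 21×21×11 grid, then bounded trust-region
refinement of the best cell (accepted only if it does not worsen the grid
optimum). ODI = (2/π)·arctan(1/κ). The Watson quadrature is the same
300-point rule as the generator, but its normalization is independently
checked against dense integration in the tests to guard against a shared
bug cancelling out.

Optimizer settings everywhere: sum-of-squares tolerance 1e-10, 500
evaluation cap; failures fall back to the grid optimum and flag the voxel.

## Tractometry

Streamlines are resampled to 100 equidistant arc-length points (labelled
1..100; endpoints exact, linear interpolation between vertices), oriented
consistently by flipping any streamline whose far end is closer to a
reference start point (ties keep the stored order). Scalar maps are sampled
by trilinear interpolation in world mm; samples outside the volume or the
mask are missing and are excluded from per-point means rather than
zero-filled (zeros would bias profiles toward the mask edge). The central
segment is the mean of points 40–60 inclusive (21 points). The source
convention ("100 points, ends labelled 0 and 100") is internally
inconsistent; this package fixes 100 samples labelled 1..100, central range
40–60 inclusive, test range 5–95 inclusive, all configurable.

Group comparison is per-subject first (profiles are averaged within subject;
streamlines are never pooled across subjects, since subjects are the
exchangeable unit), then a rank-sum (two groups) or Kruskal–Wallis (more)
test at each point in 5–95 at α = 0.01 with no multiplicity correction —
mirroring the display convention of along-tract significance bands.
Contiguous significant points are reported as runs.

## Cohort statistics

Descriptives are median [Q25; Q75] with linear-interpolation quantiles.
Omnibus tests: Kruskal–Wallis with tie correction (χ² reference), one-way
ANOVA, Pearson χ² without continuity correction for categorical tables.
Post-hoc: Dunn's z on pooled ranks with tie correction and Bonferroni over
the six pairs — the common default of the clinical software workflow this
emulates; the original method is unnamed, so this is a documented choice.
Metric correlations are Spearman, pairwise-complete.

ROC: AUC by the Mann–Whitney concordant-pair formula with half-credit ties,
orientation auto-selected so AUC ≥ 0.5 and recorded (so that metrics that
decrease with disease are handled uniformly with those that increase); CI
and the test against AUC = 0.5 use DeLong's placement-value variance; the
Youden threshold maximizes sensitivity + specificity − 1 with ties toward
the lower threshold. The case class pools MCI ∪ dementia against controls;
subjective CI is excluded from the contrast. No multiplicity correction is
applied across the metric × tract AUC grid (a deliberate fidelity choice,
and a real statistical caveat).

## Problem sizes and numerical choices

The end-to-end demo defaults to a 20×20×10 voxel phantom, 20 streamlines and
12 + 12 subjects; tests and the acceptance script use 14×14×8 grids and
4–8 subjects, 500-voxel noise ensembles, and 10,000-replicate null
calibrations — sizes chosen so the whole suite runs in minutes on one CPU
while keeping Monte-Carlo error well inside the asserted tolerances. All
randomness flows from explicit integer seeds; rerunning any stage with the
same seed is byte-identical.

## Known limitations

* **Cumulant truncation at clinical b-values.** The quadratic (kurtosis)
  signal representation truncates a bi- or multi-exponential decay. At the
  clinical shells (1000, 2500 s/mm²) this attenuates fitted kurtosis
  substantially — e.g. the 50/50 (0.5, 2.5)×10⁻³ mm²/s isotropic mixture
  whose exact cumulant kurtosis is 4/3 fits to 0.73 at those shells, and to
  1.32 at shells (80, 200) where the truncation is negligible. Consequently
  kurtosis-derived AWF is biased low in dense coherent bundles (≈ −0.06 at
  f_intra = 0.5, ≈ −0.07 at 0.65, < 0.03 below 0.4, exact algebra). The
  tests therefore verify the estimator chain in the cumulant-valid regime
  and bound the clinical-shell bias explicitly, instead of pretending it
  away. This bias is a property of kurtosis-based AWF in general, not of
  this implementation.
* The generator and the biophysical estimators share the tortuosity
  assumption; passing recovery tests demonstrates correctness of the
  chain, not robustness to tissue that violates the assumption (exchange,
  axon-diameter effects, crossing fibers are all absent).
* Rician bias is simulated but not corrected; at SNR 30 its effect on the
  MC-SMT fraction is within the asserted median error of 0.05.
* The cohort simulator draws metrics from a copula rather than from the
  imaging pipeline; only the end-to-end demo ties metric values to actual
  fitted phantoms, at small n.
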