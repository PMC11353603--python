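# microtract

Multi-shell diffusion MRI microstructure modelling, along-tract
corpus-callosum profiling, and cohort statistics — exercised end-to-end on
synthetic phantoms with known ground truth.

## What it is for

Studies of cerebral small vessel disease and vascular cognitive impairment
rank diffusion-derived microstructure metrics of the corpus callosum
(forceps minor, body, forceps major) as candidate biomarkers: per-subject
tract profiles are reduced to a central-segment value, groups graded by
cognitive impairment are compared, and each metric's discriminative power is
scored by ROC analysis. `microtract` implements that full chain for
researchers who want a tested, reproducible reference implementation —
and, since clinical diffusion data are rarely shareable, ships a synthetic
data generator so every stage can be validated against known truth.

Five model families produce 16 scalar metrics:

| family | metrics | estimator |
|---|---|---|
| DTI | FA, MD, AD, RD | two-pass WLS log-linear fit, b ≤ 1000 s/mm² |
| DKI | MK, AK, RK | joint WLS over (D, W), K(n) = MD²·W(n)/D(n)² |
| WMTI | AWF, axEAD, radEAD | AWF = max K(n)/(K(n)+3); extra-axonal tensor |
| MC-SMT | INTRA, EMD, ETR | two-compartment fit of per-shell spherical means |
| NODDI | NDI, ODI, ISO | Watson stick + zeppelin + ball, grid + refinement |

Tractometry resamples each streamline to 100 equidistant points, samples any
scalar map by trilinear interpolation, averages over streamlines, and takes
the mean of points 40–60 as the central-segment value. The statistics layer
provides Me[Q25; Q75] descriptives, Kruskal–Wallis/ANOVA/χ² with Dunn–
Bonferroni post-hocs, Spearman correlation matrices, pointwise along-tract
tests (points 5–95, α = 0.01), and ROC/AUC with DeLong confidence intervals
and Youden thresholds for the MCI ∪ dementia vs control contrast.

## Worked example

Simulate a noise-free white-matter voxel (65% sticks, dispersed with Watson
κ = 4, λ∥ = 2.2 μm²/ms) on the clinical three-shell scheme and recover its
intra-axonal fraction with MC-SMT:

```python
import numpy as np
from microtract.phantom import make_scheme, substrate_signal, CompartmentSubstrate
from microtract.io import DWIDataset
from microtract.biophysical import spherical_mean, fit_mcsmt

scheme = make_scheme(64, (1000, 2500), 1)        # 129 volumes
sub = CompartmentSubstrate(f_intra=0.65, lambda_par=2.2e-3, kappa=4.0)
dwi = DWIDataset(substrate_signal(sub, scheme)[None, None, None] * 1000, np.eye(4))
shell_b, means, _ = spherical_mean(dwi, scheme)
intra, lam, _ = fit_mcsmt(means, shell_b)
print(f"spherical means: {means[0].round(4)}")
print(f"INTRA = {intra[0]:.4f}   lambda = {lam[0]:.3e} mm^2/s")
```

prints

```
spherical means: [0.4836 0.2692]
INTRA = 0.6500   lambda = 2.200e-03 mm^2/s
```

— the shell means are the orientation-invariant signal signature, and the
fit recovers the ground-truth fraction (0.65) and intrinsic diffusivity
(2.2e-3) to four digits, because on tortuosity-consistent substrates the
two-shell spherical mean identifies the model exactly.

The full pipeline — a cohort of phantom subjects, all five model fits, tract
profiles, central segments, group tests and the AUC table — runs as

```sh
microtract demo --out-dir demo_out --seed 0
```

and writes `cohort.csv`, `descriptives.csv`, `group_tests.csv`,
`correlations.csv`, `auc_table.csv` and a `manifest.json` with per-stage
timings. The other subcommands (`simulate-phantom`, `simulate-cohort`,
`fit-models`, `profile`, `cohort-stats`) expose the individual stages on
NIfTI/bval/bvec, TCK/TRK and CSV files.

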