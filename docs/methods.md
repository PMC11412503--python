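# Methods

This note records the models, conventions and design choices behind
`myot2`, in the spirit of a methods section: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Signal model and T2 fitting

Each voxel of a multi-slice multi-echo spin-echo (MSME) acquisition is
modelled as a monoexponential decay across the echo train,

    S(TE) = S0 * exp(-TE / T2),

with S0 the fully recovered signal and T2 the transverse relaxation
time in milliseconds. No multi-exponential components, stimulated-echo
(EPG) corrections, B1 inhomogeneity or fat–water separation are
modelled; the fitted quantity is an *apparent* T2 under this model.

Two estimators:

* **`nls` (default).** Least squares on the linear intensity scale.
  S0 enters linearly, so for any candidate T2 the optimal amplitude is
  closed-form: with e_k = exp(-TE_k/T2), S0(T2) = Σ S_k e_k / Σ e_k².
  The remaining 1-D problem in T2 is solved on the bounds [1, 1000] ms
  by a coarse log-spaced grid (64 points) that brackets the optimum,
  followed by a vectorized golden-section refinement (64 iterations,
  shrinking each voxel's bracket below 1e-12 relative width). The
  log-linear solution is evaluated as a second candidate and kept when
  its residual sum of squares is lower — on noise-free decays it is
  exact to machine precision, below the floating-point plateau any
  RSS-based search bottoms out on. All voxels are processed as batched
  array operations, which is what makes cohort-scale simulation studies
  cheap.
* **`loglinear`.** Ordinary least squares of ln S on TE over strictly
  positive samples. Used for initialization/cross-checking; at low SNR
  the Rician noise floor lifts the tail of ln S and biases it upward,
  severely so for short T2 (the package's tests quantify this).
* **`nls_offset`.** An off-by-default variant adding a constant floor,
  S0·exp(-TE/T2) + C, fit per voxel with scipy. The default model is
  deliberately the strict monoexponential; the offset variant exists
  for sensitivity analyses.

Fit-quality and failure handling: per-voxel R² on the linear scale;
voxels with fewer than three usable echoes, non-decaying signals, or a
fitted T2 touching a bound are *flagged invalid*, never clipped — a
clipped boundary value would silently distort the distribution tails
that the biomarkers exist to measure. An all-invalid map raises.

The first echo can optionally be dropped (`drop_first_echo`), a common
guard against stimulated-echo contamination; it is off by default and
makes no difference on phantom data.

## Distribution biomarkers

From a fitted map and mask, muscle T2 values are collected from valid
voxels on non-excluded slices, then trimmed to the closed band between
the 1st and 99th percentiles before *any* statistic is computed.
Metrics:

* **IDR** = P90 − P10, a robust spread measure that responds to the
  magnitude of the highest retained T2 values;
* **mode**: argmax of a Gaussian KDE with Silverman bandwidth on a
  512-point grid spanning [min, max], refined by local quadratic
  interpolation, ties broken toward the smaller T2;
* **Pearson mode skewness** = (mean − mode)/sd, dimensionless, with the
  n−1 sample standard deviation;
* **D'Agostino K²** omnibus normality test (skewness + kurtosis
  z-statistics, χ² with 2 df), requiring n ≥ 20.

Conventions matter here and none is canonical, so they are fixed and
recorded in each summary's provenance block: percentiles use linear
interpolation between order statistics (NumPy's "linear", the type-7
rule); trimming keeps values equal to the bounds; the realized KDE
bandwidth is reported because the mode — hence the skew — depends on
it. Note that under this convention trimming is *not* idempotent: a
second pass removes up to another ~2% of a continuous sample, because
the percentile bounds are recomputed on the trimmed data. Degenerate
inputs degrade gracefully: a zero-spread sample has IDR 0, mode equal
to the common value, and NaN skew/normality (flagged, with warnings)
rather than an exception, so a healthy noise-free phantom still yields
a summary row.

Known behaviour of the skew sign: for a perfectly symmetric sample the
KDE-mode skew fluctuates around 0 (|skew| < 0.05 at n = 10⁵); slight
negative values on healthy noisy phantoms are sampling noise, not a
pathology signal.

## Phantom generator

The generator emulates the statistical structure the analysis assumes,
at the acquisition geometry of a typical 9.4 T mouse-hindlimb protocol
(defaults: TR 4000 ms, 30 echoes at 9 ms spacing from TE = 9 ms,
256×256 matrix, 3.5×3.5 cm FOV, 5 × 1 mm axial slices; tests and the
acceptance script run reduced 64×64 matrices with 1–2 slices, which
preserves every distributional property at ~1/16 the voxel count).

Anatomy per slice: two elliptical muscle "legs" (size wobbling a few
percent slice to slice), each with a small low-signal bone core, a thin
bright fat/skin rim of T2 140 ms just outside each leg, and an optional
bladder blob at T2 250 ms. Rim, bladder and bone are *confounders*:
outside the true muscle mask, present to exercise masking and
auto-segmentation.

Tissue T2 values default to 25 ms (healthy), 35 ms (diffuse mild
elevation) and 65 ms (focal edema/necrosis). These are plausible
mouse-muscle values chosen to reproduce the qualitative histogram
shapes of dystrophic disease — sharp healthy peak, broad mild shoulder,
distinct high-T2 tail — not tissue measurements; real studies should
calibrate them. A `severity` knob in [0, 1] sets the areal fractions of
mild and focal lesion tissue linearly (defaults 0.35·s and 0.12·s;
any nondecreasing map with f(0) = 0 may be supplied). Lesion geometry:
a per-slice smoothed Gaussian random field is thresholded at the
quantiles matching the target fractions, giving smooth random blobs
with focal cores nested inside mild surrounds. The T2 *values* remain
discrete per class, so the ground-truth lesion burden is exact up to
voxel rounding and recovery tests can count voxels; the cost is that
tissue boundaries have no partial-volume gradient (see limitations).

Noise is Rician: independent Gaussian channels added to the noise-free
signal before taking the magnitude. SNR is referenced to the
first-echo signal of healthy muscle (channel sd =
s0·exp(−TE₁/T2_healthy)/snr), the image where SNR is conventionally
quoted; `snr=inf` disables noise. Background voxels therefore carry the
Rayleigh floor σ√(π/2), and fitted T2 medians at SNR 50 sit ~1–2%
above truth — the unavoidable magnitude-bias of a strictly
monoexponential fit, quantified in the acceptance outputs.

Reproducibility: anatomy, lesions, noise and cohort draws derive from
the spec seed through independent named substreams, so a test–retest
pair shares anatomy and T2 field while drawing fresh noise, and an
identical (spec, acq, seed) triple is bit-identical.

Cohorts: group sizes and per-genotype uniform severity ranges (defaults
WT fixed 0; mdxB10 spanning 0.1–0.8, the hallmark inter-animal spread
of that model; mdxD2 0.7–1.0). Each animal also receives a simulated
Evans-blue dye surrogate, dye = intercept + slope·burden + N(0, sd)
clipped at zero (defaults 0.05 + 2·burden, sd 0.05 — noise ~5% of the
dye range), standing in for the terminal membrane-permeability assay.

What the phantoms do **not** emulate — and therefore what passing tests
do not establish about real scans: partial-volume boundaries,
respiratory ghosting (slice exclusion is exercised via the API instead),
B1/stimulated-echo effects, k-space artifacts, intramuscular fat
infiltration, registration error between sessions, or biological drift
between retests. Phantom repeatability isolates measurement noise only,
so synthetic MDC values are optimistic relative to live animals.

## Masking and auto-segmentation

Masks are binary NIfTI volumes sharing the stack's grid (0-based
indices, slice = third axis, no resampling); any nonzero voxel counts
as muscle, with a warning for values outside {0, 1}. Per-slice
exclusion uses set semantics and composes monotonically. The paper-free
auto-mask for phantoms is deliberately simple: Otsu threshold on the
first echo, a voxelwise quick-T2 screen (log-linear on the first 8
echoes; reject > 100 ms) that removes the fat rim and bladder, then
per-slice morphological opening/closing and small-component removal.
It is plumbing for synthetic end-to-end runs (Jaccard ≈ 0.97 against
phantom ground truth), not a segmentation method for real data —
externally produced masks are ingested as files. Which slices carry
"significant" artifact on real data is a user decision, recorded in
provenance, not an algorithm.

## Cohort statistics

* **Bland–Altman / MDC.** Differences are session2 − session1; limits
  of agreement bias ± 1.96·sd; MDC = 1.96·sd_diff with the n−1 sd
  (equivalently 1.96·√2·SEM with SEM = sd_diff/√2; the alternative
  2.77·SEM convention differs only in quoting 1.96·√2 ≈ 2.77
  explicitly). mdc_pct is relative to the grand mean of all 2n
  measurements.
* **Regression.** Dye uptake is regressed on the image metric (metric
  as predictor); R² is symmetric in the choice, so the headline
  statistic does not depend on the direction. In the synthetic cohorts
  the dye is linear in lesion *burden*; the IDR responds to burden as a
  staircase (P90 jumps between tissue classes), so dye–IDR linearity is
  weaker than dye–skew or dye–burden — visible in the acceptance
  outputs, and an honest reminder that R² against a nonlinearly related
  metric is bounded by the metric, not the noise.
* **Stratification.** The composite severity score is the rank-sum of
  the IDR rank and the skew rank: no training data, monotone in both
  metrics, invariant to any increasing rescaling of either. Group
  summaries report median and IQR per genotype.
* **Balancing.** Animals are dealt into groups serpentine-wise
  (1..k, k..1, …) along the severity ranking, optionally excluding
  animals whose rank percentile (rank − 0.5)/n falls outside a given
  band — the a-priori exclusion of extreme phenotypes.
* **Separability.** Two cohorts are called separable in the (skew, IDR)
  plane when a linear program finds a strictly separating line
  (equivalent to disjoint convex hulls).

## Pipeline and provenance

A run is a single serializable config (JSON/YAML); its SHA-256 hash is
embedded in every output JSON/CSV, and identical config + seed
reproduces every numeric output bit for bit (logs, which carry timings,
are the only exception). Stages — simulate, mask, fit, metrics, cohort
— log counts and timings and fail with stage-named errors; the CLI maps
error classes to exit codes (2 config, 3 data, 4 numerical).

## Numerical choices, collected

| Choice | Value | Why |
| --- | --- | --- |
| T2 bounds | [1, 1000] ms | physiological range with margin; bound hits flagged invalid |
| NLS search | 64-pt log grid + 64 golden-section iters | global bracket, machine-precision refinement, fully vectorized |
| Percentiles | linear interpolation (type 7) | NumPy default; recorded in provenance |
| Trim band | closed [P1, P99] | ties at the bound are kept |
| KDE | Gaussian, Silverman, 512-pt grid, quadratic peak refinement | standard defaults; bandwidth recorded |
| sd | n−1 denominator | sample statistic |
| MDC | 1.96·sd_diff | see above |
| Noise sd | s0·exp(−TE₁/T2_healthy)/snr | SNR referenced to the first-echo image |
| Problem sizes | 64×64, 1–2 slices, 10⁴-voxel Monte-Carlo batches, 20-seed severity sweeps, 500-cohort regression sweeps | desk-scale sizes at which every property is already stable |

## Limitations

Beyond the phantom realism caveats above: the apparent-T2 model ignores
multi-compartment relaxation, so absolute T2 values are
protocol-dependent; the KDE mode (hence the skew) depends on bandwidth,
which is why it is recorded and why cross-study comparisons should fix
it; the trimming convention is not idempotent by construction; and no
texture/radiomics or per-muscle sub-ROI analysis is attempted — the
biomarkers summarize the global distribution of one animal.
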