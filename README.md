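# myot2 — muscle T2-distribution biomarkers for dystrophic-mouse MRI

Quantitative T2 mapping is the workhorse readout for muscle disease in
mouse models of Duchenne muscular dystrophy: damaged, inflamed or
necrotic muscle holds more free water, so its transverse relaxation time
T2 rises. But mdx-model pathology is notoriously patchy — one littermate
can be nearly clean while another is riddled with lesions — so the *mean*
muscle T2 averages small hot regions into a large unchanged background
and stratifies animals poorly. `myot2` implements the alternative: treat
the full distribution of muscle T2 values as the object of interest, and
summarize its *shape*.

The package is a library plus a thin CLI for:

* **Voxelwise T2 fitting.** Multi-slice multi-echo spin-echo stacks are
  fit per voxel with the monoexponential model

  $$S(\mathrm{TE}) = S_0\, e^{-\mathrm{TE}/T_2}$$

  by bounded nonlinear least squares ($T_2 \in [1, 1000]$ ms, $S_0 > 0$,
  $S_0$ profiled out in closed form), with a log-linear variant for
  comparison.

* **Distribution biomarkers.** Muscle T2 values (masked, per-slice
  exclusions honoured, trimmed to the central 98%) are summarized by the
  interdecile range $\mathrm{IDR} = P_{90} - P_{10}$ (spread; sensitive
  to high-T2 tails), the kernel-density-estimate mode, the Pearson mode
  skewness $(\text{mean} - \text{mode})/\text{sd}$ (asymmetry), and
  D'Agostino's $K^2$ normality test.

* **Cohort statistics.** Bland–Altman test–retest analysis with minimum
  detectable change $\mathrm{MDC} = 1.96\,\mathrm{sd}(\Delta)$, simple
  linear regression of an external damage assay (Evans-blue dye uptake)
  on the image metrics, composite (IDR, skew) severity ranking, and
  serpentine assignment into severity-balanced treatment groups.

* **Synthetic phantoms.** A generator of dystrophic-hindlimb phantoms
  with exact ground truth (per-voxel T2 field, muscle mask, lesion
  burden): two muscle "legs" with bone cores, a high-T2 fat rim and a
  bladder blob as confounders, smooth random lesion blobs whose areal
  fraction is driven by a severity knob, Rician noise, and simulated
  test–retest sessions and multi-genotype cohorts. Every stage of the
  pipeline is validated against these known truths.

T2 is in milliseconds throughout. Masks are binary NIfTI volumes on the
stack's voxel grid; real segmentations (manual or model-based) are
ingested as files, and a simple Otsu/morphology auto-mask is provided so
phantom pipelines run end to end without one.

## Worked example

`examples/03_distribution_metrics.py` fits severity 0/0.3/0.6/0.9
phantoms at SNR 50 and prints their distribution metrics:

```
severity     n   mode   mean    IDR   skew    p(K2)
     0.0  1583   25.5   25.5   1.92 -0.023    4e-05
     0.3  1583   25.5   27.6  10.57  0.308 7.4e-304
     0.6  1583   25.5   30.1  11.61  0.465 6.9e-192
     0.9  1583   25.6   32.7  13.14  0.607 2.2e-128
```

The mode stays pinned at healthy muscle T2 (~25 ms) regardless of
severity — most voxels remain normal — while the IDR widens and the
Pearson skew grows as elevated-T2 tissue accumulates in the right tail.
The $K^2$ p-values collapse as soon as lesions appear: these
distributions are nowhere near Gaussian, which is exactly why mean ± sd
is the wrong summary. The other examples cover phantom generation, map
fitting, test–retest repeatability (`MDC(IDR) = 0.373 ms (3.7% of the
mean IDR)` against severity-driven IDR differences of ~10 ms) and the
full cohort workflow.

The same stages are scriptable from a shell:

```sh
myot2 simulate --severity 0.6 --seed 7 -o out/
myot2 metrics out/stack.nii --mask-path out/mask_true.nii -o out/metrics.json
```

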