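"""Distribution biomarkers: how disease severity reshapes the T2 histogram.

Healthy muscle gives a sharp 25 ms peak (small IDR, skew near 0).  Disease
adds diffusely elevated and focal high-T2 tissue: the interdecile range
(P90 - P10) widens and the Pearson mode skew (mean - mode)/sd grows with
the heavy right tail, while the mode stays pinned at healthy T2.
"""

from myot2 import AcquisitionParams, MuscleMask, PhantomSpec, fit_map, make_phantom, summarize

acq = AcquisitionParams(matrix_size=(64, 64), n_slices=2, fov_mm=(35.0, 35.0))

print(f"{'severity':>8} {'n':>5} {'mode':>6} {'mean':>6} {'IDR':>6} {'skew':>6} {'p(K2)':>8}")
for severity in (0.0, 0.3, 0.6, 0.9):
    stack, truth = make_phantom(PhantomSpec(seed=3, severity=severity, snr=50.0), acq)
    mask = MuscleMask(labels=truth.mask_true)
    d = summarize(fit_map(stack, mask), mask)  # trims to the central 98% first
    print(f"{severity:8.1f} {d.n_retained:5d} {d.mode_ms:6.1f} {d.mean_ms:6.1f} "
          f"{d.idr_ms:6.2f} {d.pearson_skew:6.3f} {d.normality_p:8.2g}")
# IDR and skew increase monotonically with severity; D'Agostino's K2 test
# rejects normality (tiny p) as soon as lesions appear, which is why mean
# and standard deviation alone summarize these distributions poorly.
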