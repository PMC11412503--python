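"""Test-retest repeatability: Bland-Altman analysis and minimum detectable change.

Each animal is 'scanned twice' — same anatomy and T2 field, independent
noise — and the IDR is measured in both sessions.  MDC = 1.96*sd(differences)
is the smallest IDR change distinguishable from measurement noise; it should
be far smaller than the IDR differences produced by disease severity.
"""

import numpy as np

from myot2 import (
    AcquisitionParams,
    MuscleMask,
    PhantomSpec,
    bland_altman,
    fit_map,
    make_retest_pair,
    summarize,
)

acq = AcquisitionParams(matrix_size=(64, 64), n_slices=1, fov_mm=(35.0, 35.0))

pairs = []
for i, severity in enumerate(np.linspace(0.2, 0.8, 6)):
    a, b, truth = make_retest_pair(
        PhantomSpec(seed=10 + i, severity=float(severity), snr=50.0),
        acq, seed_a=2 * i + 1, seed_b=2 * i + 2)
    mask = MuscleMask(labels=truth.mask_true)
    idr_a = summarize(fit_map(a, mask), mask).idr_ms
    idr_b = summarize(fit_map(b, mask), mask).idr_ms
    pairs.append((idr_a, idr_b))
    print(f"animal {i}: severity {severity:.2f}  IDR session1 {idr_a:6.2f}  "
          f"session2 {idr_b:6.2f} ms")

rep = bland_altman(pairs)
print(f"\nbias = {rep.bias:+.3f} ms, limits of agreement "
      f"[{rep.loa_low:+.3f}, {rep.loa_high:+.3f}] ms")
print(f"MDC(IDR) = {rep.mdc:.3f} ms ({rep.mdc_pct:.1f}% of the mean IDR)")
# An MDC well below 1 ms against severity-driven IDR differences of ~10 ms
# means the biomarker can track individual animals across sessions.
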