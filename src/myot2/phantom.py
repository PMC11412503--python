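"""Synthetic multi-echo hindlimb phantoms with known ground truth.

The generator emulates an axial multi-slice multi-echo spin-echo (MSME)
acquisition of a prone mouse hindlimb: two roughly elliptical "legs" of
muscle, each with a low-signal bone core, wrapped in a thin high-T2
skin/subcutaneous-fat rim, plus an optional very-high-T2 bladder blob.
Muscle pathology follows the dystrophic spectrum seen in mdx mice: a
``severity`` knob in [0, 1] controls the areal fractions of diffusely
(mildly) elevated-T2 tissue and of focal high-T2 lesions (edema/necrosis).

The forward model per voxel is the monoexponential decay

    S(TE) = S0 * exp(-TE / T2)

and noise is Rician: two independent Gaussian channels added before the
magnitude is taken, the standard model for magnitude spin-echo images.
SNR is defined at the first echo of healthy muscle — the channel noise
standard deviation is ``s0_muscle * exp(-TE_1 / t2_healthy_ms) / snr`` —
since the first, most proton-density-weighted image is where image SNR
is conventionally quoted.

Lesion geometry: a smoothed Gaussian random field is drawn per slice and
thresholded at the quantiles that yield the requested areal fractions, so
lesions are smooth random blobs while the ground-truth lesion burden is
exact up to voxel rounding.  High-T2 cores sit inside mildly elevated
surrounds, mimicking edema around focal damage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from ._exceptions import InvalidParameterError
from .cohort import CohortRecord
from .image_io import EchoStack, MuscleMask

__all__ = [
    "AcquisitionParams",
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "make_phantom",
    "make_cohort",
    "make_retest_pair",
]

# non-muscle tissue constants (ms / fraction of s0_muscle)
_T2_BONE_MS = 8.0
_S0_BONE = 0.02
_T2_FAT_MS = 140.0
_S0_FAT = 0.9
_T2_BLADDER_MS = 250.0
_S0_BLADDER = 1.1
_RIM_WIDTH = 0.08  # rim outer edge, in units of the leg's normalized radius


def _default_mild_fraction(severity: float) -> float:
    """Areal fraction of muscle with diffuse mild T2 elevation (linear in severity)."""
    return 0.35 * severity


def _default_high_fraction(severity: float) -> float:
    """Areal fraction of muscle with focal high-T2 lesions (linear in severity)."""
    return 0.12 * severity


@dataclass(frozen=True)
class AcquisitionParams:
    """MSME acquisition geometry and timing.

    Defaults reproduce a 9.4 T mouse-hindlimb protocol: TR 4000 ms,
    30 echoes at 9 ms spacing starting at TE = 9 ms, 256x256 matrix,
    3.5x3.5 cm field of view, 5 axial slices of 1 mm.
    """

    tr_ms: float = 4000.0
    echo_times_ms: np.ndarray = field(default_factory=lambda: 9.0 * np.arange(1, 31))
    matrix_size: tuple[int, int] = (256, 256)
    n_slices: int = 5
    slice_thickness_mm: float = 1.0
    fov_mm: tuple[float, float] = (35.0, 35.0)

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=np.float64)
        if te.ndim != 1 or te.size == 0:
            raise InvalidParameterError("echo_times_ms must be a nonempty vector")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise InvalidParameterError("echo times must be positive and strictly increasing")
        if self.tr_ms <= 0 or self.slice_thickness_mm <= 0:
            raise InvalidParameterError("tr_ms and slice_thickness_mm must be positive")
        rows, cols = self.matrix_size
        if rows < 8 or cols < 8 or self.n_slices < 1:
            raise InvalidParameterError("matrix must be at least 8x8 with >= 1 slice")
        if min(self.fov_mm) <= 0:
            raise InvalidParameterError("fov_mm entries must be positive")
        object.__setattr__(self, "echo_times_ms", te)

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        rows, cols = self.matrix_size
        return (self.fov_mm[0] / rows, self.fov_mm[1] / cols, self.slice_thickness_mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue model and noise settings for one synthetic animal.

    ``severity`` in [0, 1] drives both lesion fractions through
    ``lesion_fraction_mild`` / ``lesion_fraction_high`` (linear maps by
    default; any nondecreasing function with f(0) = 0 may be supplied).
    ``snr`` may be ``math.inf`` to disable noise entirely.
    """

    seed: int = 0
    severity: float = 0.0
    t2_healthy_ms: float = 25.0
    t2_lesion_mild_ms: float = 35.0
    t2_lesion_high_ms: float = 65.0
    lesion_fraction_mild: Callable[[float], float] = _default_mild_fraction
    lesion_fraction_high: Callable[[float], float] = _default_high_fraction
    s0_muscle: float = 1000.0
    snr: float = 50.0
    include_confounders: bool = True
    left_right_imbalance: float = 0.0
    lesion_smoothness_mm: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise InvalidParameterError("severity must lie in [0, 1]")
        if not (self.t2_healthy_ms < self.t2_lesion_mild_ms < self.t2_lesion_high_ms):
            raise InvalidParameterError("tissue T2 values must satisfy healthy < mild < high")
        if self.t2_healthy_ms <= 0:
            raise InvalidParameterError("t2_healthy_ms must be positive")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive (use math.inf for noiseless)")
        if self.s0_muscle <= 0:
            raise InvalidParameterError("s0_muscle must be positive")
        if not -1.0 <= self.left_right_imbalance <= 1.0:
            raise InvalidParameterError("left_right_imbalance must lie in [-1, 1]")
        for name in ("lesion_fraction_mild", "lesion_fraction_high"):
            f = getattr(self, name)
            grid = [f(s) for s in (0.0, 0.25, 0.5, 0.75, 1.0)]
            if abs(grid[0]) > 1e-12:
                raise InvalidParameterError(f"{name}(0) must be 0 (severity 0 has no lesions)")
            if any(not 0.0 <= v <= 1.0 for v in grid) or any(
                b < a - 1e-12 for a, b in zip(grid, grid[1:])
            ):
                raise InvalidParameterError(f"{name} must be nondecreasing with values in [0, 1]")
        if self.lesion_fraction_mild(1.0) + self.lesion_fraction_high(1.0) > 1.0:
            raise InvalidParameterError("lesion fractions must sum to at most 1 at severity 1")

    def noise_sigma(self, acq: "AcquisitionParams") -> float:
        """Gaussian channel noise sd implied by ``snr`` (0 when noiseless)."""
        if not math.isfinite(self.snr):
            return 0.0
        te1 = float(np.asarray(acq.echo_times_ms)[0])
        return self.s0_muscle * math.exp(-te1 / self.t2_healthy_ms) / self.snr


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel truth emitted alongside each phantom, for recovery tests."""

    t2_field_ms: np.ndarray  # 0 outside tissue
    mask_true: np.ndarray  # boolean muscle indicator
    lesion_burden: float  # fraction of muscle voxels with T2 above healthy
    severity: float

    @staticmethod
    def _burden(t2_field_ms: np.ndarray, mask_true: np.ndarray, t2_healthy_ms: float) -> float:
        n = int(mask_true.sum())
        if n == 0:
            return 0.0
        return float((t2_field_ms[mask_true] > t2_healthy_ms).sum() / n)


@dataclass(frozen=True)
class CohortSpec:
    """A multi-genotype study: group sizes, severity spreads and a dye model.

    ``severity_distributions`` maps genotype to a (low, high) uniform range.
    The defaults encode the usual phenotypes: wildtype fixed at 0, mdxB10
    spanning a wide spectrum (the hallmark inter-animal variability of that
    model), mdxD2 uniformly severe.  The simulated Evans-blue surrogate is
    ``dye = intercept + slope * lesion_burden + N(0, dye_noise_sd)``,
    clipped at zero, in arbitrary optical-density units per mg.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"WT": 5, "mdxB10": 4, "mdxD2": 3}
    )
    severity_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "WT": (0.0, 0.0),
            "mdxB10": (0.1, 0.8),
            "mdxD2": (0.7, 1.0),
        }
    )
    dye_slope: float = 2.0
    dye_intercept: float = 0.05
    dye_noise_sd: float = 0.05
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise InvalidParameterError("group sizes must be >= 0")
        if self.dye_noise_sd < 0:
            raise InvalidParameterError("dye_noise_sd must be >= 0")
        for g in self.n_per_group:
            if g not in self.severity_distributions:
                raise InvalidParameterError(f"no severity distribution for genotype {g!r}")
            lo, hi = self.severity_distributions[g]
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidParameterError(f"severity range for {g!r} must satisfy 0 <= lo <= hi <= 1")


def _ellipse(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float],
             axes: tuple[float, float]) -> np.ndarray:
    """Normalized squared radius of each voxel w.r.t. an ellipse (<= 1 is inside)."""
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2


def _anatomy(spec: PhantomSpec, acq: AcquisitionParams):
    """Rasterize the static anatomy: per-leg muscle, bone, rim, bladder.

    Returns (muscle_legs, bone, rim, bladder) boolean arrays of the full
    3-D grid; muscle_legs is a list [left, right].  Slice-to-slice leg size
    wobble is drawn from the geometry substream of the spec seed.
    """
    rows, cols = acq.matrix_size
    shape = (rows, cols, acq.n_slices)
    rr, cc = np.meshgrid(np.arange(rows) / rows, np.arange(cols) / cols, indexing="ij")
    geom_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))

    legs = [np.zeros(shape, dtype=bool), np.zeros(shape, dtype=bool)]
    bone = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    bladder = np.zeros(shape, dtype=bool)
    centers = [(0.60, 0.32), (0.60, 0.68)]
    base_axes = (0.21, 0.155)

    for s in range(acq.n_slices):
        wobble = 1.0 + 0.04 * geom_rng.standard_normal(2)
        for i, center in enumerate(centers):
            axes = (base_axes[0] * wobble[i], base_axes[1] * wobble[i])
            r2 = _ellipse(rr, cc, center, axes)
            inside = r2 <= 1.0
            legs[i][:, :, s] = inside
            rim[:, :, s] |= (r2 > 1.0) & (r2 <= (1.0 + _RIM_WIDTH) ** 2)
            bone[:, :, s] |= _ellipse(rr, cc, center, (0.030, 0.030)) <= 1.0
        bladder[:, :, s] = _ellipse(rr, cc, (0.22, 0.50), (0.065, 0.085)) <= 1.0

    for leg in legs:
        leg &= ~bone
    rim &= ~(legs[0] | legs[1]) & ~bladder
    return legs, bone, rim, bladder


def _lesion_labels(spec: PhantomSpec, acq: AcquisitionParams,
                   legs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Assign mild / high lesion voxels inside muscle by thresholding a
    smoothed Gaussian random field at the quantiles matching the target
    areal fractions.  High cores are nested inside mild surrounds."""
    f_mild = spec.lesion_fraction_mild(spec.severity)
    f_high = spec.lesion_fraction_high(spec.severity)
    shape = legs[0].shape
    mild = np.zeros(shape, dtype=bool)
    high = np.zeros(shape, dtype=bool)
    if f_mild + f_high <= 0:
        return mild, high

    dy, dx, _ = acq.voxel_dims_mm
    sigma_px = (spec.lesion_smoothness_mm / dy, spec.lesion_smoothness_mm / dx)
    field_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    imbalance = spec.left_right_imbalance

    for s in range(shape[2]):
        noise = field_rng.standard_normal(shape[:2])
        smooth = gaussian_filter(noise, sigma=sigma_px)
        for i, leg in enumerate(legs):
            # left leg index 0 gets (1+imbalance) x the target fractions
            scale = 1.0 + imbalance if i == 0 else 1.0 - imbalance
            sel = leg[:, :, s]
            m = int(sel.sum())
            if m == 0:
                continue
            vals = smooth[sel]
            n_high = min(m, int(round(scale * f_high * m)))
            n_mild = min(m - n_high, int(round(scale * f_mild * m)))
            order = np.argsort(vals)[::-1]  # largest field values first
            idx_r, idx_c = np.nonzero(sel)
            top = order[:n_high]
            nxt = order[n_high:n_high + n_mild]
            high[idx_r[top], idx_c[top], s] = True
            mild[idx_r[nxt], idx_c[nxt], s] = True
    return mild, high


def _noiseless_phantom(spec: PhantomSpec, acq: AcquisitionParams):
    """Ground-truth T2/S0 fields and the noise-free signal stack."""
    legs, bone, rim, bladder = _anatomy(spec, acq)
    muscle = legs[0] | legs[1]
    mild, high = _lesion_labels(spec, acq, legs)

    t2 = np.zeros(muscle.shape)
    s0 = np.zeros(muscle.shape)
    t2[muscle] = spec.t2_healthy_ms
    t2[mild] = spec.t2_lesion_mild_ms
    t2[high] = spec.t2_lesion_high_ms
    s0[muscle] = spec.s0_muscle
    if spec.include_confounders:
        t2[bone] = _T2_BONE_MS
        s0[bone] = _S0_BONE * spec.s0_muscle
        t2[rim] = _T2_FAT_MS
        s0[rim] = _S0_FAT * spec.s0_muscle
        t2[bladder] = _T2_BLADDER_MS
        s0[bladder] = _S0_BLADDER * spec.s0_muscle

    te = acq.echo_times_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.where(t2[..., None] > 0, np.exp(-te / np.where(t2 > 0, t2, 1.0)[..., None]), 0.0)
    signal = s0[..., None] * decay

    truth = GroundTruth(
        t2_field_ms=t2,
        mask_true=muscle,
        lesion_burden=GroundTruth._burden(t2, muscle, spec.t2_healthy_ms),
        severity=spec.severity,
    )
    return signal, truth


def _apply_rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    real = signal + sigma * rng.standard_normal(signal.shape)
    imag = sigma * rng.standard_normal(signal.shape)
    return np.hypot(real, imag)


def make_phantom(spec: PhantomSpec, acq: AcquisitionParams | None = None,
                 noise_seed: int | None = None) -> tuple[EchoStack, GroundTruth]:
    """Generate one synthetic animal: a noisy echo stack plus its ground truth.

    Deterministic given ``(spec, acq)``: anatomy, lesions and noise all
    derive from ``spec.seed`` via independent substreams.  ``noise_seed``
    overrides only the noise substream (used for test-retest pairs).
    """
    acq = acq or AcquisitionParams()
    signal, truth = _noiseless_phantom(spec, acq)
    if math.isfinite(spec.snr):
        sigma = spec.noise_sigma(acq)
        seed_seq = (
            np.random.SeedSequence([int(spec.seed), 1])
            if noise_seed is None
            else np.random.SeedSequence([int(noise_seed), 1])
        )
        signal = _apply_rician(signal, sigma, np.random.default_rng(seed_seq))
    stack = EchoStack(data=signal, echo_times_ms=acq.echo_times_ms,
                      voxel_dims_mm=acq.voxel_dims_mm)
    return stack, truth


def make_retest_pair(spec: PhantomSpec, acq: AcquisitionParams | None = None,
                     seed_a: int = 1, seed_b: int = 2,
                     shift_px: tuple[int, int] = (0, 0)
                     ) -> tuple[EchoStack, EchoStack, GroundTruth]:
    """Two acquisitions of the same animal: shared anatomy and T2 field,
    independent noise realizations (sessions two days apart, in effect).

    ``shift_px`` optionally rolls the second acquisition in-plane by whole
    voxels to mimic repositioning; off by default.
    """
    if seed_a == seed_b:
        raise InvalidParameterError("retest sessions need distinct noise seeds")
    acq = acq or AcquisitionParams()
    signal, truth = _noiseless_phantom(spec, acq)
    signal_b = signal
    if shift_px != (0, 0):
        signal_b = np.roll(signal, shift=shift_px, axis=(0, 1))
    if math.isfinite(spec.snr):
        sigma = spec.noise_sigma(acq)
        rng_a = np.random.default_rng(np.random.SeedSequence([int(seed_a), 1]))
        rng_b = np.random.default_rng(np.random.SeedSequence([int(seed_b), 1]))
        sig_a = _apply_rician(signal, sigma, rng_a)
        sig_b = _apply_rician(signal_b, sigma, rng_b)
    else:
        sig_a, sig_b = signal, signal_b
    mk = lambda s: EchoStack(data=s, echo_times_ms=acq.echo_times_ms,
                             voxel_dims_mm=acq.voxel_dims_mm)
    return mk(sig_a), mk(sig_b), truth


def make_cohort(spec: CohortSpec, acq: AcquisitionParams | None = None, seed: int = 0,
                synthesize_images: bool = True
                ) -> list[tuple[EchoStack | None, GroundTruth, CohortRecord]]:
    """Generate one phantom per animal across the genotype groups.

    Severities are drawn per genotype from the configured uniform ranges;
    each record carries genotype, true severity, lesion burden and the
    simulated dye-uptake surrogate.  With ``synthesize_images=False`` only
    ground truth and records are produced (no echo stacks), which is much
    faster when the images themselves are not needed.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    out: list[tuple[EchoStack | None, GroundTruth, CohortRecord]] = []
    for genotype in spec.n_per_group:  # insertion order: reproducible
        lo, hi = spec.severity_distributions[genotype]
        for k in range(spec.n_per_group[genotype]):
            severity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            animal_seed = int(rng.integers(0, 2**31 - 1))
            pspec = PhantomSpec(
                seed=animal_seed,
                severity=severity,
                t2_healthy_ms=spec.phantom.t2_healthy_ms,
                t2_lesion_mild_ms=spec.phantom.t2_lesion_mild_ms,
                t2_lesion_high_ms=spec.phantom.t2_lesion_high_ms,
                lesion_fraction_mild=spec.phantom.lesion_fraction_mild,
                lesion_fraction_high=spec.phantom.lesion_fraction_high,
                s0_muscle=spec.phantom.s0_muscle,
                snr=spec.phantom.snr,
                include_confounders=spec.phantom.include_confounders,
                left_right_imbalance=spec.phantom.left_right_imbalance,
                lesion_smoothness_mm=spec.phantom.lesion_smoothness_mm,
            )
            if synthesize_images:
                stack, truth = make_phantom(pspec, acq)
            else:
                _, truth = _noiseless_phantom(pspec, acq)
                stack = None
            dye = spec.dye_intercept + spec.dye_slope * truth.lesion_burden
            if spec.dye_noise_sd > 0:
                dye += spec.dye_noise_sd * float(rng.standard_normal())
            record = CohortRecord(
                animal_id=f"{genotype}_{k:02d}",
                genotype=genotype,
                session=1,
                dye_uptake=max(0.0, float(dye)),
                severity_true=severity,
                lesion_burden=truth.lesion_burden,
            )
            out.append((stack, truth, record))
    return out
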