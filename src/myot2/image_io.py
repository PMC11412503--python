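"""Image containers and I/O: multi-echo stacks, muscle masks, NIfTI round trips.

The pipeline's raw input is a 4-D multi-slice multi-echo spin-echo stack
(row, col, slice, echo) with a strictly increasing echo-time vector, and a
binary muscle mask aligned to the same grid.  Masks typically come from an
external segmentation (manual or model-based); for synthetic phantoms a
simple intensity/morphology auto-mask is provided so the pipeline can run
end to end without any external segmentation.

Conventions: 0-based voxel indices; the slice axis is the third spatial
axis; masks must share the stack's grid exactly (no resampling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from ._exceptions import DataError, InvalidParameterError

__all__ = [
    "EchoStack",
    "MuscleMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "apply_mask",
    "auto_mask_phantom",
    "exclude_slices",
]


@dataclass(frozen=True)
class EchoStack:
    """A 4-D multi-echo image volume.

    Parameters
    ----------
    data
        Nonnegative intensities indexed ``(row, col, slice, echo)``.
    echo_times_ms
        Strictly increasing echo times, one per echo-axis entry.
    voxel_dims_mm
        ``(dy, dx, dz)`` voxel spacing in millimetres.
    """

    data: np.ndarray
    echo_times_ms: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        te = np.asarray(self.echo_times_ms, dtype=np.float64)
        if data.ndim != 4:
            raise DataError(f"echo stack must be 4-D (row, col, slice, echo); got {data.ndim}-D")
        if te.ndim != 1 or te.size == 0:
            raise InvalidParameterError("echo_times_ms must be a nonempty 1-D vector")
        if data.shape[3] != te.size:
            raise DataError(
                f"echo axis length {data.shape[3]} != number of echo times {te.size}"
            )
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise InvalidParameterError("echo times must be strictly increasing and positive")
        if not np.all(np.isfinite(data)) or np.any(data < 0):
            raise DataError("stack intensities must be finite and nonnegative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "echo_times_ms", te)
        object.__setattr__(self, "voxel_dims_mm", tuple(float(v) for v in self.voxel_dims_mm))

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class MuscleMask:
    """Binary muscle labels plus a set of slices excluded from analysis."""

    labels: np.ndarray
    excluded_slices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise DataError(f"mask must be 3-D; got {labels.ndim}-D")
        if labels.dtype != bool:
            vals = np.unique(labels)
            if not np.all(np.isin(vals, (0, 1))):
                warnings.warn(
                    f"mask contains values outside {{0, 1}} ({vals[:5]}...); "
                    "treating any nonzero voxel as muscle",
                    stacklevel=2,
                )
            labels = labels != 0
        excl = frozenset(int(s) for s in self.excluded_slices)
        n_slices = labels.shape[2]
        bad = [s for s in excl if not 0 <= s < n_slices]
        if bad:
            raise InvalidParameterError(f"excluded slice indices {bad} out of range [0, {n_slices})")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "excluded_slices", excl)

    def valid_voxels(self) -> np.ndarray:
        """Boolean array of muscle voxels on non-excluded slices."""
        valid = self.labels.copy()
        for s in self.excluded_slices:
            valid[:, :, s] = False
        return valid

    @property
    def n_valid(self) -> int:
        return int(self.valid_voxels().sum())


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stack(stack: EchoStack, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a stack as 4-D NIfTI plus a JSON sidecar with acquisition metadata.

    Returns the sidecar path.  The sidecar holds ``echo_times_ms`` and
    ``voxel_dims_mm`` (plus any ``extra_meta``), which :func:`read_stack`
    needs to reconstruct the object.
    """
    path = Path(path)
    dy, dx, dz = stack.voxel_dims_mm
    affine = np.diag([dy, dx, dz, 1.0])
    img = nib.Nifti1Image(stack.data.astype(np.float64), affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, path)
    meta = {
        "echo_times_ms": [float(t) for t in stack.echo_times_ms],
        "voxel_dims_mm": list(stack.voxel_dims_mm),
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def read_stack(path: str | Path, echo_times_ms: np.ndarray | None = None) -> EchoStack:
    """Read a 4-D NIfTI stack; echo times come from the JSON sidecar unless given."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 4-D echo-indexed volume, got {data.ndim}-D")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if echo_times_ms is None:
        if "echo_times_ms" not in meta:
            raise DataError(
                f"{path}: no echo times supplied and sidecar {sidecar.name} "
                "is missing the field 'echo_times_ms'"
            )
        echo_times_ms = np.asarray(meta["echo_times_ms"], dtype=np.float64)
    voxel_dims = tuple(meta.get("voxel_dims_mm") or np.abs(np.diag(img.affine)[:3]))
    return EchoStack(data=data, echo_times_ms=np.asarray(echo_times_ms), voxel_dims_mm=voxel_dims)


def write_mask(mask: MuscleMask, path: str | Path,
               voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    """Write a mask as integer 0/1 NIfTI; exclusions go in a JSON sidecar."""
    path = Path(path)
    dy, dx, dz = voxel_dims_mm
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), np.diag([dy, dx, dz, 1.0]))
    nib.save(img, path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"excluded_slices": sorted(mask.excluded_slices)}))
    return sidecar


def read_mask(path: str | Path) -> MuscleMask:
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise DataError(f"{path}: expected a 3-D mask volume, got {labels.ndim}-D")
    excluded: list[int] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        excluded = json.loads(sidecar.read_text()).get("excluded_slices", [])
    return MuscleMask(labels=labels, excluded_slices=frozenset(excluded))


def apply_mask(stack: EchoStack, mask: MuscleMask) -> np.ma.MaskedArray:
    """Return the stack as a masked array: non-muscle voxels are invalid.

    The number of valid voxels equals the count of mask-true voxels on
    non-excluded slices; every echo of an invalid voxel is masked out.
    """
    if mask.labels.shape != stack.spatial_shape:
        raise DataError(
            f"mask shape {mask.labels.shape} does not match stack spatial shape "
            f"{stack.spatial_shape}"
        )
    valid = mask.valid_voxels()
    invalid4d = np.broadcast_to(~valid[..., None], stack.data.shape)
    return np.ma.MaskedArray(stack.data, mask=invalid4d)


def exclude_slices(mask: MuscleMask, slices: list[int] | set[int]) -> MuscleMask:
    """Return a mask with the given slices added to the exclusion set (set semantics)."""
    new = frozenset(int(s) for s in slices)
    n_slices = mask.labels.shape[2]
    bad = [s for s in new if not 0 <= s < n_slices]
    if bad:
        raise InvalidParameterError(f"slice indices {bad} out of range [0, {n_slices})")
    return replace(mask, excluded_slices=mask.excluded_slices | new)


def _quick_t2_estimate(stack: EchoStack, foreground: np.ndarray,
                       n_echoes: int = 8) -> np.ndarray:
    """Crude voxelwise T2 from a log-linear fit, for confounder screening only.

    Restricted to the first ``n_echoes`` echoes, where tissue signal still
    dominates the noise floor; this only needs to separate muscle-range T2
    from fat/fluid confounders, not to be accurate.
    """
    te = stack.echo_times_ms[:n_echoes]
    sig = stack.data[foreground][:, :n_echoes]  # (n, echoes)
    floor = max(1e-12, 1e-6 * float(sig.max(initial=0.0)))
    logs = np.log(np.clip(sig, floor, None))
    t = te - te.mean()
    slope = (logs * t).sum(axis=1) / (t * t).sum()
    with np.errstate(divide="ignore"):
        t2 = -1.0 / slope
    t2[slope >= 0] = np.inf
    out = np.zeros(stack.spatial_shape)
    out[foreground] = t2
    return out


def auto_mask_phantom(
    stack: EchoStack,
    t2_max_ms: float = 100.0,
    min_object_mm2: float = 1.0,
    opening_radius_mm: float = 0.30,
) -> MuscleMask:
    """Segment muscle on a phantom-like stack without any trained model.

    Otsu threshold on the first (proton-density-weighted) echo isolates
    tissue from background; voxels whose quick log-linear T2 exceeds
    ``t2_max_ms`` (subcutaneous fat rim, bladder) are screened out;
    morphological opening/closing cleans speckle and components smaller
    than ``min_object_mm2`` are dropped.  Low-signal structures such as
    bone fall below the Otsu threshold and are never included.

    This is plumbing for synthetic data, not a segmentation model: on real
    scans, supply an externally produced mask instead.
    """
    first = stack.data[..., 0]
    if not np.any(first > 0):
        raise DataError("auto mask: image is all zero, no foreground to segment")
    thr = threshold_otsu(first)
    fg = first > thr
    if not fg.any():
        raise DataError("auto mask: empty foreground after Otsu thresholding")

    dy, dx, _ = stack.voxel_dims_mm
    px_mm2 = dy * dx
    radius_px = max(1, int(round(opening_radius_mm / max(dy, dx))))
    footprint = morphology.disk(radius_px)
    min_size_px = max(4, int(round(min_object_mm2 / px_mm2)))

    t2_rough = _quick_t2_estimate(stack, fg)
    fg &= t2_rough <= t2_max_ms
    out = np.zeros_like(fg)
    for s in range(fg.shape[2]):
        sl = fg[:, :, s]
        sl = morphology.opening(sl, footprint)
        sl = morphology.closing(sl, footprint)
        lab = measure.label(sl, connectivity=2)
        for region in measure.regionprops(lab):
            if region.area < min_size_px:
                continue
            coords = tuple(region.coords.T)
            out[:, :, s][coords] = True
    if not out.any():
        raise DataError("auto mask: no component survived size/T2 screening")
    # thresholding contract: the mask can only contain voxels with signal
    out &= first > 0
    return MuscleMask(labels=out)
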