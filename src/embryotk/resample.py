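"""Volume size reduction: integer-factor binning and grid resampling.

Binning averages non-overlapping ``factor^3`` blocks (the standard CT
convention), dropping trailing partial blocks, and multiplies the spacing by
the factor. Resampling targets an arbitrary physical voxel size: voxels are
treated as cell-centred and the output grid covers the same physical extent,
sampled with linear or nearest-neighbour interpolation. Label maps must use
nearest — interpolating label ids invents anatomy.

Interpolated grey values are rounded half-to-even and clipped to the dtype
range, so integer volumes stay integer without drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateOutputError, InterpolationModeError
from .types import Volume3D


@dataclass(frozen=True)
class ResamplePlan:
    """A validated description of a resize step (for batch manifests)."""

    mode: str  # "bin" | "resample"
    factor: int = 1
    target_spacing: tuple[float, float, float] | None = None
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.mode not in ("bin", "resample"):
            raise ValueError(f"mode must be 'bin' or 'resample', got {self.mode!r}")
        if self.mode == "bin" and self.factor < 1:
            raise ValueError(f"bin factor must be >= 1, got {self.factor}")
        if self.mode == "resample":
            if self.target_spacing is None or any(s <= 0 for s in self.target_spacing):
                raise ValueError("resample mode requires positive target spacings")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    def apply(self, vol: Volume3D, labels: bool = False) -> Volume3D:
        if self.mode == "bin":
            return bin_volume(vol, self.factor)
        return resample_volume(vol, self.target_spacing, self.interpolation,
                               labels=labels)


def _restore_dtype(data: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)  # rint = half-even
    return data.astype(dtype)


def bin_volume(vol: Volume3D, factor: int) -> Volume3D:
    """Downsample by an integer factor: each output voxel is the mean of its
    ``factor^3`` input block; trailing partial blocks are dropped; spacing is
    multiplied by the factor. Factor 1 is the identity (copy)."""
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    if factor == 1:
        return vol.copy()
    out_shape = tuple(n // factor for n in vol.shape)
    if any(n == 0 for n in out_shape):
        raise DegenerateOutputError(
            f"bin factor {factor} exceeds a volume dimension {vol.shape}")
    nz, ny, nx = (n * factor for n in out_shape)
    blocks = vol.data[:nz, :ny, :nx].astype(np.float64).reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor)
    means = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(s * factor for s in vol.spacing)
    meta = dict(vol.metadata)
    meta["bin_factor"] = str(factor)
    return Volume3D(_restore_dtype(means, vol.data.dtype), spacing, meta)


def resample_volume(
    vol: Volume3D,
    target_spacing: tuple[float, float, float],
    interpolation: str = "linear",
    labels: bool = False,
) -> Volume3D:
    """Resample onto a grid of the given physical voxel size (micrometres).

    Output extent per axis is ``round(n * s / target_s)`` with a minimum of 1,
    so the physical extent is preserved to within one voxel. ``labels=True``
    marks the input as a label map and demands nearest-neighbour
    interpolation (:class:`InterpolationModeError` otherwise).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacings must be > 0, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if labels and interpolation != "nearest":
        raise InterpolationModeError(
            "label maps must be resampled with nearest-neighbour interpolation")

    if target_spacing == vol.spacing:
        return vol.copy()

    out_shape = tuple(
        max(1, int(round(n * s / ts)))
        for n, s, ts in zip(vol.shape, vol.spacing, target_spacing))
    # cell-centred: output sample i sits at physical (i + 0.5) * ts, which is
    # input index (i + 0.5) * ts / s - 0.5
    coords = np.meshgrid(
        *[(np.arange(m) + 0.5) * ts / s - 0.5
          for m, s, ts in zip(out_shape, vol.spacing, target_spacing)],
        indexing="ij")
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(coords), order=order,
        mode="nearest")
    meta = dict(vol.metadata)
    meta["resampled_to_um"] = ",".join(repr(s) for s in target_spacing)
    return Volume3D(_restore_dtype(out, vol.data.dtype), target_spacing, meta)


def resample_labels(
    vol: Volume3D, target_spacing: tuple[float, float, float],
) -> Volume3D:
    """Nearest-neighbour resampling for integer label volumes."""
    return resample_volume(vol, target_spacing, "nearest", labels=True)
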