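"""Automatic cropping of embryo reconstructions.

Empty space around a specimen dominates file size without carrying signal.
The crop here follows the classic recipe: a robust maximum intensity
projection (MIP) along z, an Otsu threshold on the projection, and the padded
bounding rectangle of the above-threshold pixels. "Robust" means intensities
above a high quantile are clipped before projecting, so isolated bright
scanner artefacts cannot inflate the MIP and drag the Otsu threshold up.

When the automatic crop fails (nothing above threshold) the caller gets an
:class:`EmptyForegroundError` rather than a silent full-volume box, so batch
logs surface the scans needing a manually drawn rectangle
(:func:`manual_crop_box`). One crop box can be applied across all channels of
a multi-channel acquisition with :func:`propagate_crop`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BoundsError,
    ChannelMismatchError,
    DegenerateInputError,
    EmptyForegroundError,
)
from .types import BoundingBox3D, Volume3D

DEFAULT_CLIP_FRACTION = 0.001
DEFAULT_PADDING = 16
OTSU_BINS = 256


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D maximum intensity projection, pixel (j, i) = max over the axis."""

    data: np.ndarray  # 2D float
    source_axis: int = 0


def max_intensity_projection(
    vol: Volume3D, clip_fraction: float = DEFAULT_CLIP_FRACTION, axis: int = 0,
) -> ProjectionImage:
    """Clipped MIP: intensities above the (1 - clip_fraction) quantile are
    clipped to that quantile, then the per-pixel maximum is taken along ``axis``.

    ``clip_fraction`` must satisfy 0 <= clip_fraction < 0.5. Zero disables
    clipping and gives the plain MIP.
    """
    if not 0 <= clip_fraction < 0.5:
        raise ValueError(f"clip_fraction must be in [0, 0.5), got {clip_fraction}")
    data = vol.data.astype(np.float64, copy=False)
    if clip_fraction > 0:
        ceiling = np.quantile(data, 1.0 - clip_fraction)
        data = np.minimum(data, ceiling)
    return ProjectionImage(data.max(axis=axis), source_axis=axis)


def otsu_threshold(img: ProjectionImage | np.ndarray, n_bins: int = OTSU_BINS) -> float:
    """Histogram threshold maximizing between-class variance.

    The image is binned into ``n_bins`` equal-width bins over its range; the
    returned threshold is the bin *edge* maximizing the between-class variance
    of the split {values < edge} / {values >= edge}. Ties are broken towards
    the lowest qualifying edge. A constant image has no meaningful split and
    raises :class:`DegenerateInputError`.
    """
    data = img.data if isinstance(img, ProjectionImage) else np.asarray(img)
    data = data.astype(np.float64, copy=False).ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise DegenerateInputError("Otsu threshold undefined for a constant image")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # cumulative zeroth/first moments; candidate edges are the interior ones
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    between = np.full(n_bins - 1, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(valid, m0 / np.maximum(w0, 1e-300), 0.0)
        mu1 = np.where(valid, m1 / np.maximum(w1, 1e-300), 0.0)
    between[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def derive_crop_box(
    vol: Volume3D,
    threshold: float | None = None,
    padding: int = DEFAULT_PADDING,
    crop_z: bool = False,
    clip_fraction: float = DEFAULT_CLIP_FRACTION,
) -> BoundingBox3D:
    """Bounding box of the specimen, from thresholded projections.

    The (y, x) extent is the tight bounding rectangle of z-projection pixels
    strictly above ``threshold`` (computed by Otsu on the clipped MIP when
    None), dilated by ``padding`` voxels and clamped to the volume. The z
    extent is the full axis unless ``crop_z`` is set, in which case it is
    derived the same way from the y-axis projection.

    Raises :class:`EmptyForegroundError` when no pixel exceeds the threshold —
    the autocrop failed and a manual box is needed.
    """
    proj = max_intensity_projection(vol, clip_fraction)
    if threshold is None:
        threshold = otsu_threshold(proj)
    mask = proj.data > threshold
    if not mask.any():
        raise EmptyForegroundError(
            f"no projection pixel above threshold {threshold}; draw a manual box")
    ys, xs = np.nonzero(mask)
    nz, ny, nx = vol.shape
    z0, z1 = 0, nz
    if crop_z:
        zproj = max_intensity_projection(vol, clip_fraction, axis=1)
        zmask = zproj.data > threshold
        if not zmask.any():
            raise EmptyForegroundError(
                f"no z-projection pixel above threshold {threshold}")
        zs = np.nonzero(zmask)[0]
        z0, z1 = int(zs.min()), int(zs.max()) + 1
    box = BoundingBox3D(z0, z1, int(ys.min()), int(ys.max()) + 1,
                        int(xs.min()), int(xs.max()) + 1)
    return box.padded(padding, vol.shape)


def apply_crop(vol: Volume3D, box: BoundingBox3D) -> Volume3D:
    """Extract the box; spacing and metadata preserved, box recorded as audit."""
    box.check_within(vol.shape)
    meta = dict(vol.metadata)
    meta["crop_box"] = box.format()
    return Volume3D(vol.data[box.as_slices()].copy(), vol.spacing, meta)


def propagate_crop(channels: list[Volume3D], box: BoundingBox3D) -> list[Volume3D]:
    """Apply one crop box to every channel of a multi-channel acquisition."""
    if not channels:
        return []
    shape = channels[0].shape
    for k, ch in enumerate(channels[1:], start=1):
        if ch.shape != shape:
            raise ChannelMismatchError(
                f"channel {k} shape {ch.shape} differs from channel 0 {shape}")
    return [apply_crop(ch, box) for ch in channels]


def manual_crop_box(
    rect: tuple[int, int, int, int], vol: Volume3D,
) -> BoundingBox3D:
    """Box from a user-drawn rectangle ``(y0, y1, x0, x1)`` on the projection.

    The rectangle is clamped to the image; the z extent is the full axis.
    An empty intersection raises :class:`BoundsError`.
    """
    y0, y1, x0, x1 = (int(v) for v in rect)
    nz, ny, nx = vol.shape
    cy0, cy1 = max(y0, 0), min(y1, ny)
    cx0, cx1 = max(x0, 0), min(x1, nx)
    if cy0 >= cy1 or cx0 >= cx1:
        raise BoundsError(f"rectangle {rect} does not intersect image ({ny}x{nx})")
    return BoundingBox3D(0, nz, cy0, cy1, cx0, cx1)


def autocrop_volume(
    vol: Volume3D,
    padding: int = DEFAULT_PADDING,
    clip_fraction: float = DEFAULT_CLIP_FRACTION,
    crop_z: bool = False,
) -> tuple[Volume3D, BoundingBox3D]:
    """One-call automatic crop: MIP -> Otsu -> padded box -> apply."""
    box = derive_crop_box(vol, None, padding, crop_z, clip_fraction)
    return apply_crop(vol, box), box
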