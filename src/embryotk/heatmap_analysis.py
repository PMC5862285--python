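"""Analytics for voxelwise t-statistic heatmaps and deformation fields.

The automated morphometry pipeline emits a t-statistic per voxel: positive
where the mutant cohort is locally larger/brighter than wild type, negative
where smaller/darker, zero where masked or not significant. Subtle phenotypes
can be a handful of voxels, easy to miss when paging through slices, so the
core operation here enumerates the connected significant regions and tabulates
each one's position, extent, voxel volume and mean t.

Two deliberate choices, both configurable:

* Connectivity is 26-neighbour by default (phenotype blobs are compact);
  pass ``connectivity=6`` for a face-only sensitivity check.
* Positive and negative components are never merged across a shared
  boundary: local expansion and shrinkage are opposite effects, and keeping
  them separate mirrors the red/blue display convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas_tools import DisplacementField
from .errors import AlignmentError
from .types import BoundingBox3D, Volume3D

#: a heatmap is simply a float Volume3D aligned to the population average
HeatmapVolume = Volume3D

DEFAULT_MIN_VOXELS = 5

_STRUCTURES = {26: np.ones((3, 3, 3), dtype=bool),
               6: ndimage.generate_binary_structure(3, 1)}


@dataclass(frozen=True)
class RegionRecord:
    """One connected significant region of a heatmap."""

    region_id: int
    sign: str  # "positive" | "negative"
    midpoint: tuple[int, int, int]  # integer midpoint of the bounding box
    centroid: tuple[float, float, float]
    bbox: BoundingBox3D
    voxel_volume: int
    mean_t: float


def filter_by_t(hm: HeatmapVolume, t_min: float) -> HeatmapVolume:
    """Zero every voxel with |t| < t_min; survivors keep value and sign."""
    if t_min < 0:
        raise ValueError(f"t_min must be >= 0, got {t_min}")
    data = np.where(np.abs(hm.data) >= t_min, hm.data, 0).astype(hm.data.dtype)
    return Volume3D(data, hm.spacing, dict(hm.metadata))


def connected_regions(
    hm: HeatmapVolume,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = 26,
) -> list[RegionRecord]:
    """Connected components of non-zero voxels, split by sign.

    Components smaller than ``min_voxels`` are dropped. Records are sorted by
    voxel volume descending (ties by bounding-box corner) and region ids are
    assigned in that order, so the largest effect is region 1.
    """
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    structure = _STRUCTURES[connectivity]
    t = hm.data.astype(np.float64, copy=False)
    raw: list[tuple] = []
    for sign, mask in (("positive", t > 0), ("negative", t < 0)):
        labeled, n = ndimage.label(mask, structure)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(t), labeled, idx)
        sums = ndimage.sum_labels(t, labeled, idx)
        centroids = ndimage.center_of_mass(mask, labeled, idx)
        objects = ndimage.find_objects(labeled)
        for i, sl in enumerate(objects):
            cnt = int(counts[i])
            if cnt < min_voxels:
                continue
            bbox = BoundingBox3D(sl[0].start, sl[0].stop, sl[1].start,
                                 sl[1].stop, sl[2].start, sl[2].stop)
            mid = tuple((lo + hi - 1) // 2 for lo, hi in
                        ((bbox.z0, bbox.z1), (bbox.y0, bbox.y1),
                         (bbox.x0, bbox.x1)))
            raw.append((cnt, bbox, sign, mid, tuple(float(c) for c in
                        centroids[i]), sums[i] / cnt))
    raw.sort(key=lambda r: (-r[0], r[1].z0, r[1].y0, r[1].x0))
    return [
        RegionRecord(region_id=k + 1, sign=sign, midpoint=mid,
                     centroid=cen, bbox=bbox, voxel_volume=cnt,
                     mean_t=float(mean))
        for k, (cnt, bbox, sign, mid, cen, mean) in enumerate(raw)
    ]


def region_table(
    records: list[RegionRecord],
    spacing: tuple[float, float, float],
) -> pd.DataFrame:
    """Tabular report of significant regions (voxel + physical coordinates)."""
    sz, sy, sx = spacing
    vox_mm3 = sz * sy * sx * 1e-9
    rows = []
    for r in records:
        rows.append({
            "region_id": r.region_id,
            "sign": r.sign,
            "mid_z": r.midpoint[0], "mid_y": r.midpoint[1], "mid_x": r.midpoint[2],
            "mid_z_um": r.midpoint[0] * sz, "mid_y_um": r.midpoint[1] * sy,
            "mid_x_um": r.midpoint[2] * sx,
            "bbox": r.bbox.format(),
            "voxel_volume": r.voxel_volume,
            "volume_mm3": r.voxel_volume * vox_mm3,
            "mean_t": r.mean_t,
        })
    columns = ["region_id", "sign", "mid_z", "mid_y", "mid_x", "mid_z_um",
               "mid_y_um", "mid_x_um", "bbox", "voxel_volume", "volume_mm3",
               "mean_t"]
    return pd.DataFrame(rows, columns=columns)


def write_region_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_csv(path, sep=sep, index=False)
    return path


def read_region_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def filter_vectors(
    fld: DisplacementField, mag_min: float = 0.0, stride: int = 1,
) -> DisplacementField:
    """Zero vectors below ``mag_min`` (Euclidean, micrometres), then decimate
    the grid to every ``stride``-th voxel per axis; survivors are unchanged."""
    if mag_min < 0:
        raise ValueError(f"mag_min must be >= 0, got {mag_min}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    vec = fld.vectors.copy()
    if mag_min > 0:
        vec[np.linalg.norm(vec, axis=-1) < mag_min] = 0.0
    vec = vec[::stride, ::stride, ::stride]
    spacing = tuple(s * stride for s in fld.spacing)
    return DisplacementField(vec, spacing, dict(fld.metadata))


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------

def _hot_ramp(x: np.ndarray) -> np.ndarray:
    """Red-hot ramp on [0,1] -> RGB: dark red -> red -> yellow (never white,
    so the strongest positive effects stay unmistakably red)."""
    r = np.clip(2 * x, 0, 1)
    g = np.clip(2 * x - 1, 0, 1)
    b = np.zeros_like(x)
    return np.stack([r, g, b], axis=-1)


def _cold_ramp(x: np.ndarray) -> np.ndarray:
    """Blue-cold ramp on [0,1] -> RGB: dark blue -> blue -> cyan (mirror of
    the hot ramp)."""
    b = np.clip(2 * x, 0, 1)
    g = np.clip(2 * x - 1, 0, 1)
    r = np.zeros_like(x)
    return np.stack([r, g, b], axis=-1)


def overlay_slice(
    avg_slice: np.ndarray, t_slice: np.ndarray,
    t_max: float, alpha: float = 0.7, grey_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Blend one grey slice with its red/blue t overlay -> uint8 RGB."""
    if grey_range is None:
        lo, hi = float(avg_slice.min()), float(avg_slice.max())
    else:
        lo, hi = grey_range
    grey = np.zeros_like(avg_slice, dtype=np.float64) if hi == lo else \
        np.clip((avg_slice.astype(np.float64) - lo) / (hi - lo), 0, 1)
    rgb = np.repeat(grey[..., None], 3, axis=-1)
    t = t_slice.astype(np.float64)
    scale = max(t_max, np.finfo(float).tiny)
    pos = t > 0
    neg = t < 0
    if pos.any():
        ramp = _hot_ramp(np.clip(t[pos] / scale, 0, 1) * 0.7 + 0.3)
        rgb[pos] = (1 - alpha) * rgb[pos] + alpha * ramp
    if neg.any():
        ramp = _cold_ramp(np.clip(-t[neg] / scale, 0, 1) * 0.7 + 0.3)
        rgb[neg] = (1 - alpha) * rgb[neg] + alpha * ramp
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def overlay_montage(
    avg: Volume3D,
    hm: HeatmapVolume,
    path: str | Path,
    axis: str = "z",
    indices: list[int] | None = None,
    alpha: float = 0.7,
    scale_bar_um: float | None = None,
) -> Path:
    """PNG montage of slices: greyscale average, positive t red-hot, negative
    t blue-cold, alpha-blended; optional white scale bar of the given length.
    """
    if avg.shape != hm.shape:
        raise AlignmentError(
            f"average shape {avg.shape} != heatmap shape {hm.shape}")
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    n = avg.shape[ax]
    if indices is None:
        indices = [n // 4, n // 2, (3 * n) // 4]
    for i in indices:
        if not 0 <= i < n:
            raise AlignmentError(f"slice index {i} outside axis {axis} (0..{n - 1})")
    t_max = float(np.abs(hm.data).max())
    grey_range = (float(avg.data.min()), float(avg.data.max()))
    panels = []
    for i in indices:
        avg_sl = np.take(avg.data, i, axis=ax)
        t_sl = np.take(hm.data, i, axis=ax)
        panels.append(overlay_slice(avg_sl, t_sl, t_max, alpha, grey_range))
    img = np.concatenate(panels, axis=1)
    if scale_bar_um is not None:
        # bar along x of the first panel, 3 px high, 5 px in from the corner
        px = (avg.spacing[2], avg.spacing[2], avg.spacing[1])[ax]
        bar = min(int(round(scale_bar_um / px)), img.shape[1] - 10)
        if bar > 0:
            img[-8:-5, 5:5 + bar] = 255
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img)
    return path
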