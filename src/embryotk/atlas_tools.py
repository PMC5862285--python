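"""Atlas construction and organ volumetry.

After groupwise registration brings a cohort of embryo scans into a common
coordinate space, three operations make the atlas useful:

* :func:`population_average` — the voxelwise mean of the registered volumes,
  whose improved signal-to-noise makes it the canvas for segmentation.
* :func:`propagate_labels` — transfer of the atlas label map onto a subject
  through the registration's displacement field, by nearest-neighbour
  pull-back sampling. Registration itself is out of scope here: the field is
  an input.
* :func:`organ_volumes` / :func:`organ_volume_difference` — per-structure
  voxel counts, physical volumes and wild-type vs mutant ratios.

Displacement-field convention (pinned, since "apply the inverse transform"
underdetermines it): fields are *target-to-source pull-backs*. The vector
stored at target voxel index ``(k, j, i)`` has components ``(dz, dy, dx)`` in
micrometres; the propagated label at that voxel is the atlas label at
physical position ``index * spacing + d``. Out-of-bounds samples map to
background (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import volume_io
from .errors import AlignmentError
from .types import Volume3D
from .watershed_seg import LabelMap


@dataclass
class DisplacementField:
    """Per-voxel 3-vector pull-back field in physical micrometres.

    ``vectors`` is indexed ``(z, y, x, component)`` with components ordered
    ``(dz, dy, dx)`` to match the volume index order.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nz, ny, nx, 3), got {self.vectors.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def population_average(vols: list[Volume3D]) -> Volume3D:
    """Voxelwise arithmetic mean of registered volumes (float32).

    All inputs must share dimensions and spacing; a mismatch signals
    unregistered inputs and raises :class:`AlignmentError`. The number of
    averaged volumes is recorded in the metadata.
    """
    if not vols:
        raise ValueError("need at least one volume to average")
    ref = vols[0]
    acc = np.zeros(ref.shape, dtype=np.float64)
    for k, v in enumerate(vols):
        if v.shape != ref.shape or v.spacing != ref.spacing:
            raise AlignmentError(
                f"volume {k} (shape {v.shape}, spacing {v.spacing}) is not on "
                f"the reference grid (shape {ref.shape}, spacing {ref.spacing}); "
                "inputs must be registered first")
        acc += v.data
    mean = (acc / len(vols)).astype(np.float32)
    return Volume3D(mean, ref.spacing, {"n_averaged": str(len(vols))})


def propagate_labels(atlas: LabelMap, fld: DisplacementField) -> LabelMap:
    """Pull the atlas labels onto the field's target grid.

    For each target voxel at physical position p, the output label is the
    atlas label at the voxel nearest to ``p + d(p)``; samples falling outside
    the atlas map to background. Nearest-neighbour sampling is mandatory for
    labels, so no new label ids can appear.
    """
    if tuple(fld.spacing) != tuple(atlas.volume.spacing):
        raise AlignmentError(
            f"field spacing {fld.spacing} != atlas spacing {atlas.volume.spacing}")
    nz, ny, nx = fld.shape
    spacing = np.asarray(fld.spacing, dtype=np.float64)
    idx = np.indices((nz, ny, nx), dtype=np.float64)
    # physical sample position, then back to (fractional) atlas indices
    sample = idx * spacing[:, None, None, None] + np.moveaxis(
        fld.vectors.astype(np.float64), -1, 0)
    src = np.rint(sample / spacing[:, None, None, None]).astype(np.int64)
    inb = np.ones((nz, ny, nx), dtype=bool)
    for ax, n in enumerate(atlas.volume.shape):
        inb &= (src[ax] >= 0) & (src[ax] < n)
    out = np.zeros((nz, ny, nx), dtype=atlas.data.dtype)
    out[inb] = atlas.data[src[0][inb], src[1][inb], src[2][inb]]
    vol = Volume3D(out, fld.spacing, dict(atlas.volume.metadata))
    return LabelMap(vol, dict(atlas.names))


def organ_volumes(lm: LabelMap) -> pd.DataFrame:
    """Exact per-label voxel counts and physical volumes.

    Returns a DataFrame with columns ``label_id, name, voxel_count,
    volume_mm3`` (one row per non-zero label present, sorted by label_id);
    ``volume_mm3`` is exactly ``voxel_count`` times the voxel volume.
    """
    labels, counts = np.unique(lm.data, return_counts=True)
    vox_mm3 = lm.volume.voxel_volume_mm3
    rows = [
        {"label_id": int(lab), "name": lm.names.get(int(lab), f"label_{int(lab)}"),
         "voxel_count": int(cnt), "volume_mm3": int(cnt) * vox_mm3}
        for lab, cnt in zip(labels, counts) if lab != 0
    ]
    return pd.DataFrame(rows, columns=["label_id", "name", "voxel_count",
                                       "volume_mm3"])


def organ_volume_difference(wt: pd.DataFrame, mut: pd.DataFrame) -> pd.DataFrame:
    """Per-organ wild-type vs mutant comparison over the union of labels.

    ``ratio = mut_mm3 / wt_mm3``; a label missing on one side contributes 0,
    and the ratio is NaN (undefined) where the wild-type volume is 0.
    """
    w = wt.set_index("label_id") if len(wt) else pd.DataFrame(
        columns=["name", "volume_mm3"])
    m = mut.set_index("label_id") if len(mut) else pd.DataFrame(
        columns=["name", "volume_mm3"])
    labels = sorted(set(w.index) | set(m.index))
    rows = []
    for lab in labels:
        wt_mm3 = float(w["volume_mm3"].get(lab, 0.0))
        mut_mm3 = float(m["volume_mm3"].get(lab, 0.0))
        name = w["name"].get(lab, m["name"].get(lab, f"label_{lab}"))
        ratio = mut_mm3 / wt_mm3 if wt_mm3 > 0 else float("nan")
        rows.append({"label_id": int(lab), "name": name, "wt_mm3": wt_mm3,
                     "mut_mm3": mut_mm3, "ratio": ratio})
    return pd.DataFrame(rows, columns=["label_id", "name", "wt_mm3", "mut_mm3",
                                       "ratio"])


def write_volume_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an organ table as TSV (.tsv) or CSV (anything else)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# displacement-field NRRD I/O (4D, 3-component innermost axis)
# ---------------------------------------------------------------------------

_FIELD_KINDS = ("domain", "domain", "domain", "vector")  # slow-to-fast


def write_displacement_field(
    fld: DisplacementField, path: str | Path, compress: bool = False,
) -> Path:
    """4D NRRD with the 3-vector on the fastest axis (kinds: vector domain...)."""
    spacings = tuple(fld.spacing) + (float("nan"),)
    return volume_io.write_nrrd_array(
        path, fld.vectors.astype(np.float32), spacings,
        metadata=fld.metadata, encoding="bzip2" if compress else "raw",
        kinds=_FIELD_KINDS)


def read_displacement_field(path: str | Path) -> DisplacementField:
    array, spacings, metadata, _ = volume_io.read_nrrd_array(path)
    if array.ndim != 4 or array.shape[-1] != 3:
        raise AlignmentError(
            f"{path}: expected a (nz, ny, nx, 3) displacement field, "
            f"got shape {array.shape}")
    sp = tuple(1.0 if np.isnan(s) else float(s) for s in spacings[:3])
    return DisplacementField(array.astype(np.float32), sp, metadata)
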