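"""Core in-memory types shared by every module.

The universal currency is :class:`Volume3D`: a scalar 3D image indexed
``(z, y, x)`` with per-axis physical spacing in micrometres and a flat
string->string metadata map. Index order is 0-based ``(z, y, x)``; on disk
NRRD sizes run fast-to-slow ``(x, y, z)`` and the conversion happens only at
the I/O boundary (see :mod:`embryotk.volume_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, UnsupportedDtypeError

#: dtypes a Volume3D may carry; anything else must be converted explicitly.
SUPPORTED_DTYPES = {
    "uint8": np.uint8,
    "uint16": np.uint16,
    "float32": np.float32,
}

_DTYPE_TAGS = {np.dtype(v): k for k, v in SUPPORTED_DTYPES.items()}


@dataclass
class Volume3D:
    """A scalar 3D image with physical spacing and provenance metadata.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``; dtype must be uint8, uint16 or float32.
    spacing
        Physical voxel size ``(sz, sy, sx)`` in micrometres; all > 0.
    metadata
        Flat key -> string map (centre, modality, acquisition parameters, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D data must be 3D, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if self.data.dtype not in _DTYPE_TAGS:
            raise UnsupportedDtypeError(
                f"unsupported dtype {self.data.dtype}; expected one of "
                f"{sorted(SUPPORTED_DTYPES)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.metadata = {str(k): str(v) for k, v in self.metadata.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype_tag(self) -> str:
        """One of ``uint8``, ``uint16``, ``float32`` — faithful to storage."""
        return _DTYPE_TAGS[self.data.dtype]

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in cubic millimetres."""
        sz, sy, sx = self.spacing
        return sz * sy * sx * 1e-9

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, dict(self.metadata))

    def astype_tag(self, tag: str) -> "Volume3D":
        """Return a copy converted to the given dtype tag (values clipped)."""
        if tag not in SUPPORTED_DTYPES:
            raise UnsupportedDtypeError(f"unknown dtype tag {tag!r}")
        dt = np.dtype(SUPPORTED_DTYPES[tag])
        data = self.data
        if np.issubdtype(dt, np.integer):
            info = np.iinfo(dt)
            data = np.clip(np.rint(data.astype(np.float64)), info.min, info.max)
        return Volume3D(data.astype(dt), self.spacing, dict(self.metadata))


@dataclass(frozen=True)
class BoundingBox3D:
    """Half-open voxel-index crop region ``[lo, hi)`` per axis."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        for lo, hi, ax in ((self.z0, self.z1, "z"), (self.y0, self.y1, "y"),
                           (self.x0, self.x1, "x")):
            if lo >= hi:
                raise ValueError(f"empty box on axis {ax}: [{lo}, {hi})")
            if lo < 0:
                raise ValueError(f"negative lower bound on axis {ax}: {lo}")

    @property
    def extents(self) -> tuple[int, int, int]:
        return (self.z1 - self.z0, self.y1 - self.y0, self.x1 - self.x0)

    def as_slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1),
                slice(self.x0, self.x1))

    def padded(self, padding: int, shape: tuple[int, int, int]) -> "BoundingBox3D":
        """Dilate each bound outward by ``padding`` voxels, clamped to ``shape``."""
        nz, ny, nx = shape
        return BoundingBox3D(
            max(self.z0 - padding, 0), min(self.z1 + padding, nz),
            max(self.y0 - padding, 0), min(self.y1 + padding, ny),
            max(self.x0 - padding, 0), min(self.x1 + padding, nx),
        )

    def check_within(self, shape: tuple[int, int, int]) -> None:
        nz, ny, nx = shape
        if self.z1 > nz or self.y1 > ny or self.x1 > nx:
            raise BoundsError(f"box {self} exceeds volume shape {shape}")

    def format(self) -> str:
        return f"{self.z0},{self.z1},{self.y0},{self.y1},{self.x0},{self.x1}"

    @classmethod
    def parse(cls, text: str) -> "BoundingBox3D":
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 6:
            raise ValueError(f"expected 6 comma-separated bounds, got {text!r}")
        return cls(*parts)
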