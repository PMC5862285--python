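"""Deterministic synthetic phantoms: embryo volumes, heatmaps, fields.

Real micro-CT reconstructions of embryos are gigabytes each and cannot ship
with a test suite, so every fixture in this toolkit is fabricated here. The
phantom family is deliberately simple — a body ellipsoid containing nested
organ ellipsoids at distinct intensities, plus Gaussian noise — because
ellipsoids have closed-form volumes and known poses, which turns accuracy
checks (crop recovery, Dice, organ-volume ratios) into analytic oracles.

Everything is a pure function of its spec and seed: one ``numpy`` Generator
per call, no global state, no filesystem reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import PhantomSpecError
from .types import Volume3D
from .watershed_seg import LabelMap


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ: centre/radii in voxel units, optional rotation."""

    name: str
    center: tuple[float, float, float]  # (z, y, x) voxel coordinates
    radii: tuple[float, float, float]
    intensity: float
    label_id: int
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians about z, y, x

    def analytic_volume_voxels(self) -> float:
        rz, ry, rx = self.radii
        return 4.0 / 3.0 * np.pi * rz * ry * rx


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of an embryo phantom; (spec, seed) fixes every voxel."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (14.0, 14.0, 14.0)  # µm, micro-CT-ish
    body: OrganSpec | None = None
    organs: tuple[OrganSpec, ...] = ()
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    dtype: str = "uint8"

    def validate(self) -> None:
        ids = [o.label_id for o in self.organs]
        if len(ids) != len(set(ids)):
            raise PhantomSpecError(f"duplicate organ label ids: {sorted(ids)}")
        if any(i <= 0 for i in ids):
            raise PhantomSpecError("organ label ids must be positive")
        for o in self.organs:
            for c, r, n in zip(o.center, o.radii, self.dims):
                if r <= 0:
                    raise PhantomSpecError(f"{o.name}: non-positive radius")
                if c - r < -0.5 or c + r > n - 0.5:
                    raise PhantomSpecError(
                        f"organ {o.name} does not fit within dims {self.dims}")


def _rotation_matrix(angles: tuple[float, float, float]) -> np.ndarray:
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])  # rotate y-x plane
    ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def ellipsoid_mask(
    dims: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Boolean mask of a (possibly rotated) ellipsoid on a voxel grid."""
    grids = np.indices(dims, dtype=np.float64)
    delta = grids - np.asarray(center, dtype=np.float64)[:, None, None, None]
    if any(a != 0 for a in angles):
        rot = _rotation_matrix(angles)
        delta = np.einsum("ij,j...->i...", rot.T, delta)
    radii_arr = np.asarray(radii, dtype=np.float64)[:, None, None, None]
    return (np.sum((delta / radii_arr) ** 2, axis=0) <= 1.0)


@dataclass
class EmbryoPhantom:
    """A generated phantom: noisy volume, noise-free truth labels, body mask."""

    volume: Volume3D
    truth: LabelMap
    body_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


def make_embryo_phantom(spec: PhantomSpec) -> EmbryoPhantom:
    """Render the spec: body + organs + noise; truth is the clean geometry."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    body = spec.body or OrganSpec(
        "body",
        center=tuple((n - 1) / 2.0 for n in spec.dims),
        radii=tuple(0.42 * n for n in spec.dims),
        intensity=90.0, label_id=255)
    body_mask = ellipsoid_mask(spec.dims, body.center, body.radii, body.angles)
    clean = np.full(spec.dims, spec.background_intensity, dtype=np.float64)
    clean[body_mask] = body.intensity
    labels = np.zeros(spec.dims, dtype=np.uint16)
    names = {}
    for organ in spec.organs:
        m = ellipsoid_mask(spec.dims, organ.center, organ.radii, organ.angles)
        if (labels[m] != 0).any():
            raise PhantomSpecError(
                f"organ {organ.name} overlaps an earlier organ; phantom organs "
                "must be disjoint")
        clean[m] = organ.intensity
        labels[m] = organ.label_id
        names[organ.label_id] = organ.name
    noisy = clean
    if spec.noise_sd > 0:
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.dims)
    vol = Volume3D(noisy.astype(np.float32), spec.spacing,
                   {"phantom_seed": str(spec.seed)}).astype_tag(spec.dtype)
    truth = LabelMap(Volume3D(labels, spec.spacing, {}), names)
    return EmbryoPhantom(volume=vol, truth=truth, body_mask=body_mask, spec=spec)


# organ layout loosely matching a mid-gestation (E14.5) mouse embryo atlas
_E14_5_ORGANS = (
    # name, centre (fractions of dims), radii (fractions), intensity, label
    ("liver", (0.60, 0.54, 0.50), (0.14, 0.15, 0.13), 160, 1),
    ("lungs", (0.40, 0.36, 0.40), (0.06, 0.07, 0.06), 140, 2),
    ("kidney", (0.72, 0.36, 0.36), (0.045, 0.045, 0.045), 150, 3),
    ("adrenal gland", (0.72, 0.36, 0.60), (0.03, 0.03, 0.03), 170, 4),
    ("stomach lumen", (0.52, 0.26, 0.68), (0.045, 0.045, 0.04), 30, 5),
    ("lateral brain ventricle", (0.20, 0.40, 0.36), (0.045, 0.05, 0.045), 25, 6),
    ("mesencephalic vesicle", (0.20, 0.40, 0.64), (0.05, 0.05, 0.045), 35, 7),
    ("dorsal root ganglia", (0.44, 0.70, 0.50), (0.04, 0.04, 0.04), 155, 8),
    ("trigeminal ganglion", (0.24, 0.64, 0.50), (0.035, 0.035, 0.035), 145, 9),
    ("humerus primordium", (0.42, 0.52, 0.74), (0.035, 0.035, 0.05), 180, 10),
)


def e14_5_spec(
    dims: tuple[int, int, int] = (80, 80, 80),
    noise_sd: float = 2.0,
    seed: int = 0,
    organ_scale: dict[str, float] | None = None,
) -> PhantomSpec:
    """Preset 10-organ phantom named after the mid-gestation atlas structures.

    ``organ_scale`` multiplies the radii of named organs (isotropically), e.g.
    ``{"liver": 0.7 ** (1 / 3)}`` shrinks the liver volume by 30%.
    """
    organs = []
    for name, cf, rf, intensity, lab in _E14_5_ORGANS:
        scale = (organ_scale or {}).get(name, 1.0)
        organs.append(OrganSpec(
            name,
            center=tuple(c * n for c, n in zip(cf, dims)),
            radii=tuple(max(2.0, r * n * scale) for r, n in zip(rf, dims)),
            intensity=intensity, label_id=lab))
    return PhantomSpec(dims=dims, organs=tuple(organs), noise_sd=noise_sd,
                       seed=seed)


def five_organ_spec(
    dims: tuple[int, int, int] = (72, 72, 72),
    noise_sd: float = 15.0,
    seed: int = 0,
) -> PhantomSpec:
    """Five well-resolved organs (radii >= 5 voxels at the default size).

    Organ-to-body contrast is 45 grey levels at the default noise sd 15 —
    i.e. exactly 3x the noise — which is the regime a segmentation engine
    must handle on an averaged volume. One organ (``brain``) is darker than
    the body, standing in for fluid-filled structures.
    """
    n = np.asarray(dims, dtype=np.float64)
    mk = lambda name, c, r, i, lab: OrganSpec(  # noqa: E731
        name, tuple(np.asarray(c) * n), tuple(np.asarray(r) * n), i, lab)
    organs = (
        mk("liver", (0.60, 0.55, 0.50), (0.14, 0.15, 0.13), 135, 1),
        mk("lungs", (0.38, 0.36, 0.40), (0.09, 0.10, 0.09), 150, 2),
        mk("kidney", (0.70, 0.34, 0.34), (0.08, 0.08, 0.08), 165, 3),
        mk("stomach", (0.50, 0.26, 0.68), (0.08, 0.08, 0.075), 180, 4),
        mk("brain", (0.22, 0.42, 0.50), (0.10, 0.09, 0.09), 45, 5),
    )
    return PhantomSpec(dims=dims, organs=organs, noise_sd=noise_sd, seed=seed)


def random_embryo_spec(
    seed: int,
    dims: tuple[int, int, int] = (56, 56, 56),
    noise_sd_max_fraction: float = 0.10,
) -> PhantomSpec:
    """Random pose/size/intensity phantom for robustness sweeps.

    The body ellipsoid gets a random centre, radii and rotation; noise sd is
    drawn up to ``noise_sd_max_fraction`` of the specimen-to-background
    dynamic range, emulating a well-exposed contrast-stained scan.
    """
    rng = np.random.default_rng(seed)
    dims_arr = np.asarray(dims, dtype=np.float64)
    radii = rng.uniform(0.16, 0.30, size=3) * dims_arr
    margin = radii.max() + 1.0  # rotated ellipsoid stays within max semi-axis
    lo = np.full(3, margin)
    hi = dims_arr - 1 - lo
    center = np.where(hi > lo, rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi)),
                      (dims_arr - 1) / 2)
    bg = float(rng.uniform(0, 10))
    intensity = float(rng.uniform(130, 220))
    body = OrganSpec(
        "body", center=tuple(center), radii=tuple(radii),
        intensity=intensity, label_id=255,
        angles=tuple(rng.uniform(0, np.pi, size=3)))
    return PhantomSpec(
        dims=dims, body=body, organs=(), background_intensity=bg,
        noise_sd=float(rng.uniform(0.0, noise_sd_max_fraction *
                                   (intensity - bg))),
        seed=seed)


# ---------------------------------------------------------------------------
# heatmap phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobSpec:
    center: tuple[int, int, int]
    radius: float
    t_value: float


def make_heatmap_phantom(
    dims: tuple[int, int, int],
    blobs: list[BlobSpec],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[Volume3D, list[dict]]:
    """Spherical regions of constant t on a zero background.

    Returns the heatmap and a ground-truth record per blob: its voxel count,
    t value and bounding box, for self-consistency checks against
    :func:`embryotk.heatmap_analysis.connected_regions`.
    """
    t = np.zeros(dims, dtype=np.float32)
    truth = []
    for blob in blobs:
        for c, n in zip(blob.center, dims):
            if not 0 <= c < n:
                raise PhantomSpecError(f"blob centre {blob.center} outside {dims}")
        m = ellipsoid_mask(dims, blob.center, (blob.radius,) * 3)
        t[m] = blob.t_value
        zs, ys, xs = np.nonzero(m)
        truth.append({"t_value": blob.t_value, "voxel_count": int(m.sum()),
                      "bbox": (int(zs.min()), int(zs.max()) + 1,
                               int(ys.min()), int(ys.max()) + 1,
                               int(xs.min()), int(xs.max()) + 1)})
    return Volume3D(t, spacing, {}), truth


def random_sparse_heatmap(
    seed: int,
    dims: tuple[int, int, int] = (28, 28, 28),
    fill_fraction: float = 0.03,
) -> Volume3D:
    """Sparse random +/- t-values for connected-component oracle sweeps."""
    rng = np.random.default_rng(seed)
    t = np.zeros(dims, dtype=np.float32)
    mask = rng.random(dims) < fill_fraction
    vals = rng.normal(0.0, 4.0, size=dims).astype(np.float32)
    vals[np.abs(vals) < 0.5] = 0.5  # keep strictly non-zero where masked
    t[mask] = vals[mask]
    return Volume3D(t, (1.0, 1.0, 1.0), {})


# ---------------------------------------------------------------------------
# displacement phantoms
# ---------------------------------------------------------------------------

def make_displacement_phantom(
    dims: tuple[int, int, int],
    kind: str = "zero",
    amplitude: float = 0.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0),
    center: tuple[float, float, float] | None = None,
    radius: float | None = None,
    outer_radius: float | None = None,
):
    """Analytic displacement fields for testing label propagation.

    Kinds (all vectors in micrometres, pull-back convention):

    * ``zero`` — identity transform.
    * ``translation`` — constant ``amplitude * direction`` everywhere.
    * ``radial`` — smooth expansion about ``center``: magnitude
      ``amplitude * (r/R) * exp(1 - r/R)``, zero at the centre, peaking at
      exactly ``r = radius``.
    * ``scaling`` — locally linear ``d(p) = amplitude * (p - c)`` inside
      ``radius``, tapering smoothly to zero at ``outer_radius``; under
      pull-back this rescales a centred label region by ``1/(1+amplitude)``
      per axis, i.e. an exactly known volume factor ``(1+amplitude)^-3``.
    """
    from .atlas_tools import DisplacementField

    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    sp = np.asarray(spacing, dtype=np.float64)
    if kind == "zero":
        return DisplacementField(np.zeros(dims + (3,), dtype=np.float32),
                                 tuple(spacing), {"kind": "zero"})
    if kind == "translation":
        d = np.asarray(direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("translation direction must be non-zero")
        vec = (amplitude * d / norm).astype(np.float32)
        field = np.broadcast_to(vec, dims + (3,)).copy()
        return DisplacementField(field, tuple(spacing), {"kind": "translation"})

    if center is None:
        center = tuple((n - 1) / 2.0 for n in dims)
    phys = (np.indices(dims, dtype=np.float64)
            * sp[:, None, None, None]
            - (np.asarray(center) * sp)[:, None, None, None])
    r = np.sqrt(np.sum(phys ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r > 0, phys / np.maximum(r, 1e-12), 0.0)

    if kind == "radial":
        if radius is None or radius <= 0:
            raise ValueError("radial kind requires a positive radius")
        mag = amplitude * (r / radius) * np.exp(1.0 - r / radius)
        field = np.moveaxis(mag * unit, 0, -1).astype(np.float32)
        return DisplacementField(field, tuple(spacing), {"kind": "radial"})

    if kind == "scaling":
        if radius is None or outer_radius is None or outer_radius <= radius:
            raise ValueError("scaling kind requires radius < outer_radius")
        taper = np.clip((outer_radius - r) / (outer_radius - radius), 0.0, 1.0)
        taper = np.where(r <= radius, 1.0, taper)
        field = np.moveaxis(amplitude * phys * taper, 0, -1).astype(np.float32)
        return DisplacementField(field, tuple(spacing), {"kind": "scaling"})

    raise ValueError(f"unknown displacement kind {kind!r}")
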