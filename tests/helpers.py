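"""Independent brute-force oracles shared across the test suite.

These deliberately use naive algorithms (explicit loops, stack-based flood
fill, exhaustive scans) so they share no code path with the implementations
they check.
"""

from __future__ import annotations

import numpy as np


def otsu_exhaustive(data: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance scan over all interior bin edges."""
    flat = np.asarray(data, dtype=np.float64).ravel()
    counts, edges = np.histogram(flat, bins=n_bins, range=(flat.min(), flat.max()))
    best_score, best_edge = -np.inf, None
    for k in range(1, n_bins):  # split: bins [0, k) vs [k, n_bins)
        w0 = counts[:k].sum()
        w1 = counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        centers = 0.5 * (edges[:-1] + edges[1:])
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_edge = score, edges[k]
    return float(best_edge)


def block_mean_loop(data: np.ndarray, factor: int) -> np.ndarray:
    """Explicit triple-loop block mean (trailing partial blocks dropped)."""
    nz, ny, nx = (n // factor for n in data.shape)
    out = np.empty((nz, ny, nx), dtype=np.float64)
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                block = data[k * factor:(k + 1) * factor,
                             j * factor:(j + 1) * factor,
                             i * factor:(i + 1) * factor]
                out[k, j, i] = block.astype(np.float64).mean()
    return out


def mip_loop(data: np.ndarray) -> np.ndarray:
    """Explicit per-pixel maximum over z."""
    nz, ny, nx = data.shape
    out = np.zeros((ny, nx), dtype=np.float64)
    for j in range(ny):
        for i in range(nx):
            m = data[0, j, i]
            for k in range(1, nz):
                if data[k, j, i] > m:
                    m = data[k, j, i]
            out[j, i] = m
    return out


def flood_fill_regions(t: np.ndarray) -> list[dict]:
    """Stack-based 26-neighbour connected components, split by sign.

    Returns one record per component: voxel count, mean t, sign.
    """
    t = np.asarray(t, dtype=np.float64)
    visited = np.zeros(t.shape, dtype=bool)
    nz, ny, nx = t.shape
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    records = []
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if t[z0, y0, x0] == 0 or visited[z0, y0, x0]:
                    continue
                sign = 1.0 if t[z0, y0, x0] > 0 else -1.0
                stack = [(z0, y0, x0)]
                visited[z0, y0, x0] = True
                voxels = []
                while stack:
                    z, y, x = stack.pop()
                    voxels.append((z, y, x))
                    for dz, dy, dx in offsets:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                            continue
                        if visited[zz, yy, xx] or t[zz, yy, xx] * sign <= 0:
                            continue
                        visited[zz, yy, xx] = True
                        stack.append((zz, yy, xx))
                vals = [t[v] for v in voxels]
                records.append({
                    "voxel_count": len(voxels),
                    "mean_t": float(np.mean(vals)),
                    "sign": "positive" if sign > 0 else "negative",
                })
    return records


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


def random_volume(rng: np.random.Generator, shape, dtype_tag: str):
    """Random test volume of the given dtype with random spacing."""
    if dtype_tag == "uint8":
        data = rng.integers(0, 256, shape, dtype=np.uint8)
    elif dtype_tag == "uint16":
        data = rng.integers(0, 65536, shape, dtype=np.uint16)
    else:
        data = rng.normal(0, 100, shape).astype(np.float32)
    spacing = tuple(float(s) for s in rng.uniform(0.5, 30.0, 3))
    return data, spacing
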