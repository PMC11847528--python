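"""Exact streamline-to-voxel rasterization.

A streamline is a polyline in world mm.  After mapping its vertices to
continuous voxel-index space (voxel ``i`` owns the half-open box
``[i, i+1)``), each segment is traversed exactly: the parameter values at
which the segment crosses integer planes along any axis are enumerated and
sorted, and the voxel between two consecutive crossings is read off at the
interval midpoint.  This produces the exact set of voxels whose boxes the
segment passes through — the same set grid-stepping traversal algorithms
produce — without a sampling-density parameter.

The kernels are numba-jitted; the batch entry point processes a whole
tractogram at once and returns a CSR-like (values, offsets) pair of linear
voxel ids so that downstream code can reuse one rasterization across many
lesions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import GeometryError, GridSpec, Tractogram

__all__ = [
    "rasterize_polyline",
    "rasterize_tractogram",
    "streamline_voxels",
]


@njit(cache=True)
def _segment_voxels(p0, p1, nx, ny, nz, out, n_out):
    """Append linear ids of voxels traversed by segment p0->p1 (index space)."""
    d = p1 - p0
    # Collect crossing parameters with integer planes on each axis.
    n_cross = 0
    for a in range(3):
        lo = min(p0[a], p1[a])
        hi = max(p0[a], p1[a])
        n_cross += int(np.floor(hi) - np.ceil(lo)) + 1
    ts = np.empty(n_cross + 2, dtype=np.float64)
    m = 0
    ts[m] = 0.0
    m += 1
    for a in range(3):
        if d[a] == 0.0:
            continue
        lo = min(p0[a], p1[a])
        hi = max(p0[a], p1[a])
        k = np.ceil(lo)
        while k <= hi:
            t = (k - p0[a]) / d[a]
            if 0.0 < t < 1.0:
                ts[m] = t
                m += 1
            k += 1.0
    ts[m] = 1.0
    m += 1
    ts_sorted = np.sort(ts[:m])
    prev_lin = -1
    for i in range(m - 1):
        tm = 0.5 * (ts_sorted[i] + ts_sorted[i + 1])
        x = int(np.floor(p0[0] + tm * d[0]))
        y = int(np.floor(p0[1] + tm * d[1]))
        z = int(np.floor(p0[2] + tm * d[2]))
        if x < 0 or y < 0 or z < 0 or x >= nx or y >= ny or z >= nz:
            continue
        lin = (x * ny + y) * nz + z
        if lin != prev_lin:
            out[n_out] = lin
            n_out += 1
            prev_lin = lin
    return n_out


@njit(cache=True)
def _polyline_voxels(points, nx, ny, nz):
    """Unique linear voxel ids traversed by one polyline (index space)."""
    n_seg = points.shape[0] - 1
    # Upper bound on traversed voxels: crossings + 1 per segment.
    bound = 0
    for i in range(n_seg):
        for a in range(3):
            bound += int(abs(points[i + 1, a] - points[i, a])) + 2
        bound += 2
    out = np.empty(bound, dtype=np.int64)
    n_out = 0
    for i in range(n_seg):
        n_out = _segment_voxels(points[i], points[i + 1], nx, ny, nz, out, n_out)
    return np.unique(out[:n_out])


@njit(cache=True)
def _batch_voxels(points, poly_offsets, nx, ny, nz):
    n_lines = poly_offsets.shape[0] - 1
    chunks = []
    total = 0
    for i in range(n_lines):
        vox = _polyline_voxels(points[poly_offsets[i] : poly_offsets[i + 1]], nx, ny, nz)
        chunks.append(vox)
        total += vox.shape[0]
    values = np.empty(total, dtype=np.int64)
    offsets = np.empty(n_lines + 1, dtype=np.int64)
    offsets[0] = 0
    pos = 0
    for i in range(n_lines):
        vox = chunks[i]
        values[pos : pos + vox.shape[0]] = vox
        pos += vox.shape[0]
        offsets[i + 1] = pos
    return values, offsets


def rasterize_polyline(points_world: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Unique linear voxel ids traversed by one world-mm polyline.

    Ids index ``grid.shape`` in C order; voxels outside the grid are dropped.
    """
    pts = grid.world_to_index(np.asarray(points_world, dtype=float))
    nx, ny, nz = grid.shape
    return _polyline_voxels(np.ascontiguousarray(pts), nx, ny, nz)


def rasterize_tractogram(t: Tractogram, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize every streamline of a tractogram.

    Returns
    -------
    values, offsets
        ``values[offsets[k]:offsets[k+1]]`` are the sorted unique linear
        voxel ids traversed by streamline ``k``.
    """
    if len(t) == 0:
        return np.empty(0, dtype=np.int64), np.zeros(1, dtype=np.int64)
    counts = np.array([s.shape[0] for s in t.streamlines])
    poly_offsets = np.zeros(len(counts) + 1, dtype=np.int64)
    np.cumsum(counts, out=poly_offsets[1:])
    pts_world = np.concatenate(t.streamlines, axis=0)
    pts = np.ascontiguousarray(grid.world_to_index(pts_world))
    nx, ny, nz = grid.shape
    return _batch_voxels(pts, poly_offsets, nx, ny, nz)


def streamline_voxels(points_world: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Voxel (i, j, k) triples traversed by a polyline, shape (n, 3)."""
    lin = rasterize_polyline(points_world, grid)
    return np.stack(np.unravel_index(lin, grid.shape), axis=1)


def mask_hits(values: np.ndarray, offsets: np.ndarray, mask_flat: np.ndarray) -> np.ndarray:
    """Per-streamline boolean: does the streamline traverse a True voxel?

    Operates on the CSR pair from :func:`rasterize_tractogram`.
    """
    n = offsets.shape[0] - 1
    if values.size == 0:
        return np.zeros(n, dtype=bool)
    hit_vox = mask_flat[values]
    # reduceat needs care with empty rows (offsets[i] == offsets[i+1]).
    starts = offsets[:-1]
    nonempty = starts < offsets[1:]
    out = np.zeros(n, dtype=bool)
    if nonempty.any():
        safe_starts = np.minimum(starts[nonempty], values.size - 1)
        red = np.logical_or.reduceat(hit_vox, safe_starts)
        out[nonempty] = red
    return out
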