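"""Exact voxel-centre-to-point distance bucketing on large grids.

The confusion-table construction needs, for every voxel centre of a grid
with up to ~10^7 cells, the radius bucket of its exact Euclidean distance
to the nearest point of a cloud — "exact" meaning the true point distance,
not a centre-to-centre approximation. Querying a k-d tree per voxel is
prohibitively slow on planar-heavy vegetation scenes, so the field is
computed in three exact stages:

1. An exact Euclidean distance transform on the occupancy grid gives, per
   voxel centre, the distance ``e`` to the nearest *occupied cell centre*
   and that cell's identity. With ``h`` the half voxel diagonal, the true
   point distance ``d`` is bracketed by ``e - h <= d <= u``, where ``u``
   is the (exact) distance to a representative point stored in the
   nearest occupied cell.
2. Any voxel whose bracket ``[e - h, u]`` does not straddle a requested
   radius has its bucket determined exactly; no further work.
3. Straddling voxels get their exact distance: near-field ones through a
   compiled cell-list search bounded by ``u``, far-field ones through a
   batched dual-tree nearest-neighbour query.

Every stage is exact, so the resulting bucket indices equal those of a
brute-force per-voxel scan (property-tested against one).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["bucketize_grid_distances", "grid_dims", "voxel_axes"]

# near-field search window cap (in cells); beyond this the dual-tree path wins
_RMAX = 6


def grid_dims(bounds: np.ndarray, voxel_size: float) -> np.ndarray:
    span = bounds[1] - bounds[0]
    return np.maximum(np.ceil(span / voxel_size - 1e-9).astype(np.int64), 1)


def voxel_axes(bounds: np.ndarray, dims: np.ndarray, voxel_size: float) -> list[np.ndarray]:
    return [bounds[0][a] + (np.arange(dims[a]) + 0.5) * voxel_size for a in range(3)]


@njit(cache=True)
def _nn_cell_search(qx, qy, qz, qi, qj, qk, ub,
                    indptr, order, px, py, pz,
                    nx, ny, nz, ox, oy, oz, vox):
    """Exact NN distance per query, searching cells within the ub window.

    ``ub`` must be an achieved point distance (so the true minimum is
    <= ub and the window of cells within ub of the query suffices).
    """
    out = np.empty(len(qx))
    half_diag = 0.8660254037844387 * vox
    for t in range(len(qx)):
        best = ub[t]
        R = int(np.ceil(best / vox)) + 1
        i0 = max(qi[t] - R, 0); i1 = min(qi[t] + R, nx - 1)
        j0 = max(qj[t] - R, 0); j1 = min(qj[t] + R, ny - 1)
        k0 = max(qk[t] - R, 0); k1 = min(qk[t] + R, nz - 1)
        for ci in range(i0, i1 + 1):
            cx = ox + (ci + 0.5) * vox
            dx = qx[t] - cx
            for cj in range(j0, j1 + 1):
                cy = oy + (cj + 0.5) * vox
                dy = qy[t] - cy
                dxy2 = dx * dx + dy * dy
                if dxy2 > (best + half_diag) * (best + half_diag):
                    continue
                base = (ci * ny + cj) * nz
                for ck in range(k0, k1 + 1):
                    cz = oz + (ck + 0.5) * vox
                    dz = qz[t] - cz
                    cdist2 = dxy2 + dz * dz
                    lim = best + half_diag
                    if cdist2 > lim * lim:
                        continue
                    for s in range(indptr[base + ck], indptr[base + ck + 1]):
                        p = order[s]
                        ddx = qx[t] - px[p]
                        ddy = qy[t] - py[p]
                        ddz = qz[t] - pz[p]
                        d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                        if d < best:
                            best = d
        out[t] = best
    return out


def _cell_csr(flat: np.ndarray, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(flat, kind="stable").astype(np.int64)
    counts = np.bincount(flat, minlength=n_cells)
    indptr = np.zeros(n_cells + 1, np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order


def bucketize_grid_distances(
    points: np.ndarray,
    bounds: np.ndarray,
    voxel_size: float,
    radii: np.ndarray,
) -> np.ndarray:
    """Per-voxel bucket of the exact NN point distance against sorted radii.

    Returns, for every voxel of the grid over ``bounds`` (C order), the
    index of the first radius >= the exact distance from the voxel centre
    to the nearest point (``len(radii)`` if the distance exceeds every
    radius, including the empty-cloud case where it is infinite).
    """
    bounds = np.asarray(bounds, np.float64).reshape(2, 3)
    radii = np.asarray(radii, np.float64)
    dims = grid_dims(bounds, voxel_size)
    n_vox = int(dims.prod())
    if len(points) == 0:
        return np.full(n_vox, len(radii), np.int64)
    vox = float(voxel_size)
    h = vox * np.sqrt(3.0) / 2.0

    idx = np.floor((points - bounds[0]) / vox).astype(np.int64)
    idx = np.clip(idx, 0, dims - 1)
    flat = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]

    occ = np.zeros(n_vox, bool)
    occ[flat] = True
    # deterministic representative point per occupied cell (lowest point index)
    rep_of_cell = np.full(n_vox, -1, np.int64)
    rep_of_cell[flat[::-1]] = np.arange(len(points) - 1, -1, -1)

    e, (fi, fj, fk) = ndimage.distance_transform_edt(
        ~occ.reshape(tuple(dims)), sampling=vox, return_indices=True
    )
    e = e.ravel()
    ff = (fi.ravel().astype(np.int64) * dims[1] + fj.ravel()) * dims[2] + fk.ravel()
    del fi, fj, fk

    # stage 2a: centre-to-centre bracket e +/- h decides most voxels without
    # touching point coordinates at all
    b_lo = np.searchsorted(radii, np.maximum(e - h, 0.0), side="left")
    bucket = b_lo.astype(np.int64)
    cand = np.flatnonzero(b_lo != np.searchsorted(radii, e + h, side="left"))
    if len(cand) == 0:
        return bucket

    # stage 2b: exact distance to the nearest cell's representative point
    # tightens the upper bound for the candidates
    ax = voxel_axes(bounds, dims, vox)
    ci, cj, ck = np.unravel_index(cand, tuple(dims))
    qx = ax[0][ci]; qy = ax[1][cj]; qz = ax[2][ck]
    rp = points[rep_of_cell[ff[cand]]]
    u = np.sqrt((qx - rp[:, 0]) ** 2 + (qy - rp[:, 1]) ** 2 + (qz - rp[:, 2]) ** 2)
    del rp
    still = b_lo[cand] != np.searchsorted(radii, u, side="left")
    amb_idx = cand[still]
    if len(amb_idx) == 0:
        return bucket
    ub = u[still]
    qx, qy, qz = qx[still], qy[still], qz[still]
    qi, qj, qk = ci[still].astype(np.int64), cj[still].astype(np.int64), ck[still].astype(np.int64)

    # stage 3: exact distances for the band-straddling remainder
    near = ub <= _RMAX * vox
    if np.any(near):
        indptr, order = _cell_csr(flat, n_vox)
        d_near = _nn_cell_search(
            qx[near], qy[near], qz[near],
            qi[near], qj[near], qk[near],
            ub[near],
            indptr, order,
            np.ascontiguousarray(points[:, 0]),
            np.ascontiguousarray(points[:, 1]),
            np.ascontiguousarray(points[:, 2]),
            int(dims[0]), int(dims[1]), int(dims[2]),
            float(bounds[0][0]), float(bounds[0][1]), float(bounds[0][2]),
            vox,
        )
        bucket[amb_idx[near]] = np.searchsorted(radii, d_near, side="left")
    if np.any(~near):
        from sklearn.neighbors import KDTree  # batched dual-tree far-field NN

        tree = KDTree(points, leaf_size=32)
        q = np.column_stack([qx[~near], qy[~near], qz[~near]])
        d_far, _ = tree.query(q, k=1, dualtree=True)
        bucket[amb_idx[~near]] = np.searchsorted(radii, d_far[:, 0], side="left")
    return bucket
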