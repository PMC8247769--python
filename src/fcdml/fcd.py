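"""Functional connectivity density (FCD) mapping.

For each in-mask voxel, FCD counts its suprathreshold Pearson
correlations (R > r_threshold, strictly positive) with other in-mask
voxels:

* gFCD — connections to *all* other voxels (global degree);
* lFCD — size of the spatially contiguous cluster grown from the voxel
  through 26-connected neighbors whose correlation with the seed exceeds
  the threshold (local hub size), minus the seed itself;
* lrFCD — gFCD − lFCD, the distant (long-range) connections.

The voxel-voxel correlation matrix is evaluated as a single symmetric
rank-k BLAS product of the standardized series at desk scale, or in
voxel blocks when the mask is too large to materialize N x N; counts
are identical either way.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.linalg import blas as _blas

from .types import BoldRun, BrainMask, FCDMap

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "standardized_series",
    "correlation_matrix",
    "compute_gfcd",
    "compute_lfcd",
    "compute_lrfcd",
    "compute_fcd_maps",
    "smooth_map",
]

# Above this mask size the full correlation matrix is evaluated in row
# blocks instead of one symmetric product (memory contract O(N*block)).
_FULL_MATRIX_MAX_VOXELS = 9000


def standardized_series(run: BoldRun, mask: BrainMask) -> np.ndarray:
    """In-mask series, demeaned and scaled to unit norm (N x T, float32).

    Zero-variance voxels become all-zero rows, so their correlation with
    anything is 0 and they form no connections (degree 0 by convention).
    """
    if run.n_frames < 3:
        raise ValueError("need at least 3 frames for correlation")
    mask.check_grid(run.shape3d, run.affine)
    X = run.data[mask.data].astype(np.float32)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    X[nz] /= norms[nz]
    X[~nz] = 0.0
    return np.ascontiguousarray(X)


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Full N x N correlation matrix from standardized series (float32)."""
    C = _blas.ssyrk(1.0, X, lower=0)  # upper triangle
    C = C + np.triu(C, 1).T
    return C


def _degree_from_blocks(X: np.ndarray, r_threshold: float, block: int) -> np.ndarray:
    """Suprathreshold degree per voxel without materializing N x N."""
    N = X.shape[0]
    deg = np.zeros(N, dtype=np.int64)
    for start in range(0, N, block):
        stop = min(start + block, N)
        C = X[start:stop] @ X.T  # b x N
        hits = C > r_threshold
        # remove self-correlation (r = 1 > threshold) for non-degenerate rows
        rows = np.arange(start, stop)
        self_hits = hits[np.arange(stop - start), rows]
        deg[start:stop] += hits.sum(axis=1) - self_hits
    return deg


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _grow_all_tri(hits, nbr_idx, nbr_cnt):  # pragma: no cover - compiled
        # hits holds the strict upper triangle of the suprathreshold
        # adjacency; symmetric lookups index (min, max).
        N = hits.shape[0]
        out = np.zeros(N, dtype=np.int64)
        visited = np.full(N, -1, dtype=np.int64)
        stack = np.empty(N, dtype=np.int64)
        for s in range(N):
            visited[s] = s
            stack[0] = s
            top = 1
            size = 0
            while top > 0:
                top -= 1
                v = stack[top]
                for k in range(nbr_cnt[v]):
                    u = nbr_idx[v, k]
                    if visited[u] != s:
                        if u < s:
                            con = hits[u, s]
                        elif u > s:
                            con = hits[s, u]
                        else:
                            con = False
                        if con:
                            visited[u] = s
                            stack[top] = u
                            top += 1
                            size += 1
            out[s] = size
        return out

    @numba.njit(cache=True)
    def _grow_all(adj, nbr_idx, nbr_cnt):  # pragma: no cover - compiled
        N = adj.shape[0]
        out = np.zeros(N, dtype=np.int64)
        visited = np.full(N, -1, dtype=np.int64)
        stack = np.empty(N, dtype=np.int64)
        for s in range(N):
            visited[s] = s
            stack[0] = s
            top = 1
            size = 0
            while top > 0:
                top -= 1
                v = stack[top]
                for k in range(nbr_cnt[v]):
                    u = nbr_idx[v, k]
                    if visited[u] != s and adj[s, u]:
                        visited[u] = s
                        stack[top] = u
                        top += 1
                        size += 1
            out[s] = size
        return out


def _grow_all_python(adj, nbr_idx, nbr_cnt):
    """Pure-python fallback mirror of the compiled region growth."""
    N = adj.shape[0]
    out = np.zeros(N, dtype=np.int64)
    for s in range(N):
        seen = {s}
        stack = [s]
        while stack:
            v = stack.pop()
            for u in nbr_idx[v, : nbr_cnt[v]]:
                u = int(u)
                if u not in seen and adj[s, u]:
                    seen.add(u)
                    stack.append(u)
        out[s] = len(seen) - 1
    return out


def _neighbor_table(mask: BrainMask, connectivity: int = 26):
    """Spatial neighbor lists (mask-index space) for each in-mask voxel."""
    idx = np.argwhere(mask.data)
    N = idx.shape[0]
    lut = -np.ones(mask.data.shape, dtype=np.int64)
    lut[tuple(idx.T)] = np.arange(N)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    K = len(offsets)
    nbr_idx = np.zeros((N, K), dtype=np.int64)
    nbr_cnt = np.zeros(N, dtype=np.int64)
    shape = mask.data.shape
    for off in offsets:
        pos = idx + np.array(off)
        ok = np.all((pos >= 0) & (pos < np.array(shape)), axis=1)
        tgt = np.full(N, -1, dtype=np.int64)
        tgt[ok] = lut[tuple(pos[ok].T)]
        has = tgt >= 0
        rows = np.flatnonzero(has)
        nbr_idx[rows, nbr_cnt[rows]] = tgt[rows]
        nbr_cnt[rows] += 1
    return nbr_idx, nbr_cnt


def _map_from_masked(values: np.ndarray, mask: BrainMask) -> np.ndarray:
    out = np.zeros(mask.data.shape, dtype=values.dtype)
    out[mask.data] = values
    return out


def compute_gfcd(
    run: BoldRun,
    mask: BrainMask,
    r_threshold: float = 0.6,
    block_size: int = 2048,
    _X: Optional[np.ndarray] = None,
    _C: Optional[np.ndarray] = None,
) -> FCDMap:
    """Global FCD: per-voxel count of suprathreshold connections to all voxels."""
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (0, 1)")
    X = standardized_series(run, mask) if _X is None else _X
    N = X.shape[0]
    if _C is not None:
        hits = _C > r_threshold
        deg = hits.sum(axis=1) - np.diag(hits)
    elif N <= _FULL_MATRIX_MAX_VOXELS:
        C = correlation_matrix(X)
        hits = C > r_threshold
        deg = hits.sum(axis=1) - np.diag(hits)
    else:
        deg = _degree_from_blocks(X, r_threshold, block_size)
    return FCDMap(
        _map_from_masked(deg.astype(np.int64), mask),
        kind="gFCD",
        r_threshold=r_threshold,
        affine=mask.affine,
        subject_id=run.subject_id,
        session=run.session,
    )


def compute_lfcd(
    run: BoldRun,
    mask: BrainMask,
    r_threshold: float = 0.6,
    mode: str = "grow",
    connectivity: int = 26,
    _X: Optional[np.ndarray] = None,
    _C: Optional[np.ndarray] = None,
) -> FCDMap:
    """Local FCD by seed-correlation region growing (default) or neighbor count.

    ``grow``: starting from each seed voxel, spatially 26-connected voxels
    are admitted when their correlation *with the seed* exceeds the
    threshold; growth proceeds only through admitted voxels, so the local
    cluster is contiguous and contains the seed. lFCD = cluster size - 1.

    ``neighbors``: simple count of immediate suprathreshold spatial
    neighbors.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (0, 1)")
    X = standardized_series(run, mask) if _X is None else _X
    N = X.shape[0]
    C = _C
    if C is None:
        if N > _FULL_MATRIX_MAX_VOXELS:
            raise NotImplementedError(
                "lFCD currently requires the in-memory correlation matrix; "
                f"mask has {N} voxels (limit {_FULL_MATRIX_MAX_VOXELS})"
            )
        C = correlation_matrix(X)
    adj = C > r_threshold
    np.fill_diagonal(adj, False)
    nbr_idx, nbr_cnt = _neighbor_table(mask, connectivity)
    if mode == "grow":
        grow = _grow_all if _HAVE_NUMBA else _grow_all_python
        counts = grow(adj, nbr_idx, nbr_cnt)
    elif mode == "neighbors":
        counts = np.zeros(N, dtype=np.int64)
        for k in range(nbr_idx.shape[1]):
            has = nbr_cnt > k
            rows = np.flatnonzero(has)
            counts[rows] += adj[rows, nbr_idx[rows, k]]
    else:
        raise ValueError(f"unknown lFCD mode {mode!r}")
    return FCDMap(
        _map_from_masked(counts, mask),
        kind="lFCD",
        r_threshold=r_threshold,
        affine=mask.affine,
        subject_id=run.subject_id,
        session=run.session,
    )


def compute_lrfcd(gfcd: FCDMap, lfcd: FCDMap) -> FCDMap:
    """Long-range FCD = gFCD − lFCD voxelwise (distant connections)."""
    if gfcd.kind != "gFCD" or lfcd.kind != "lFCD":
        raise ValueError("compute_lrfcd expects a gFCD and an lFCD map")
    if gfcd.subject_id != lfcd.subject_id or gfcd.session != lfcd.session:
        raise ValueError("maps belong to different runs")
    if gfcd.data.shape != lfcd.data.shape or not np.allclose(
        gfcd.affine, lfcd.affine
    ):
        raise ValueError("grid mismatch between gFCD and lFCD")
    if gfcd.r_threshold != lfcd.r_threshold:
        raise ValueError("threshold mismatch between gFCD and lFCD")
    data = gfcd.data - lfcd.data
    if data.min() < 0:
        # cannot happen with the seed-correlation growth criterion
        raise ValueError("negative long-range count; inconsistent input maps")
    return FCDMap(
        data,
        kind="lrFCD",
        r_threshold=gfcd.r_threshold,
        affine=gfcd.affine,
        subject_id=gfcd.subject_id,
        session=gfcd.session,
    )


def compute_fcd_maps(
    run: BoldRun,
    mask: BrainMask,
    r_threshold: float = 0.6,
    lfcd_mode: str = "grow",
    connectivity: int = 26,
    fwhm_mm: float = 0.0,
    voxel_size_mm: Optional[float] = None,
) -> dict[str, FCDMap]:
    """All three FCD maps of one run, sharing one correlation evaluation.

    The symmetric correlation product is evaluated once as an upper
    triangle and both the global degree counts and the local region
    growth are read from it, so this entry point is substantially
    cheaper than calling the per-map functions separately (the counts
    are identical). When ``fwhm_mm`` > 0 the returned maps are
    additionally smoothed (raw integer counts satisfy the
    gFCD = lFCD + lrFCD identity before smoothing).
    """
    X = standardized_series(run, mask)
    N = X.shape[0]
    if N <= _FULL_MATRIX_MAX_VOXELS and lfcd_mode == "grow" and _HAVE_NUMBA:
        Ctri = _blas.ssyrk(1.0, X, lower=0)  # strict upper + diagonal
        hits = Ctri > r_threshold
        diag = np.diag(hits).copy()
        np.fill_diagonal(hits, False)
        deg = hits.sum(axis=1) + hits.sum(axis=0)
        nbr_idx, nbr_cnt = _neighbor_table(mask, connectivity)
        counts = _grow_all_tri(hits, nbr_idx, nbr_cnt)
        g = FCDMap(
            _map_from_masked(deg.astype(np.int64), mask), kind="gFCD",
            r_threshold=r_threshold, affine=mask.affine,
            subject_id=run.subject_id, session=run.session,
        )
        l = FCDMap(
            _map_from_masked(counts, mask), kind="lFCD",
            r_threshold=r_threshold, affine=mask.affine,
            subject_id=run.subject_id, session=run.session,
        )
    else:
        C = correlation_matrix(X) if N <= _FULL_MATRIX_MAX_VOXELS else None
        g = compute_gfcd(run, mask, r_threshold, _X=X, _C=C)
        l = compute_lfcd(
            run, mask, r_threshold, mode=lfcd_mode, connectivity=connectivity,
            _X=X, _C=C,
        )
    lr = compute_lrfcd(g, l)
    maps = {"gFCD": g, "lFCD": l, "lrFCD": lr}
    if fwhm_mm and fwhm_mm > 0:
        vs = voxel_size_mm if voxel_size_mm is not None else run.voxel_size_mm[0]
        maps = {k: smooth_map(m, fwhm_mm, mask, vs) for k, m in maps.items()}
    return maps


def smooth_map(
    fcd_map: FCDMap,
    fwhm_mm: float,
    mask: BrainMask,
    voxel_size_mm: float,
) -> FCDMap:
    """Masked-normalized Gaussian smoothing of an FCD map.

    The kernel mass is renormalized inside the mask so smoothing neither
    leaks counts out of the brain nor dilutes edge voxels; a constant map
    stays constant and an interior cluster's total count is conserved.
    fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return fcd_map
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    m = mask.data.astype(np.float64)
    num = ndimage.gaussian_filter(fcd_map.data.astype(np.float64) * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(num)
    inside = mask.data & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return FCDMap(
        out,
        kind=fcd_map.kind,
        r_threshold=fcd_map.r_threshold,
        affine=fcd_map.affine,
        subject_id=fcd_map.subject_id,
        session=fcd_map.session,
        smoothed_fwhm_mm=fwhm_mm,
    )
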