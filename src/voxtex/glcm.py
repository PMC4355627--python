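"""Per-voxel gray-level co-occurrence matrices.

Two local variants are provided, both anchored on a neighborhood around
each voxel ``V`` of a quantized volume:

* full-3D ("VGLCM-3D"): co-occurrences are counted over all ordered voxel
  pairs ``(u, u + O)`` with *both* endpoints inside the Euclidean ball of
  radius ``R`` around ``V`` (clipped to the grid), for every 3D offset
  ``O`` with Chebyshev norm <= d.

* three orthogonal planes ("VGLCM-TOP-3D"): the same construction is run
  independently inside the axial, sagittal and coronal disks of radius
  ``R`` through ``V``, with the offsets restricted to each plane.  Each
  plane's matrix is normalized on its own; texture features (not the
  matrices) are averaged across planes downstream.

Counts for one offset and its negation are mirror images, and the full
offset set is closed under negation, so every local matrix is symmetric
and its normalized form is a proper joint probability over ordered
gray-level pairs.

The map-level functions are vectorized: for each *relative* displacement
pair ``(s, s + O)`` that fits inside the neighborhood ball, the
contribution to every voxel's matrix is accumulated with a single shifted
array operation, which makes whole-volume computation practical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantize import QuantizedVolume

#: axis spanned by each anatomical plane, in (y, x, z) array order.
#: "fixed" is the out-of-plane axis; "inplane" the two axes of the disk.
PLANES = {
    "axial": {"fixed": 2, "inplane": (0, 1)},      # z fixed; y-x plane
    "sagittal": {"fixed": 1, "inplane": (0, 2)},   # x fixed; y-z plane
    "coronal": {"fixed": 0, "inplane": (1, 2)},    # y fixed; x-z plane
}
PLANE_NAMES = ("axial", "sagittal", "coronal")


def offsets_3d(d: int) -> np.ndarray:
    """All nonzero 3D integer offsets with Chebyshev norm <= d.

    Returns an array of shape ((2d+1)^3 - 1, 3); the set is closed under
    negation.  At d=1 there are 26 offsets, at d=2 there are 124.
    """
    if d < 1:
        raise ValueError(f"offset distance d must be >= 1, got {d}")
    r = np.arange(-d, d + 1)
    grid = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[np.any(grid != 0, axis=1)]


def offsets_plane(d: int, plane: str) -> np.ndarray:
    """All nonzero in-plane offsets with Chebyshev norm <= d.

    The out-of-plane component is zero.  (2d+1)^2 - 1 offsets per plane:
    8 at d=1, 24 at d=2.
    """
    if d < 1:
        raise ValueError(f"offset distance d must be >= 1, got {d}")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANE_NAMES}")
    r = np.arange(-d, d + 1)
    ab = np.stack(np.meshgrid(r, r, indexing="ij"), axis=-1).reshape(-1, 2)
    ab = ab[np.any(ab != 0, axis=1)]
    out = np.zeros((len(ab), 3), dtype=int)
    i0, i1 = PLANES[plane]["inplane"]
    out[:, i0] = ab[:, 0]
    out[:, i1] = ab[:, 1]
    return out


def _ball_points(R: int) -> np.ndarray:
    """Lattice points with squared Euclidean norm <= R^2 (3D)."""
    r = np.arange(-R, R + 1)
    g = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
    return g[(g**2).sum(axis=1) <= R * R]


def _disk_points(R: int, plane: str) -> np.ndarray:
    """In-plane lattice points with squared norm <= R^2, embedded in 3D."""
    r = np.arange(-R, R + 1)
    g = np.stack(np.meshgrid(r, r, indexing="ij"), axis=-1).reshape(-1, 2)
    g = g[(g**2).sum(axis=1) <= R * R]
    out = np.zeros((len(g), 3), dtype=int)
    i0, i1 = PLANES[plane]["inplane"]
    out[:, i0] = g[:, 0]
    out[:, i1] = g[:, 1]
    return out


def spherical_neighborhood(center, R: int, dims) -> np.ndarray:
    """In-bounds voxels within Euclidean distance R of ``center``.

    Membership is decided on integer squared distances (<= R^2), so no
    floating-point radius comparison is involved.  Always contains the
    center.  Raises if the center is outside the grid.
    """
    center = np.asarray(center, dtype=int)
    dims = tuple(dims)
    if np.any(center < 0) or np.any(center >= np.array(dims)):
        raise ValueError(f"center {tuple(center)} outside grid of dims {dims}")
    pts = center + _ball_points(int(R))
    ok = np.all((pts >= 0) & (pts < np.array(dims)), axis=1)
    return pts[ok]


def plane_disk(center, R: int, dims, plane: str) -> np.ndarray:
    """In-bounds voxels of the radius-R disk through ``center`` on ``plane``.

    The out-of-plane coordinate is fixed at the center's.
    """
    center = np.asarray(center, dtype=int)
    dims = tuple(dims)
    if np.any(center < 0) or np.any(center >= np.array(dims)):
        raise ValueError(f"center {tuple(center)} outside grid of dims {dims}")
    pts = center + _disk_points(int(R), plane)
    ok = np.all((pts >= 0) & (pts < np.array(dims)), axis=1)
    return pts[ok]


@dataclass
class LocalGLCM:
    """One voxel's (or ROI's) co-occurrence matrix.

    ``counts`` are raw ordered-pair counts summed over all offsets;
    ``n_pairs`` their total.  ``p`` is the normalized matrix (all zeros
    when degenerate, i.e. no pairs were found).
    """

    counts: np.ndarray
    n_pairs: int

    @property
    def degenerate(self) -> bool:
        return self.n_pairs == 0

    @property
    def p(self) -> np.ndarray:
        if self.n_pairs == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.n_pairs)


def roi_glcm(qvol: QuantizedVolume, region: np.ndarray, offsets: np.ndarray) -> LocalGLCM:
    """Co-occurrence matrix of a voxel region, summed over an offset set.

    Counts ordered pairs ``(u, u + O)`` with both endpoints inside the
    region.  This is the direct (per-region) construction; the map-level
    functions below agree with it voxel for voxel but are vectorized.
    """
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise ValueError("region is empty")
    offsets = np.asarray(offsets, dtype=int)
    if offsets.size == 0:
        raise ValueError("offset set is empty")
    Ng = qvol.Ng
    gray = {tuple(u): int(qvol.data[tuple(u)]) for u in region}
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for off in offsets:
        for u in region:
            v = tuple(u + off)
            if v in gray:
                counts[gray[tuple(u)] - 1, gray[v] - 1] += 1
    return LocalGLCM(counts=counts, n_pairs=int(counts.sum()))


@dataclass
class GLCMMap:
    """Per-voxel co-occurrence counts for a whole volume.

    ``counts`` has shape (Ny, Nx, Nz, Ng, Ng); ``n_pairs`` the per-voxel
    pair totals; ``valid`` marks voxels that are in-mask and yielded at
    least one pair.
    """

    counts: np.ndarray
    n_pairs: np.ndarray
    valid: np.ndarray
    Ng: int

    def probabilities(self) -> np.ndarray:
        """Normalized matrices, NaN at invalid voxels."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / self.n_pairs[..., None, None].astype(float)
        p[~self.valid] = np.nan
        return p

    def local(self, voxel) -> LocalGLCM:
        v = tuple(voxel)
        return LocalGLCM(counts=self.counts[v], n_pairs=int(self.n_pairs[v]))


def _displacement_pairs(points: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """All (s, t = s + O) with s and t neighborhood members, per offset.

    Returns an array of shape (M, 2, 3).  Both pair endpoints must lie in
    the neighborhood: pairs straddling its boundary are not counted.
    """
    member = {tuple(p) for p in points}
    pairs = []
    for off in offsets:
        for s in points:
            t = s + off
            if tuple(t) in member:
                pairs.append((s, t))
    return np.asarray(pairs, dtype=int).reshape(-1, 2, 3)


def _accumulate_counts(
    q: np.ndarray, Ng: int, pairs: np.ndarray, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter-accumulate per-voxel GLCM counts over displacement pairs.

    For a displacement pair (s, t) anchored at voxel V, a co-occurrence
    (q[V+s], q[V+t]) is counted iff V+s and V+t are in bounds (grid
    clipping) and, when a mask is given, V, V+s, V+t are all in-mask.
    """
    dims = q.shape
    nvox = q.size
    vox_index = np.arange(nvox, dtype=np.int64).reshape(dims)
    qz = q.astype(np.int64) - 1  # 0-based gray codes
    flat = np.zeros(Ng * Ng * nvox, dtype=np.int64)
    lins: list[np.ndarray] = []
    pending = 0
    for s, t in pairs:
        lo = [max(0, -int(s[k]), -int(t[k])) for k in range(3)]
        hi = [dims[k] - max(0, int(s[k]), int(t[k])) for k in range(3)]
        if any(h <= l for l, h in zip(lo, hi)):
            continue
        center = tuple(slice(lo[k], hi[k]) for k in range(3))
        at_s = tuple(slice(lo[k] + int(s[k]), hi[k] + int(s[k])) for k in range(3))
        at_t = tuple(slice(lo[k] + int(t[k]), hi[k] + int(t[k])) for k in range(3))
        code = qz[at_s] * Ng + qz[at_t]
        lin = code.ravel() * nvox + vox_index[center].ravel()
        if mask is not None:
            keep = (mask[center] & mask[at_s] & mask[at_t]).ravel()
            lin = lin[keep]
        lins.append(lin)
        pending += lin.size
        if pending >= 8_000_000:  # bound scratch memory for large pair sets
            flat += np.bincount(np.concatenate(lins), minlength=flat.size)
            lins, pending = [], 0
    if lins:
        flat += np.bincount(np.concatenate(lins), minlength=flat.size)
    counts = flat.reshape(Ng, Ng, nvox)
    counts = np.moveaxis(counts, -1, 0).reshape(*dims, Ng, Ng)
    n_pairs = counts.sum(axis=(-2, -1))
    return counts, n_pairs


def vglcm3d_map(
    qvol: QuantizedVolume, R: int = 2, d: int = 1, mask: np.ndarray | None = None
) -> GLCMMap:
    """Spherical-neighborhood co-occurrence matrices at every voxel.

    For each (in-mask) voxel, counts ordered pairs (u, u+O) with both
    endpoints inside the radius-R ball around the voxel (clipped to the
    grid and mask), summed over the full 3D offset set of distance d.
    """
    if R < 1:
        raise ValueError(f"neighborhood radius R must be >= 1, got {R}")
    q = np.asarray(qvol.data)
    pairs = _displacement_pairs(_ball_points(R), offsets_3d(d))
    m = None if mask is None else np.asarray(mask, bool)
    counts, n_pairs = _accumulate_counts(q, qvol.Ng, pairs, m)
    valid = n_pairs > 0
    if m is not None:
        valid &= m
    return GLCMMap(counts=counts, n_pairs=n_pairs, valid=valid, Ng=qvol.Ng)


def vglcm_top3d_map(
    qvol: QuantizedVolume, R: int = 2, d: int = 1, mask: np.ndarray | None = None
) -> dict[str, GLCMMap]:
    """Per-plane co-occurrence matrices at every voxel (axial, sagittal, coronal).

    Each plane uses the radius-R disk through the voxel on that plane with
    the in-plane offset set of distance d, and is normalized independently
    of the other planes.
    """
    if R < 1:
        raise ValueError(f"neighborhood radius R must be >= 1, got {R}")
    q = np.asarray(qvol.data)
    m = None if mask is None else np.asarray(mask, bool)
    out: dict[str, GLCMMap] = {}
    for plane in PLANE_NAMES:
        pairs = _displacement_pairs(_disk_points(R, plane), offsets_plane(d, plane))
        counts, n_pairs = _accumulate_counts(q, qvol.Ng, pairs, m)
        valid = n_pairs > 0
        if m is not None:
            valid &= m
        out[plane] = GLCMMap(counts=counts, n_pairs=n_pairs, valid=valid, Ng=qvol.Ng)
    return out
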