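"""Independent brute-force references used by the tests.

Deliberately written as literal enumerations — nested loops over voxel
pairs and term-by-term feature sums — sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

# out-of-plane axis per plane, (y, x, z) array order
_FIXED_AXIS = {"axial": 2, "sagittal": 1, "coronal": 0}


def oracle_neighborhood(center, R, dims, plane=None):
    """All in-bounds voxels within squared distance R^2 of center; for a
    plane, restricted to the slice through the center."""
    out = []
    for y in range(dims[0]):
        for x in range(dims[1]):
            for z in range(dims[2]):
                dy, dx, dz = y - center[0], x - center[1], z - center[2]
                if plane is not None:
                    if (y, x, z)[_FIXED_AXIS[plane]] != center[_FIXED_AXIS[plane]]:
                        continue
                if dy * dy + dx * dx + dz * dz <= R * R:
                    out.append((y, x, z))
    return out


def oracle_local_counts(q, Ng, region, d, plane=None):
    """GLCM counts for one region: every ordered pair of region voxels
    whose displacement is a valid offset (nonzero, Chebyshev norm <= d,
    and in-plane when a plane is given) contributes one count."""
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for u in region:
        for v in region:
            dd = (v[0] - u[0], v[1] - u[1], v[2] - u[2])
            if dd == (0, 0, 0):
                continue
            if max(abs(dd[0]), abs(dd[1]), abs(dd[2])) > d:
                continue
            if plane is not None and dd[_FIXED_AXIS[plane]] != 0:
                continue
            counts[q[u] - 1, q[v] - 1] += 1
    return counts


def oracle_vglcm_counts(q, Ng, R, d, mode, mask=None):
    """Per-voxel GLCM counts for a whole (small) volume.

    mode "full3d" returns {voxel: counts}; mode "top3d" returns
    {voxel: {plane: counts}}.  Out-of-mask voxels are dropped from
    neighborhoods and skipped as centers.
    """
    dims = q.shape
    result = {}
    for y in range(dims[0]):
        for x in range(dims[1]):
            for z in range(dims[2]):
                if mask is not None and not mask[y, x, z]:
                    continue
                c = (y, x, z)
                if mode == "full3d":
                    region = oracle_neighborhood(c, R, dims)
                    if mask is not None:
                        region = [u for u in region if mask[u]]
                    result[c] = oracle_local_counts(q, Ng, region, d)
                else:
                    per_plane = {}
                    for plane in ("axial", "sagittal", "coronal"):
                        region = oracle_neighborhood(c, R, dims, plane=plane)
                        if mask is not None:
                            region = [u for u in region if mask[u]]
                        per_plane[plane] = oracle_local_counts(q, Ng, region, d, plane)
                    result[c] = per_plane
    return result


def oracle_features(p):
    """Term-by-term evaluation of the eight texture features."""
    Ng = p.shape[0]
    f1 = f2 = f3 = f5 = 0.0
    mu_x = mu_y = 0.0
    for i in range(1, Ng + 1):
        for j in range(1, Ng + 1):
            pij = p[i - 1, j - 1]
            f1 += i * j * pij
            f2 += pij / (1 + (i - j) ** 2)
            f3 += pij * pij
            f5 += abs(i - j) * pij
            mu_x += i * pij
            mu_y += j * pij
    var_x = var_y = cov = f6 = 0.0
    for i in range(1, Ng + 1):
        for j in range(1, Ng + 1):
            pij = p[i - 1, j - 1]
            var_x += (i - mu_x) ** 2 * pij
            var_y += (j - mu_y) ** 2 * pij
            cov += (i - mu_x) * (j - mu_y) * pij
            f6 += (i - mu_x) ** 2 * pij
    f4 = cov / math.sqrt(var_x * var_y) if var_x > 0 and var_y > 0 else 0.0
    pxy = {}
    for i in range(1, Ng + 1):
        for j in range(1, Ng + 1):
            pxy[i + j] = pxy.get(i + j, 0.0) + p[i - 1, j - 1]
    f7 = sum(k * v for k, v in pxy.items())
    f8 = -sum(v * math.log(v) for v in pxy.values() if v > 0)
    return {"f1": f1, "f2": f2, "f3": f3, "f4": f4, "f5": f5, "f6": f6, "f7": f7, "f8": f8}
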