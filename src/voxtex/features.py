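"""Haralick-style texture features of a normalized co-occurrence matrix.

Eight scalar features are computed from the normalized matrix
``p(i, j)`` over gray levels ``i, j in {1..Ng}``, with row/column
marginals ``p_x(i) = sum_j p(i,j)`` (and ``p_y`` symmetric), marginal
means ``mu_x, mu_y``, variances ``sigma_x^2, sigma_y^2`` and the
gray-level-sum distribution ``p_{x+y}(k) = sum_{i+j=k} p(i,j)``:

    f1 autocorrelation       sum_ij i*j*p(i,j)
    f2 homogeneity           sum_ij p(i,j) / (1 + (i-j)^2)
    f3 energy                sum_ij p(i,j)^2
    f4 correlation           sum_ij (i-mu_x)(j-mu_y) p(i,j) / (sigma_x sigma_y)
    f5 dissimilarity         sum_ij |i-j| p(i,j)
    f6 variance (sum sq.)    sum_ij (i-mu_x)^2 p(i,j)
    f7 sum average           sum_{k=2}^{2Ng} k p_{x+y}(k)
    f8 sum entropy           -sum_k p_{x+y}(k) log p_{x+y}(k),  0 log 0 = 0

Homogeneity uses the inverse-difference-moment kernel 1/(1+(i-j)^2); the
1/(1+|i-j|) variant and the entropy log base are switchable since both
conventions circulate in the literature.  Correlation on a matrix with a
zero marginal variance (e.g. a constant neighborhood) is defined as 0 —
a constant patch carries no correlation signal — so downstream statistics
stay finite.

For the three-orthogonal-planes method each feature is computed per plane
and the per-voxel feature is the arithmetic mean over the axial, sagittal
and coronal values; matrices themselves are never averaged across planes.
"""

from __future__ import annotations

import numpy as np

from .glcm import GLCMMap, LocalGLCM, PLANE_NAMES

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8")

FEATURE_LABELS = {
    "f1": "autocorrelation",
    "f2": "homogeneity",
    "f3": "energy",
    "f4": "correlation",
    "f5": "dissimilarity",
    "f6": "sum of squares: variance",
    "f7": "sum average",
    "f8": "sum entropy",
}


def _features_from_p(
    p: np.ndarray,
    requested: tuple[str, ...],
    homogeneity_form: str = "squared",
    log_base: float | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized feature evaluation on p of shape (..., Ng, Ng)."""
    Ng = p.shape[-1]
    i = np.arange(1, Ng + 1, dtype=float)
    ii = i[:, None]  # row level i
    jj = i[None, :]  # column level j
    out: dict[str, np.ndarray] = {}

    px = p.sum(axis=-1)  # (..., Ng)
    py = p.sum(axis=-2)
    mu_x = (px * i).sum(axis=-1)
    mu_y = (py * i).sum(axis=-1)
    need_sumdist = any(f in requested for f in ("f7", "f8"))
    if need_sumdist:
        # p_{x+y}(k), k = 2..2Ng: sum over anti-diagonals i+j=k
        k_of = (ii + jj).astype(int)  # (Ng, Ng)
        pxy = np.zeros(p.shape[:-2] + (2 * Ng + 1,))
        for k in range(2, 2 * Ng + 1):
            sel = k_of == k
            pxy[..., k] = p[..., sel].sum(axis=-1)

    if "f1" in requested:
        out["f1"] = (p * (ii * jj)).sum(axis=(-2, -1))
    if "f2" in requested:
        if homogeneity_form == "squared":
            w = 1.0 / (1.0 + (ii - jj) ** 2)
        elif homogeneity_form == "abs":
            w = 1.0 / (1.0 + np.abs(ii - jj))
        else:
            raise ValueError(f"unknown homogeneity_form {homogeneity_form!r}")
        out["f2"] = (p * w).sum(axis=(-2, -1))
    if "f3" in requested:
        out["f3"] = (p**2).sum(axis=(-2, -1))
    if "f4" in requested:
        var_x = (px * i**2).sum(axis=-1) - mu_x**2
        var_y = (py * i**2).sum(axis=-1) - mu_y**2
        cov = (p * (ii * jj)).sum(axis=(-2, -1)) - mu_x * mu_y
        denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_y, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            f4 = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        out["f4"] = f4
    if "f5" in requested:
        out["f5"] = (p * np.abs(ii - jj)).sum(axis=(-2, -1))
    if "f6" in requested:
        out["f6"] = (p * (ii - mu_x[..., None, None]) ** 2).sum(axis=(-2, -1))
    if "f7" in requested:
        k = np.arange(2 * Ng + 1, dtype=float)
        out["f7"] = (pxy * k).sum(axis=-1)
    if "f8" in requested:
        with np.errstate(invalid="ignore", divide="ignore"):
            logp = np.where(pxy > 0, np.log(np.where(pxy > 0, pxy, 1.0)), 0.0)
        h = -(pxy * logp).sum(axis=-1)
        if log_base is not None:
            h = h / np.log(log_base)
        out["f8"] = h
    return out


def compute_features(
    glcm: LocalGLCM | np.ndarray,
    requested=FEATURE_NAMES,
    homogeneity_form: str = "squared",
    log_base: float | None = None,
) -> dict[str, float]:
    """Texture features of a single normalized GLCM.

    Accepts a ``LocalGLCM`` or a normalized probability matrix directly.
    A degenerate matrix (no pairs) yields NaN for every feature.
    """
    requested = tuple(requested)
    unknown = set(requested) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    if isinstance(glcm, LocalGLCM):
        if glcm.degenerate:
            return {f: float("nan") for f in requested}
        p = glcm.p
    else:
        p = np.asarray(glcm, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {p.shape}")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"matrix is not normalized (sum={total})")
    vals = _features_from_p(p, requested, homogeneity_form, log_base)
    return {f: float(vals[f]) for f in requested}


def feature_maps(
    glcm_maps: GLCMMap | dict[str, GLCMMap],
    method: str,
    requested=FEATURE_NAMES,
    homogeneity_form: str = "squared",
    log_base: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-voxel texture maps from a whole-volume GLCM computation.

    method "full3d": features of the single spherical-neighborhood matrix.
    method "top3d": arithmetic mean of each feature over the axial,
    sagittal and coronal matrices; a voxel is valid only where all three
    planes produced a non-degenerate matrix.  Invalid voxels are NaN.
    """
    requested = tuple(requested)
    if method == "full3d":
        if not isinstance(glcm_maps, GLCMMap):
            raise ValueError("full3d expects a single GLCMMap")
        p = glcm_maps.probabilities()
        vals = _features_from_p(np.nan_to_num(p), requested, homogeneity_form, log_base)
        return {
            f: np.where(glcm_maps.valid, vals[f], np.nan) for f in requested
        }
    if method == "top3d":
        if not isinstance(glcm_maps, dict) or set(glcm_maps) != set(PLANE_NAMES):
            got = sorted(glcm_maps) if isinstance(glcm_maps, dict) else type(glcm_maps)
            raise ValueError(f"top3d expects GLCMMaps for planes {PLANE_NAMES}, got {got}")
        valid = np.logical_and.reduce([glcm_maps[pl].valid for pl in PLANE_NAMES])
        acc = {f: 0.0 for f in requested}
        for pl in PLANE_NAMES:
            p = glcm_maps[pl].probabilities()
            vals = _features_from_p(np.nan_to_num(p), requested, homogeneity_form, log_base)
            for f in requested:
                acc[f] = acc[f] + vals[f]
        return {f: np.where(valid, acc[f] / 3.0, np.nan) for f in requested}
    raise ValueError(f"unknown method {method!r}; expected 'top3d' or 'full3d'")
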