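"""Voxelwise group comparison of texture maps.

At every voxel a linear model ``value ~ intercept + group + covariates``
is fitted across subjects and the group effect is tested with the partial
(extra-sum-of-squares) F statistic against the covariate-only reduced
model, with (g - 1, n - g - c) degrees of freedom for g groups and c
covariates.  An F-test rather than a t-test is used so that texture
increases and decreases are treated symmetrically and more than two
groups are supported.  Multiple comparisons over voxels are handled by
Benjamini-Hochberg FDR, and the thresholded map can be cleaned with a
cluster-extent filter (26-connected components by default).

The entry point is the :class:`VoxelwiseGroupComparison` model object;
``fit()`` returns a :class:`StatMapResults` carrying the F, p and q maps,
degrees of freedom, significance maps and a cluster table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def fdr_correct(p_map: np.ndarray, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up over all finite voxels of a p-value map.

    Returns ``(q_map, sig)``: per-voxel adjusted values (NaN where the
    input was invalid) and the boolean map of voxels with q < threshold.
    """
    p_map = np.asarray(p_map, dtype=float)
    valid = np.isfinite(p_map)
    q_map = np.full(p_map.shape, np.nan)
    sig = np.zeros(p_map.shape, dtype=bool)
    if not valid.any():
        import warnings

        warnings.warn("no valid p-values to correct; empty significance map")
        return q_map, sig
    pv = p_map[valid]
    _, q, _, _ = multipletests(pv, alpha=q_threshold, method="fdr_bh")
    q_map[valid] = q
    sig[valid] = q < q_threshold
    return q_map, sig


def cluster_extent_filter(
    sig: np.ndarray,
    k_min: int,
    connectivity: int = 26,
    f_map: np.ndarray | None = None,
):
    """Drop connected components smaller than ``k_min`` voxels.

    Returns the filtered boolean map and a cluster table (size, centroid,
    and — when an F map is supplied — the peak-F voxel and value), sorted
    by descending size.  Coordinates are 0-based (y, x, z) voxel indices.
    """
    sig = np.asarray(sig, dtype=bool)
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    labels, n = ndimage.label(sig, structure=_CONNECTIVITY[connectivity])
    rows = []
    keep = np.zeros_like(sig)
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < k_min:
            continue
        keep |= comp
        coords = np.argwhere(comp)
        row = {
            "size": size,
            "centroid_y": float(coords[:, 0].mean()),
            "centroid_x": float(coords[:, 1].mean()),
            "centroid_z": float(coords[:, 2].mean()),
        }
        if f_map is not None:
            fv = np.asarray(f_map)[comp]
            peak = coords[int(np.nanargmax(fv))]
            row.update(
                peak_y=int(peak[0]), peak_x=int(peak[1]), peak_z=int(peak[2]),
                peak_F=float(np.nanmax(fv)),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("size", ascending=False).reset_index(drop=True)
    return keep, table


class VoxelwiseGroupComparison:
    """Voxelwise linear model for a stack of subject texture maps.

    Parameters
    ----------
    maps : array (n_subjects, Ny, Nx, Nz)
        One texture map per subject, all on the same grid.  NaN marks
        invalid voxels; a voxel enters the analysis only if it is valid
        (finite) for every subject and its response is not constant.
    groups : sequence of length n_subjects
        Group label per subject (2 or more groups).
    covariates : DataFrame or array (n_subjects, c), optional
        Nuisance regressors (e.g. age, sex coded 0/1).  Mean-centered
        internally before fitting.
    """

    def __init__(self, maps, groups, covariates=None):
        maps = np.asarray(maps, dtype=float)
        if maps.ndim != 4:
            raise ValueError(f"maps must be (n_subjects, Ny, Nx, Nz), got {maps.shape}")
        self.maps = maps
        self.n_subjects = maps.shape[0]
        self.grid = maps.shape[1:]
        groups = np.asarray(groups)
        if groups.shape[0] != self.n_subjects:
            raise ValueError("groups length must match number of maps")
        self.group_labels, self.group_codes = np.unique(groups, return_inverse=True)
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        if covariates is None:
            cov = np.empty((self.n_subjects, 0))
            self.covariate_names: list[str] = []
        elif isinstance(covariates, pd.DataFrame):
            cov = covariates.to_numpy(dtype=float)
            self.covariate_names = list(covariates.columns)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            self.covariate_names = [f"x{k}" for k in range(cov.shape[1])]
        if cov.shape[0] != self.n_subjects:
            raise ValueError("covariate rows must match number of maps")
        self.covariates = cov - cov.mean(axis=0, keepdims=True)
        n_params = 1 + (self.n_groups - 1) + self.covariates.shape[1]
        if self.n_subjects <= n_params:
            raise ValueError(
                f"{self.n_subjects} subjects cannot identify {n_params} parameters"
            )

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, maps, covariates=None):
        """Build from a cohort table (column ``group``) and a map stack.

        ``covariates`` names columns of the cohort table to adjust for.
        """
        cov = cohort[list(covariates)] if covariates else None
        return cls(maps, cohort["group"].to_numpy(), cov)

    def _design(self):
        # full model: intercept + (g-1) group dummies + centered covariates
        dummies = np.zeros((self.n_subjects, self.n_groups - 1))
        for k in range(1, self.n_groups):
            dummies[:, k - 1] = self.group_codes == k
        ones = np.ones((self.n_subjects, 1))
        X_full = np.hstack([ones, dummies, self.covariates])
        X_red = np.hstack([ones, self.covariates])
        return X_full, X_red

    def fit(self) -> "StatMapResults":
        """Fit the per-voxel GLM and return F/p maps for the group effect."""
        X_full, X_red = self._design()
        n = self.n_subjects
        df_num = self.n_groups - 1
        df_den = n - X_full.shape[1]

        Y = self.maps.reshape(n, -1)
        valid = np.isfinite(Y).all(axis=0)
        # constant responses carry no information and break the F ratio
        valid[valid] &= np.ptp(Y[:, valid], axis=0) > 0
        Yv = Y[:, valid]

        Qf, _ = np.linalg.qr(X_full)
        Qr, _ = np.linalg.qr(X_red)
        total = (Yv**2).sum(axis=0)
        rss_full = total - ((Qf.T @ Yv) ** 2).sum(axis=0)
        rss_red = total - ((Qr.T @ Yv) ** 2).sum(axis=0)
        rss_full = np.clip(rss_full, 0.0, None)
        extra = np.clip(rss_red - rss_full, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (extra / df_num) / (rss_full / df_den)
        # a perfect full-model fit: infinite F if the group term did the
        # explaining, 0 if the covariates alone already fit perfectly
        F = np.where(rss_full > 0, F, np.where(extra > 0, np.inf, 0.0))
        p = stats.f.sf(F, df_num, df_den)

        F_map = np.full(Y.shape[1], np.nan)
        p_map = np.full(Y.shape[1], np.nan)
        F_map[valid] = F
        p_map[valid] = p
        return StatMapResults(
            model=self,
            F=F_map.reshape(self.grid),
            p=p_map.reshape(self.grid),
            df=(df_num, df_den),
            valid=valid.reshape(self.grid),
        )


@dataclass
class StatMapResults:
    """Result of a voxelwise group comparison.

    Carries the per-voxel F and p maps and degrees of freedom; FDR
    correction and cluster filtering are applied on demand.
    """

    model: VoxelwiseGroupComparison
    F: np.ndarray
    p: np.ndarray
    df: tuple[int, int]
    valid: np.ndarray
    _fdr_cache: dict = field(default_factory=dict, repr=False)

    def fdr(self, q_threshold: float = 0.05):
        """(q_map, sig) after Benjamini-Hochberg over valid voxels."""
        if q_threshold not in self._fdr_cache:
            self._fdr_cache[q_threshold] = fdr_correct(self.p, q_threshold)
        return self._fdr_cache[q_threshold]

    def significance_map(
        self, q_threshold: float = 0.05, extent: int = 0, connectivity: int = 26
    ):
        """Binary map after FDR threshold and cluster-extent filter,
        plus the surviving-cluster table."""
        _, sig = self.fdr(q_threshold)
        if extent > 1:
            return cluster_extent_filter(sig, extent, connectivity, f_map=self.F)
        _, table = cluster_extent_filter(sig, 1, connectivity, f_map=self.F)
        return sig, table

    def summary(self, q_threshold: float = 0.05, extent: int = 0) -> str:
        q_map, _ = self.fdr(q_threshold)
        sig, table = self.significance_map(q_threshold, extent)
        lines = [
            "Voxelwise group comparison (partial F-test)",
            "=" * 46,
            f"subjects:            {self.model.n_subjects}",
            f"groups:              {list(map(str, self.model.group_labels))}",
            f"covariates:          {self.model.covariate_names or 'none'}",
            f"degrees of freedom:  F({self.df[0]}, {self.df[1]})",
            f"voxels analyzed:     {int(self.valid.sum())} of {self.valid.size}",
            f"FDR threshold:       q < {q_threshold}"
            + (f", extent >= {extent}" if extent else ""),
            f"significant voxels:  {int(sig.sum())}",
            f"clusters:            {len(table)}",
        ]
        if len(table):
            lines.append("")
            lines.append(table.to_string(index=False))
        return "\n".join(lines)
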