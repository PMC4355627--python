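"""Volume and table I/O.

Volumes are stored as NIfTI-1 (.nii / .nii.gz) and held in memory as plain
numpy arrays indexed ``(y, x, z)``: axis 0 runs anterior-posterior (y),
axis 1 left-right (x) and axis 2 inferior-superior (z).  The mapping from
the file is deterministic: the array is taken in the file's stored axis
order, so files written by this package round-trip bit-exactly; for
externally produced files the caller is responsible for reorienting to this
convention first (e.g. with ``nibabel.as_closest_canonical``).  All
user-facing voxel coordinates (lesion centers, cluster peaks) are 0-based
array indices in this convention.

Invalid voxels in texture/statistic maps are written as NaN; the NIfTI
header description records this sentinel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel written for voxels with no valid texture value
BACKGROUND_FILL = np.nan


@dataclass
class Volume:
    """A 3D scalar field on a regular grid, indexed ``(y, x, z)``."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical spacing per axis in mm (from the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def read_volume(path, mask_path=None):
    """Read a NIfTI volume (and optional binary mask) into memory.

    Returns ``Volume`` or, when ``mask_path`` is given, a tuple
    ``(Volume, mask)`` where the mask is a boolean array of identical shape.

    Raises ``ValueError`` for non-3D input or volume/mask shape mismatch.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} from {path}")
    vol = Volume(data=data, affine=img.affine)
    if mask_path is None:
        return vol
    mimg = nib.load(str(mask_path))
    mdata = np.asanyarray(mimg.dataobj)
    if mdata.shape != data.shape:
        raise ValueError(
            f"mask shape {mdata.shape} does not match volume shape {data.shape}"
        )
    mask = mdata > 0
    return vol, mask


def write_volume(vol: Volume, path, dtype=None) -> None:
    """Write a ``Volume`` to NIfTI, preserving its affine."""
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def write_texture_map(data: np.ndarray, path, affine=None, valid=None) -> None:
    """Write a per-voxel texture (or statistic) map to NIfTI.

    Voxels flagged invalid in ``valid`` (or already NaN) are written as the
    NaN background sentinel; the header description notes the convention so
    downstream statistics never silently ingest degenerate voxels.
    """
    out = np.asarray(data, dtype=np.float32).copy()
    if valid is not None:
        out[~np.asarray(valid, bool)] = BACKGROUND_FILL
        if not valid.any():
            warnings.warn("texture map has no valid voxels; writing all-background file")
    img = nib.Nifti1Image(out, np.eye(4) if affine is None else affine)
    img.header["descrip"] = b"voxtex map; invalid voxels = NaN"
    nib.save(img, str(path))


def load_cohort_table(path, require_files: bool = True) -> pd.DataFrame:
    """Load a cohort CSV: subject_id, group, volume_path plus covariates.

    Checks that subject ids are unique, every referenced volume exists, and
    that at least two groups with >= 2 subjects each are present (the
    minimum for a group comparison).
    """
    df = pd.read_csv(path)
    required = {"subject_id", "group", "volume_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id: {dup!r}")
    counts = df.groupby("group").size()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            f"need at least two groups with >=2 subjects each, got sizes {counts.to_dict()}"
        )
    if require_files:
        from pathlib import Path

        for p in df["volume_path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"volume listed in cohort table not found: {p}")
    return df
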