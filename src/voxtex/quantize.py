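"""Gray-level quantization.

Co-occurrence statistics are computed on a small number of gray levels
``Ng`` (typically 8 or 16).  A volume whose intensities occupy ``{1..Qg}``
is mapped onto ``{1..Ng}`` by the monotone linear rule

    q(I) = round((I - 1) * (Ng - 1) / (Qg - 1)) + 1

with round-half-away-from-zero, which sends 1 -> 1 and Qg -> Ng.
``standardize_intensity`` provides the preceding step for raw volumes:
a robust percentile-linear rescale onto [1, Qg].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Volume


@dataclass
class QuantizedVolume:
    """A 3D integer volume with gray levels in ``{1..Ng}``.

    ``Qg`` records the gray-level count of the volume the quantization was
    applied to (provenance only).
    """

    data: np.ndarray
    Ng: int
    Qg: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"quantized volume must be 3D, got {self.data.shape}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape


def standardize_intensity(
    vol: Volume | np.ndarray,
    mask: np.ndarray | None = None,
    p_low: float = 1.0,
    p_high: float = 99.0,
    Qg: int = 256,
) -> Volume:
    """Linearly rescale intensities so the [p_low, p_high] percentile range
    (computed inside the mask) maps onto [1, Qg]; values outside are clipped.

    The affine rescale makes the result invariant to global intensity
    scaling/offset between subjects, a cheap stand-in for scanner intensity
    standardization.  Raises ``ValueError`` on a constant volume.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=float)
    affine = vol.affine if isinstance(vol, Volume) else np.eye(4)
    sel = data[np.asarray(mask, bool)] if mask is not None else data
    lo, hi = np.percentile(sel, [p_low, p_high])
    if hi <= lo:
        raise ValueError("volume has no dynamic range inside the mask (constant?)")
    scaled = 1.0 + (data - lo) * (Qg - 1.0) / (hi - lo)
    return Volume(data=np.clip(scaled, 1.0, float(Qg)), affine=affine)


def quantize_volume(vol: Volume | np.ndarray, Ng: int, Qg: int = 256) -> QuantizedVolume:
    """Map a volume with values in [1, Qg] onto integer levels {1..Ng}.

    Monotone, endpoint-preserving (1 -> 1, Qg -> Ng); rounding is
    half-away-from-zero so bin edges are deterministic across platforms.
    Raises ``ValueError`` if Ng < 2, Qg < Ng, or any value falls outside
    [1, Qg] (the first offending voxel is reported).
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if Ng < 2:
        raise ValueError(f"Ng must be >= 2, got {Ng}")
    if Qg < Ng:
        raise ValueError(f"Qg ({Qg}) must be >= Ng ({Ng})")
    bad = (data < 1) | (data > Qg)
    if bad.any():
        idx = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(
            f"intensity {data[idx]} at voxel {idx} outside [1, {Qg}]; "
            "standardize intensities first"
        )
    scaled = (np.asarray(data, dtype=float) - 1.0) * (Ng - 1.0) / (Qg - 1.0)
    # round half away from zero (values are >= 0 here, so floor(x + 0.5))
    q = np.floor(scaled + 0.5).astype(np.int64) + 1
    return QuantizedVolume(data=q, Ng=Ng, Qg=Qg)
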