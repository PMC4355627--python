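"""Synthetic validation cohorts: smooth backgrounds plus Gaussian lesions.

Emulates an artificial-effects experiment: a control arm of smooth 3D
noise volumes and a lesion arm built from the *same* backgrounds (seed
matched, mirroring the design where artifacts are added to the images of
the same healthy subjects) with additive hyper-/hypo-intense effects of
Gaussian spatial profile at fixed interior locations.  Each lesion has a
hard support radius so the ground-truth mask is unambiguous for the
overlap metrics.

Backgrounds are stationary smoothed Gaussian noise — enough to exercise
quantization, co-occurrence, feature and statistics stages — not brain
phantoms; for real data the lesion insertion can be applied to volumes
read from disk instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Volume, write_volume


@dataclass
class LesionSpec:
    """One additive Gaussian-profile lesion.

    amplitude is the peak intensity change in units of the background SD;
    sign +1 = hyper-intense, -1 = hypo-intense.  The binary ground-truth
    mask is the lattice ball of ``support_radius`` voxels around
    ``center`` (0-based (y, x, z) indices); the Gaussian profile has
    spatial scale ``sigma`` voxels and is truncated at the mask edge.
    """

    center: tuple[int, int, int]
    sigma: float = 2.0
    support_radius: int = 4
    amplitude: float = 3.0
    sign: int = 1
    tissue_context: str = "generic"

    def __post_init__(self) -> None:
        if self.support_radius < 1:
            raise ValueError("support_radius must be >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0 (use sign for hypo-intense)")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 (hyper) or -1 (hypo)")


@dataclass
class CohortConfig:
    """Design of a two-arm synthetic cohort (shared background model)."""

    n_per_group: int = 30
    dims: tuple[int, int, int] = (32, 32, 32)
    smoothing_scale: float = 2.0
    mean: float = 128.0
    sd: float = 24.0
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0


def generate_background(dims, smoothing_scale, mean, sd, seed) -> Volume:
    """A smooth random volume with the exact target sample mean and SD.

    Gaussian white noise is smoothed with an isotropic Gaussian kernel of
    the given scale (voxels; 0 = no smoothing) and then affinely rescaled
    to the requested moments.  Deterministic given the seed.
    """
    if sd <= 0:
        raise ValueError("background sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(tuple(dims))
    if smoothing_scale > 0:
        x = ndimage.gaussian_filter(x, smoothing_scale)
    x = (x - x.mean()) / x.std() * sd + mean
    return Volume(data=x)


def _ball_mask(center, radius, dims) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in dims)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius * radius


def add_lesion(vol: Volume, spec: LesionSpec, background_sd: float):
    """Add one lesion to a copy of ``vol``; returns (volume, mask).

    Inside the support-radius ball the profile
    ``sign * amplitude * background_sd * exp(-r^2 / (2 sigma^2))``
    is added; outside it the volume is untouched.  Lesions must be fully
    interior: a mask clipped by the grid boundary is an error.
    """
    dims = vol.dims
    c = np.asarray(spec.center, dtype=int)
    if np.any(c - spec.support_radius < 0) or np.any(
        c + spec.support_radius > np.array(dims) - 1
    ):
        raise ValueError(
            f"lesion at {tuple(c)} with support radius {spec.support_radius} "
            f"is clipped by the grid {dims}; lesions must be interior"
        )
    mask = _ball_mask(c, spec.support_radius, dims)
    grids = np.ogrid[tuple(slice(0, n) for n in dims)]
    r2 = sum((g - cc) ** 2 for g, cc in zip(grids, c)).astype(float)
    bump = spec.sign * spec.amplitude * background_sd * np.exp(-r2 / (2 * spec.sigma**2))
    out = vol.data.copy()
    out[mask] += bump[mask]
    return Volume(data=out, affine=vol.affine), mask


def default_lesion_specs(dims=(32, 32, 32), amplitude: float = 3.0) -> list[LesionSpec]:
    """Eight interior lesions: 4 hyper- and 4 hypo-intense on a 2x2x2
    layout of centers, sigma 2 voxels, support radius 4."""
    dims = tuple(dims)
    lo = [max(8, d // 4) for d in dims]
    hi = [min(d - 9, 3 * d // 4) for d in dims]
    specs = []
    k = 0
    for y in (lo[0], hi[0]):
        for x in (lo[1], hi[1]):
            for z in (lo[2], hi[2]):
                specs.append(
                    LesionSpec(
                        center=(y, x, z),
                        sigma=2.0,
                        support_radius=4,
                        amplitude=amplitude,
                        sign=1 if k % 2 == 0 else -1,
                    )
                )
                k += 1
    return specs


@dataclass
class SimulatedCohort:
    """In-memory result of ``build_cohort``."""

    volumes: dict[str, Volume]
    lesion_masks: list[np.ndarray]
    table: pd.DataFrame
    background_sd: float


def build_cohort(config: CohortConfig, out_dir=None) -> SimulatedCohort:
    """Generate the two-arm cohort defined by ``config``.

    Control subject i and lesioned subject i share the same background
    (seed-matched), so outside the lesion masks the two arms are
    identical.  Lesion masks must be pairwise disjoint.  When ``out_dir``
    is given, volumes, masks and the cohort CSV are written there.
    """
    masks = []
    for spec in config.lesions:
        _probe = Volume(np.zeros(config.dims))
        _, m = add_lesion(_probe, spec, background_sd=config.sd)
        masks.append(m)
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if (masks[a] & masks[b]).any():
                raise ValueError(f"lesion masks {a} and {b} overlap; adjust centers")

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_per_group)]

    volumes: dict[str, Volume] = {}
    rows = []
    for i, subj_seed in enumerate(child_seeds):
        bg = generate_background(
            config.dims, config.smoothing_scale, config.mean, config.sd, subj_seed
        )
        lesioned = bg
        for spec in config.lesions:
            lesioned, _ = add_lesion(lesioned, spec, background_sd=config.sd)
        cid, lid = f"ctrl{i:03d}", f"les{i:03d}"
        volumes[cid] = bg
        volumes[lid] = lesioned
        rows.append({"subject_id": cid, "group": "control", "volume_path": f"{cid}.nii.gz"})
        rows.append({"subject_id": lid, "group": "lesion", "volume_path": f"{lid}.nii.gz"})
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, vol in volumes.items():
            write_volume(vol, out_dir / f"{sid}.nii.gz", dtype=np.float32)
        for r, m in enumerate(masks):
            write_volume(Volume(m.astype(np.uint8)), out_dir / f"lesion{r:02d}_mask.nii.gz")
        table = table.assign(
            volume_path=[str(out_dir / p) for p in table["volume_path"]]
        )
        table.to_csv(out_dir / "cohort.csv", index=False)

    return SimulatedCohort(
        volumes=volumes, lesion_masks=masks, table=table, background_sd=config.sd
    )
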