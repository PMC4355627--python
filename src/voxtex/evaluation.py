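"""Overlap-based scoring of a detection map against ground-truth lesions.

Given a binary detected map ``D`` and disjoint lesion masks ``L_r``, the
aggregate measures are computed from pooled voxel counts:

    UO (union overlap / Jaccard)  sum_r |L_r ∩ D_r|  /  sum_r |L_r ∪ D_r|
    FN error                      sum_r |L_r \\ D_r|  /  sum_r |L_r|
    FP error                      sum_r |D_r \\ L_r|  /  sum_r |D_r|

where ``D_r`` is the part of the detection assigned to lesion r.  A
lesion counts as detected when ``L_r ∩ D`` is nonempty; the detection
rate is the percentage of detected lesions.

Assignment of detected voxels to lesions: a voxel inside some ``L_r``
belongs to that lesion; any other detected voxel is assigned by the
connected component it lies in — to the lesion(s) that component touches
(nearest lesion center on ties) — and components touching no lesion are
*unassigned*.  Unassigned voxels count in the FP numerator and in every
denominator over ``D`` (a detection far from all lesions is a false
positive, not a free pass), and their count is also reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats


@dataclass
class EvaluationReport:
    """Per-lesion and aggregate overlap scores."""

    per_lesion: pd.DataFrame
    uo: float
    fn: float
    fp: float
    detection_rate: float
    n_unassigned: int
    n_detected_voxels: int

    def to_frame(self) -> pd.DataFrame:
        """Aggregate row in a tabular layout (Detect %, UO, FN, FP)."""
        return pd.DataFrame(
            [
                {
                    "detect_pct": self.detection_rate,
                    "UO": self.uo,
                    "FN_error": self.fn,
                    "FP_error": self.fp,
                    "UO_mean": self.per_lesion["uo"].mean(),
                    "UO_sd": self.per_lesion["uo"].std(),
                    "FN_mean": self.per_lesion["fn"].mean(),
                    "FN_sd": self.per_lesion["fn"].std(),
                    "unassigned_voxels": self.n_unassigned,
                }
            ]
        )


def score_detection(detected: np.ndarray, lesions: list[np.ndarray]) -> EvaluationReport:
    """Score a binary detection map against disjoint lesion masks."""
    D = np.asarray(detected, dtype=bool)
    if not lesions:
        raise ValueError("need at least one lesion mask")
    L = [np.asarray(m, dtype=bool) for m in lesions]
    for m in L:
        if m.shape != D.shape:
            raise ValueError(f"mask shape {m.shape} != detected shape {D.shape}")
    for a in range(len(L)):
        for b in range(a + 1, len(L)):
            if (L[a] & L[b]).any():
                raise ValueError(f"lesion masks {a} and {b} are not disjoint")

    centers = [np.argwhere(m).mean(axis=0) for m in L]
    union_L = np.logical_or.reduce(L)

    # assign detected voxels: own-lesion voxels directly, the rest by the
    # connected component they belong to
    assign = np.full(D.shape, -1, dtype=int)  # -1 = unassigned
    for r, m in enumerate(L):
        assign[D & m] = r
    labels, ncomp = ndimage.label(D, structure=ndimage.generate_binary_structure(3, 3))
    for lab in range(1, ncomp + 1):
        comp = labels == lab
        touched = [r for r, m in enumerate(L) if (comp & m).any()]
        free = comp & ~union_L
        if not touched or not free.any():
            continue
        if len(touched) == 1:
            assign[free] = touched[0]
        else:
            coords = np.argwhere(free)
            dists = np.stack(
                [((coords - centers[r]) ** 2).sum(axis=1) for r in touched]
            )
            assign[free] = np.asarray(touched)[np.argmin(dists, axis=0)]

    rows = []
    inter_sum = union_sum = miss_sum = extra_sum = 0
    for r, m in enumerate(L):
        Dr = D & (assign == r)
        inter = int((m & Dr).sum())
        miss = int((m & ~Dr).sum())
        extra = int((Dr & ~m).sum())
        uni = inter + miss + extra
        rows.append(
            {
                "lesion": r,
                "detected": inter > 0,
                "size_L": int(m.sum()),
                "size_D": int(Dr.sum()),
                "intersection": inter,
                "uo": inter / uni if uni else 0.0,
                "fn": miss / m.sum(),
                "fp": extra / Dr.sum() if Dr.sum() else 0.0,
            }
        )
        inter_sum += inter
        union_sum += uni
        miss_sum += miss
        extra_sum += extra
    n_unassigned = int((D & (assign == -1)).sum())
    n_detected = int(D.sum())
    size_L_total = int(union_L.sum())

    per_lesion = pd.DataFrame(rows)
    detection_rate = 100.0 * per_lesion["detected"].mean()
    uo = inter_sum / (union_sum + n_unassigned) if (union_sum + n_unassigned) else 0.0
    fn = miss_sum / size_L_total
    fp = (extra_sum + n_unassigned) / n_detected if n_detected else float("nan")
    return EvaluationReport(
        per_lesion=per_lesion,
        uo=uo,
        fn=fn,
        fp=fp,
        detection_rate=detection_rate,
        n_unassigned=n_unassigned,
        n_detected_voxels=n_detected,
    )


def compare_measurements(sample_a, sample_b, welch: bool = False):
    """Two-sample two-tailed t-test between measurement sets.

    Pooled-variance by default (``welch=True`` for unequal variances).
    Used to compare UO/FN/FP populations across quantization levels or
    between the full-3D and three-planes methods.  Two zero-variance
    samples with equal means give (0, 1); zero variance with unequal
    means raises.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
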