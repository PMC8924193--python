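"""Object-level segmentation metrics and multi-observer agreement.

Object-Dice (OD) and object-Hausdorff (OH) follow the gland-segmentation
challenge formulation: objects are matched by maximal pixel overlap, each
matched pair's Dice / boundary-Hausdorff is weighted by relative object size,
and the two directions (segmentation vs reference and reference vs
segmentation) are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "dice",
    "hausdorff",
    "boundary_points",
    "match_objects",
    "object_dice",
    "object_hausdorff",
    "ObjectMetricReport",
    "evaluate_rois",
    "pairwise_agreement",
    "ObserverAgreementReport",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks; two empty masks score 1 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of object pixels with a 4-neighbor outside the object."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1)
    inner = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~inner)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance undefined for an empty point set")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def _objects(labels: np.ndarray) -> dict[int, np.ndarray]:
    labels = np.asarray(labels)
    return {int(i): labels == i for i in np.unique(labels[labels > 0])}


def _overlap_match(
    objs_a: dict[int, np.ndarray], labels_b: np.ndarray, objs_b: dict[int, np.ndarray]
) -> dict[int, tuple[int | None, bool]]:
    """Match each object in A to the B object of maximal overlap (ties -> lower
    label); zero-overlap objects fall back to the B object with minimal
    boundary Hausdorff distance (used for OH). Returns
    {a_id: (b_id or None, overlapped)}."""
    out: dict[int, tuple[int | None, bool]] = {}
    b_boundaries = {i: boundary_points(m) for i, m in objs_b.items()}
    for aid, amask in objs_a.items():
        covered = labels_b[amask]
        counts = np.bincount(covered[covered > 0])
        if counts.size and counts.max() > 0:
            out[aid] = (int(np.argmax(counts)), True)  # argmax -> lowest label on ties
        elif objs_b:
            ab = boundary_points(amask)
            best, best_d = None, np.inf
            for bid in sorted(objs_b):
                d = max(
                    directed_hausdorff(ab, b_boundaries[bid])[0],
                    directed_hausdorff(b_boundaries[bid], ab)[0],
                )
                if d < best_d:
                    best, best_d = bid, d
            out[aid] = (best, False)
        else:
            out[aid] = (None, False)
    return out


def match_objects(
    seg: np.ndarray, ref: np.ndarray
) -> tuple[dict[int, tuple[int | None, bool]], dict[int, tuple[int | None, bool]], bool]:
    """Bidirectional object matching. Returns (seg->ref, ref->seg, flagged)
    where ``flagged`` marks an empty side."""
    seg = np.asarray(seg)
    ref = np.asarray(ref)
    objs_s = _objects(seg)
    objs_g = _objects(ref)
    flagged = not objs_s or not objs_g
    s2g = _overlap_match(objs_s, ref, objs_g)
    g2s = _overlap_match(objs_g, seg, objs_s)
    return s2g, g2s, flagged


def _directional_weighted(
    objs_a: dict[int, np.ndarray],
    objs_b: dict[int, np.ndarray],
    matching: dict[int, tuple[int | None, bool]],
    pair_fn,
) -> float:
    total_area = sum(int(m.sum()) for m in objs_a.values())
    acc = 0.0
    for aid, amask in objs_a.items():
        w = int(amask.sum()) / total_area
        bid, _ = matching[aid]
        acc += w * pair_fn(amask, None if bid is None else objs_b[bid])
    return acc


def object_dice(seg: np.ndarray, ref: np.ndarray) -> float:
    """Size-weighted bidirectional object-level Dice; in [0, 1]."""
    objs_s = _objects(np.asarray(seg))
    objs_g = _objects(np.asarray(ref))
    if not objs_s and not objs_g:
        return 1.0
    if not objs_s or not objs_g:
        return 0.0
    s2g, g2s, _ = match_objects(seg, ref)

    def pair_dice(a, b):
        return 0.0 if b is None else dice(a, b)

    fwd = _directional_weighted(objs_s, objs_g, s2g, pair_dice)
    bwd = _directional_weighted(objs_g, objs_s, g2s, pair_dice)
    return 0.5 * (fwd + bwd)


def object_hausdorff(seg: np.ndarray, ref: np.ndarray) -> float:
    """Size-weighted bidirectional object-level Hausdorff distance, in pixels.

    Undefined (ValueError) when either side has no objects.
    """
    objs_s = _objects(np.asarray(seg))
    objs_g = _objects(np.asarray(ref))
    if not objs_s or not objs_g:
        raise ValueError("object Hausdorff undefined: one side has no objects")
    s2g, g2s, _ = match_objects(seg, ref)

    def pair_h(a, b):
        return hausdorff(boundary_points(a), boundary_points(b))

    fwd = _directional_weighted(objs_s, objs_g, s2g, pair_h)
    bwd = _directional_weighted(objs_g, objs_s, g2s, pair_h)
    return 0.5 * (fwd + bwd)


@dataclass
class ObjectMetricReport:
    """Per-ROI OD/OH values with mean +/- SD aggregates (OH may be NaN when
    undefined for a ROI; aggregates skip NaNs and the ROI is flagged)."""

    per_roi: list[tuple[str, float, float]] = field(default_factory=list)
    flagged_rois: list[str] = field(default_factory=list)

    def _vals(self, idx: int) -> np.ndarray:
        v = np.array([row[idx] for row in self.per_roi], dtype=np.float64)
        return v[~np.isnan(v)]

    @property
    def od_mean(self) -> float:
        return float(self._vals(1).mean()) if len(self._vals(1)) else float("nan")

    @property
    def od_sd(self) -> float:
        return float(self._vals(1).std(ddof=0)) if len(self._vals(1)) else float("nan")

    @property
    def oh_mean(self) -> float:
        return float(self._vals(2).mean()) if len(self._vals(2)) else float("nan")

    @property
    def oh_sd(self) -> float:
        return float(self._vals(2).std(ddof=0)) if len(self._vals(2)) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_roi, columns=["roi", "object_dice", "object_hausdorff"])
        agg = pd.DataFrame(
            [
                ("mean", self.od_mean, self.oh_mean),
                ("sd", self.od_sd, self.oh_sd),
            ],
            columns=df.columns,
        )
        return pd.concat([df, agg], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate_rois(
    pairs: Sequence[tuple[str, np.ndarray, np.ndarray]]
) -> ObjectMetricReport:
    """OD/OH for a list of (roi id, segmentation, reference) instance maps."""
    report = ObjectMetricReport()
    for roi, seg, ref in pairs:
        od = object_dice(seg, ref)
        try:
            oh = object_hausdorff(seg, ref)
        except ValueError:
            oh = float("nan")
            report.flagged_rois.append(roi)
        report.per_roi.append((roi, od, oh))
    return report


@dataclass
class ObserverAgreementReport:
    pairwise: dict[tuple[int, int], tuple[float, float]]  # (od, oh) per observer pair
    od_mean: float
    oh_mean: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise)


def pairwise_agreement(
    annotations: Sequence[Sequence[np.ndarray]],
) -> ObserverAgreementReport:
    """Average OD/OH over every unordered observer pair and every ROI.

    ``annotations[k][i]`` is observer k's instance map for ROI i.
    """
    n_obs = len(annotations)
    if n_obs < 2:
        raise ValueError("pairwise agreement requires at least 2 observers")
    n_rois = len(annotations[0])
    if any(len(a) != n_rois for a in annotations):
        raise ValueError("observers must annotate the same ROIs")
    pairwise: dict[tuple[int, int], tuple[float, float]] = {}
    for i, j in combinations(range(n_obs), 2):
        ods, ohs = [], []
        for r in range(n_rois):
            ods.append(object_dice(annotations[i][r], annotations[j][r]))
            ohs.append(object_hausdorff(annotations[i][r], annotations[j][r]))
        pairwise[(i, j)] = (float(np.mean(ods)), float(np.mean(ohs)))
    od_mean = float(np.mean([v[0] for v in pairwise.values()]))
    oh_mean = float(np.mean([v[1] for v in pairwise.values()]))
    return ObserverAgreementReport(pairwise=pairwise, od_mean=od_mean, oh_mean=oh_mean)
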