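"""Synthetic two-channel MxIF ROI generator with ground truth.

Produces tissue-packed cells (a seeded Voronoi-like partition restricted to a
tissue region), one nucleus blob per cell on the nuclear channel and a
membrane ridge along cell borders on the membrane channel, with controllable
membrane breaks, intensity variation, background haze and noise. Also
provides the oracle edit provider (a simulated human corrector) and label
degradation used in harness ablations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .nuclear_weak_labeler import EditOverlay, NuclearSegResult
from .raster_core import IntensityRaster, read_label_map, read_raster, write_label_map, write_raster

__all__ = [
    "SynthConfig",
    "SynthROI",
    "generate_roi",
    "membrane_mask_from_cells",
    "oracle_edit_provider",
    "degrade_labels",
    "write_roi",
    "read_roi",
]


@dataclass(frozen=True)
class SynthConfig:
    frame: tuple[int, int] = (512, 512)
    n_cells: int = 150
    cell_radius: int = 18  # max growth radius of a cell around its seed point
    nucleus_radius_range: tuple[int, int] = (4, 7)
    membrane_width: int = 3
    membrane_break_probability: float = 0.0
    nucleus_intensity_range: tuple[int, int] = (20000, 45000)
    membrane_intensity_range: tuple[int, int] = (15000, 35000)
    background_level: int = 1500
    noise_sd: float = 0.0
    tissue: str = "disks"  # "disks": cells bounded by cell_radius; "full": cells tile the frame
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.membrane_break_probability <= 1.0:
            raise ValueError("membrane_break_probability must be in [0, 1]")
        if self.tissue not in ("disks", "full"):
            raise ValueError("tissue must be 'disks' or 'full'")
        for lo, hi in (self.nucleus_radius_range, self.nucleus_intensity_range,
                       self.membrane_intensity_range):
            if lo > hi:
                raise ValueError("ranges must have min <= max")


@dataclass
class SynthROI:
    dapi: IntensityRaster
    mem: IntensityRaster
    gt_cells: np.ndarray
    gt_nuclei: np.ndarray
    config: SynthConfig

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.gt_cells[self.gt_cells > 0])))


def _sample_seeds(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing with a minimum separation; may return fewer than requested."""
    h, w = cfg.frame
    min_sep = max(3.0, 1.15 * cfg.cell_radius)
    margin = max(2, cfg.cell_radius // 3)
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < cfg.n_cells and tries < 300 * cfg.n_cells:
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts)


def _partition_cells(cfg: SynthConfig, seeds: np.ndarray) -> np.ndarray:
    """Voronoi partition of the tissue region (union of seed disks)."""
    h, w = cfg.frame
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (cc[None] - seeds[:, 1, None, None]) ** 2
    nearest = d2.argmin(axis=0)
    if cfg.tissue == "full":
        return (nearest + 1).astype(np.int32)
    mind2 = d2.min(axis=0)
    tissue = mind2 <= cfg.cell_radius**2
    labels = np.where(tissue, nearest + 1, 0).astype(np.int32)
    return labels


def _boundary_segments(cells: np.ndarray) -> tuple[np.ndarray, dict]:
    """Boundary pixels of the cell partition, grouped into seams.

    A seam is the set of boundary pixels between one unordered label pair
    (background counts as a partner). Returns (boundary mask, {pair: mask}).
    """
    h, w = cells.shape
    padded = np.pad(cells, 1, mode="constant")
    segments: dict[tuple[int, int], np.ndarray] = {}
    boundary = np.zeros(cells.shape, dtype=bool)
    fg = cells > 0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        neigh = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        diff = fg & (neigh != cells)
        boundary |= diff
        rs, cs = np.nonzero(diff)
        for r, c in zip(rs, cs):
            a, b = int(cells[r, c]), int(neigh[r, c])
            key = (min(a, b), max(a, b))
            if key not in segments:
                segments[key] = np.zeros(cells.shape, dtype=bool)
            segments[key][r, c] = True
    return boundary, segments


def membrane_mask_from_cells(cells: np.ndarray, membrane_width: int) -> np.ndarray:
    """Ground-truth cell boundary dilated to the configured membrane width."""
    boundary, _ = _boundary_segments(cells)
    radius = max(0, (membrane_width - 1) // 2)
    if radius:
        boundary = ndi.binary_dilation(boundary, structure=disk(radius))
    return boundary


def generate_roi(config: SynthConfig) -> SynthROI:
    """Generate one synthetic ROI; deterministic per config seed.

    If the requested density is infeasible the generated cell count is lower
    than requested (recorded in the returned ground truth).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame
    seeds = _sample_seeds(cfg, rng)
    if len(seeds) == 0:
        raise ValueError("no cells placeable at the requested density")
    cells = _partition_cells(cfg, seeds)

    # one nucleus per cell, strictly inside the membrane-eroded cell interior
    nuclei = np.zeros_like(cells)
    rlo, rhi = cfg.nucleus_radius_range
    dist_in = ndi.distance_transform_edt(cells > 0)
    for oid in np.unique(cells[cells > 0]):
        obj = cells == oid
        r_n = int(rng.integers(rlo, rhi + 1))
        # pad so the frame border counts as outside the cell
        dist_obj = ndi.distance_transform_edt(np.pad(obj, 1))[1:-1, 1:-1]
        dist_obj = np.where(obj, dist_obj, 0)
        while r_n >= 1:
            # margin: nucleus radius + inward reach of the dilated membrane
            ok = dist_obj > (r_n + cfg.membrane_width / 2.0 + 1.0)
            if ok.any():
                break
            r_n -= 1
        if r_n < 1:
            r_n = 1
            ok = dist_obj == dist_obj.max()
        rows, cols = np.nonzero(ok)
        i = int(rng.integers(0, len(rows)))
        cr, cc2 = rows[i], cols[i]
        rr, cc = np.mgrid[0:h, 0:w]
        blob = (rr - cr) ** 2 + (cc - cc2) ** 2 <= r_n**2
        nuclei[blob] = oid

    # membrane ridge with optional per-seam breaks
    boundary, segments = _boundary_segments(cells)
    radius = max(0, (cfg.membrane_width - 1) // 2)
    mem_f = np.zeros((h, w), dtype=np.float64)
    mlo, mhi = cfg.membrane_intensity_range
    for key in sorted(segments):
        if cfg.membrane_break_probability > 0 and rng.random() < cfg.membrane_break_probability:
            continue
        seg = segments[key]
        if radius:
            seg = ndi.binary_dilation(seg, structure=disk(radius))
        # per-pixel variation (+/-10%) so watershed floods split ridges
        # between neighbors instead of one region claiming a whole seam
        base = float(rng.integers(mlo, mhi + 1))
        texture = rng.uniform(0.9, 1.1, size=mem_f.shape)
        mem_f = np.maximum(mem_f, seg * base * texture)

    # nuclear channel
    dapi_f = np.zeros((h, w), dtype=np.float64)
    nlo, nhi = cfg.nucleus_intensity_range
    for oid in np.unique(nuclei[nuclei > 0]):
        dapi_f[nuclei == oid] = float(rng.integers(nlo, nhi + 1))
    dapi_f = ndi.gaussian_filter(dapi_f, sigma=0.8)

    dapi_f += cfg.background_level
    mem_f += cfg.background_level
    if cfg.noise_sd > 0:
        dapi_f += rng.normal(0.0, cfg.noise_sd, size=(h, w))
        mem_f += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    dapi = IntensityRaster(np.clip(np.rint(dapi_f), 0, 65535).astype(np.uint16), bit_depth=16)
    mem = IntensityRaster(np.clip(np.rint(mem_f), 0, 65535).astype(np.uint16), bit_depth=16)
    return SynthROI(dapi=dapi, mem=mem, gt_cells=cells, gt_nuclei=nuclei, config=cfg)


# ---------------------------------------------------------------------------
# Oracle editor (simulated human correction) and label degradation


def _order_as_polyline(points: np.ndarray) -> list[tuple[int, int]]:
    """Order seam pixels along their principal axis."""
    if len(points) == 1:
        return [tuple(points[0])]
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    order = np.argsort(t, kind="stable")
    return [(int(r), int(c)) for r, c in points[order]]


def _extend_polyline(
    pl: list[tuple[int, int]], shape: tuple[int, int], by: int = 2
) -> list[tuple[int, int]]:
    if len(pl) < 2:
        return pl
    h, w = shape

    def ext(p, q):  # extend past p along q->p
        dr, dc = p[0] - q[0], p[1] - q[1]
        n = max(abs(dr), abs(dc), 1)
        return (
            int(np.clip(p[0] + round(by * dr / n), 0, h - 1)),
            int(np.clip(p[1] + round(by * dc / n), 0, w - 1)),
        )

    return [ext(pl[0], pl[1])] + pl + [ext(pl[-1], pl[-2])]


def oracle_edit_provider(predicted: NuclearSegResult, gt: np.ndarray) -> EditOverlay:
    """Simulated human editor: splits merged objects along ground-truth seams
    and circles spurious objects (majority on ground-truth background) for
    removal. Returns an empty overlay when prediction matches ground truth."""
    gt = np.asarray(gt)
    pred = predicted.instances
    if pred.shape != gt.shape:
        raise ValueError("prediction/ground-truth shape mismatch")
    overlay = EditOverlay()
    gt_ids = np.unique(gt[gt > 0])
    gt_sizes = {int(g): int((gt == g).sum()) for g in gt_ids}
    for pid in np.unique(pred[pred > 0]):
        pmask = pred == pid
        parea = int(pmask.sum())
        inside = gt[pmask]
        # gt objects mostly covered by this prediction -> merge candidates
        counts = np.bincount(inside[inside > 0], minlength=int(gt.max()) + 1)
        covered = [int(g) for g in gt_ids if counts[g] / gt_sizes[int(g)] > 0.5]
        if len(covered) >= 2:
            dists = np.stack(
                [ndi.distance_transform_edt(gt != g) for g in covered]
            )
            nearest = dists.argmin(axis=0)
            seam = np.zeros(gt.shape, dtype=bool)
            h, w = gt.shape
            for dr, dc in ((1, 0), (0, 1)):
                a = nearest[: h - dr, : w - dc] if (dr or dc) else nearest
                b = nearest[dr:, dc:]
                diff = a != b
                pm = pmask[: h - dr, : w - dc] & pmask[dr:, dc:]
                sel = diff & pm
                seam[: h - dr, : w - dc] |= sel
                seam[dr:, dc:] |= sel
            comp, ncomp = ndi.label(seam, structure=np.ones((3, 3), dtype=bool))
            for ci in range(1, ncomp + 1):
                pts = np.argwhere(comp == ci)
                pl = _extend_polyline(_order_as_polyline(pts), gt.shape)
                overlay.split_lines.append(pl)
        elif int((inside > 0).sum()) <= parea / 2:
            # spurious object: circle it for removal
            grown = ndi.binary_dilation(pmask, structure=disk(1))
            from skimage.measure import find_contours

            contours = find_contours(grown.astype(float), 0.5)
            if contours:
                longest = max(contours, key=len)
                overlay.removal_contours.append(
                    [(int(round(r)), int(round(c))) for r, c in longest]
                )
    return overlay


def degrade_labels(
    gt: np.ndarray, boundary_jitter_px: float, drop_fraction: float, seed: int
) -> np.ndarray:
    """Weak-quality labels: smooth random boundary jitter plus object drops.

    The jitter warps label lookups through a smoothed displacement field, so
    the output is always a valid disjoint partition. ``drop_fraction`` of the
    objects (rounded) are relabeled to background.
    """
    if boundary_jitter_px < 0 or drop_fraction < 0:
        raise ValueError("parameters must be >= 0")
    gt = np.asarray(gt)
    rng = np.random.default_rng(seed)
    out = gt.copy()
    if boundary_jitter_px > 0:
        h, w = gt.shape
        flow = rng.normal(0.0, 1.0, size=(2, h, w))
        flow = np.stack([ndi.gaussian_filter(f, sigma=4.0) for f in flow])
        mx = np.abs(flow).max()
        if mx > 0:
            flow *= boundary_jitter_px / mx
        rr, cc = np.mgrid[0:h, 0:w]
        src_r = np.clip(np.rint(rr + flow[0]), 0, h - 1).astype(np.intp)
        src_c = np.clip(np.rint(cc + flow[1]), 0, w - 1).astype(np.intp)
        out = gt[src_r, src_c]
    ids = np.unique(out[out > 0])
    n_drop = int(round(drop_fraction * len(ids)))
    if n_drop:
        drop = rng.choice(ids, size=min(n_drop, len(ids)), replace=False)
        out = np.where(np.isin(out, drop), 0, out)
    return out.astype(np.int32)


# ---------------------------------------------------------------------------
# Directory I/O


def write_roi(path: str | Path, roi: SynthROI) -> None:
    """Write a SynthROI as TIFFs + a JSON manifest."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    write_raster(p / "dapi.tif", roi.dapi)
    write_raster(p / "mem.tif", roi.mem)
    write_label_map(p / "gt_cells.tif", roi.gt_cells)
    write_label_map(p / "gt_nuclei.tif", roi.gt_nuclei)
    (p / "manifest.json").write_text(
        json.dumps({"config": dataclasses.asdict(roi.config), "n_cells": roi.n_cells}, indent=2)
    )


def read_roi(path: str | Path) -> SynthROI:
    p = Path(path)
    manifest = json.loads((p / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    for key in ("frame", "nucleus_radius_range", "nucleus_intensity_range",
                "membrane_intensity_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    return SynthROI(
        dapi=read_raster(p / "dapi.tif"),
        mem=read_raster(p / "mem.tif"),
        gt_cells=read_label_map(p / "gt_cells.tif"),
        gt_nuclei=read_label_map(p / "gt_nuclei.tif"),
        config=SynthConfig(**cfg_dict),
    )
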