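"""Classical nuclear segmentation, three-class map encoding and edit overlays.

The pipeline is Otsu thresholding of the nuclear channel followed by a
marker-controlled watershed seeded at distance-transform maxima. Instance
maps convert to/from a per-pixel three-class encoding
(background / interior / boundary) used as the semantic training target.
"""

from __future__ import annotations

import heapq
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon
from skimage.feature import peak_local_max

from .raster_core import IntensityRaster

logger = logging.getLogger(__name__)

# three-class pixel codes
BACKGROUND = 0
INTERIOR = 1
BOUNDARY = 2

# PNG encodings: nuclei use red boundary / blue interior / green background;
# cell maps use black boundary / white interior / grey background.
NUCLEAR_COLORS = {BOUNDARY: (255, 0, 0), INTERIOR: (0, 0, 255), BACKGROUND: (0, 255, 0)}
CELL_COLORS = {BOUNDARY: (0, 0, 0), INTERIOR: (255, 255, 255), BACKGROUND: (128, 128, 128)}

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT_4
    if connectivity == 8:
        return _STRUCT_8
    raise ValueError("connectivity must be 4 or 8")


@dataclass
class EditOverlay:
    """Human correction record.

    ``split_lines`` are polylines (lists of (row, col) vertices) rasterized as
    added boundaries; ``removal_contours`` are closed (row, col) contours whose
    interiors mark objects for deletion.
    """

    split_lines: list[list[tuple[int, int]]] = field(default_factory=list)
    removal_contours: list[list[tuple[int, int]]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.split_lines and not self.removal_contours

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for pts in list(self.split_lines) + list(self.removal_contours):
            for r, c in pts:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(f"overlay coordinate ({r}, {c}) out of bounds for {shape}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "split_lines": [[[int(r), int(c)] for r, c in pl] for pl in self.split_lines],
                "removal_contours": [
                    [[int(r), int(c)] for r, c in ct] for ct in self.removal_contours
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EditOverlay":
        obj = json.loads(text)
        return cls(
            split_lines=[[(int(r), int(c)) for r, c in pl] for pl in obj.get("split_lines", [])],
            removal_contours=[
                [(int(r), int(c)) for r, c in ct] for ct in obj.get("removal_contours", [])
            ],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EditOverlay":
        return cls.from_json(Path(path).read_text())


@dataclass
class NuclearSegResult:
    """Instance label map plus its three-class encoding."""

    instances: np.ndarray
    three_class: np.ndarray

    @property
    def n_objects(self) -> int:
        return int(len(np.unique(self.instances[self.instances > 0])))


def otsu_threshold(raster: IntensityRaster) -> tuple[int, bool]:
    """Exhaustive Otsu threshold over the intensity histogram.

    Returns ``(threshold, degenerate)`` where foreground is defined as pixels
    strictly greater than the threshold. The threshold maximizes the
    between-class variance over all 2**bit_depth candidate values (ties go to
    the lowest candidate). A constant image returns that constant with the
    degenerate flag set.
    """
    px = raster.pixels
    n_levels = 2**raster.bit_depth
    hist = np.bincount(px.ravel(), minlength=n_levels).astype(np.float64)
    if np.count_nonzero(hist) <= 1:
        warnings.warn("degenerate histogram: constant image", stacklevel=2)
        return int(px.flat[0]), True
    total = hist.sum()
    p = hist / total
    levels = np.arange(n_levels, dtype=np.float64)
    omega0 = np.cumsum(p)  # P(class0) for threshold t = pixels <= t
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    return int(np.argmax(sigma_b)), False


def distance_seeds(foreground: np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Markers at regional maxima of the Euclidean distance transform.

    Maxima closer than ``min_distance`` are suppressed; every marker lies
    inside the foreground. Returns an instance label map of single-pixel (or
    plateau) markers, empty for an empty mask.
    """
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(dist, min_distance=min_distance, labels=fg, exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    return markers


def seeded_watershed(
    elevation: np.ndarray,
    markers: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Marker-controlled watershed by priority flooding.

    Pixels are popped in non-decreasing elevation order; at equal elevation
    the earliest-queued candidate floods first (FIFO, i.e. breadth-first on
    plateaus, so a flat ridge between two markers splits at the equidistant
    column). Initial candidates are queued in lexicographic (row, col) order
    of the marker pixels, which makes the whole flood deterministic. Flooding
    uses 4-connectivity. When ``mask`` is given, only masked pixels reachable
    from a marker are labeled and markers must lie inside the mask.
    """
    elev = np.asarray(elevation, dtype=np.float64)
    markers = np.asarray(markers)
    if markers.shape != elev.shape:
        raise ValueError("marker/elevation shape mismatch")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if ((markers > 0) & ~mask).any():
            raise ValueError("markers must lie inside the mask")
    else:
        mask = np.ones(elev.shape, dtype=bool)

    labels = np.where(mask, markers, 0).astype(np.int32)
    if not (labels > 0).any():
        return np.zeros(elev.shape, dtype=np.int32)

    h, w = elev.shape
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for r, c in zip(*np.nonzero(labels)):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (elev[rr, cc], counter, rr, cc, int(labels[r, c])))
                counter += 1
    while heap:
        _, _, r, c, lab = heapq.heappop(heap)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (elev[rr, cc], counter, rr, cc, lab))
                counter += 1
    return labels


def instances_to_three_class(
    instances: np.ndarray, connectivity: int = 4, boundary_px: int = 1
) -> np.ndarray:
    """Encode an instance map as {background, interior, boundary}.

    Boundary pixels are object pixels with a neighbor (4-connected by default)
    outside their object; ``boundary_px`` thickens the boundary inward.
    """
    instances = np.asarray(instances)
    out = np.full(instances.shape, BACKGROUND, dtype=np.uint8)
    fg = instances > 0
    if not fg.any():
        return out
    struct = _structure(connectivity)
    boundary = np.zeros(instances.shape, dtype=bool)
    interior_all = fg.copy()
    padded = np.pad(instances, 1, mode="constant")
    # a pixel is boundary if any structuring-element neighbor has a different label
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if not struct[dr + 1, dc + 1] or (dr == 0 and dc == 0):
                continue
            shifted = padded[1 + dr : 1 + dr + instances.shape[0], 1 + dc : 1 + dc + instances.shape[1]]
            boundary |= fg & (shifted != instances)
    for _ in range(boundary_px - 1):
        grow = np.zeros_like(boundary)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if not struct[dr + 1, dc + 1] or (dr == 0 and dc == 0):
                    continue
                p = np.pad(boundary, 1)
                grow |= p[1 + dr : 1 + dr + boundary.shape[0], 1 + dc : 1 + dc + boundary.shape[1]]
        boundary |= grow & fg
    out[interior_all] = INTERIOR
    out[boundary] = BOUNDARY
    return out


def three_class_to_instances(
    three_class: np.ndarray, connectivity: int = 4
) -> tuple[np.ndarray, dict]:
    """Decode a three-class map back to an instance label map.

    Connected components of interior pixels become objects; every boundary
    pixel is assigned to the nearest interior component (Euclidean distance,
    ties to the lowest label). Boundary pixels in an image with no interior
    component are dropped to background and counted in the report.
    """
    tc = np.asarray(three_class)
    interior = tc == INTERIOR
    boundary = tc == BOUNDARY
    comp, n = ndi.label(interior, structure=_structure(connectivity))
    report = {"dropped_boundary_pixels": 0, "n_objects": int(n)}
    if n == 0:
        report["dropped_boundary_pixels"] = int(boundary.sum())
        return np.zeros(tc.shape, dtype=np.int32), report
    out = comp.astype(np.int32)
    bpx = np.argwhere(boundary)
    if len(bpx):
        from scipy.spatial import cKDTree

        ipx = np.argwhere(interior)
        tree = cKDTree(ipx)
        dmin, _ = tree.query(bpx)
        # exact Euclidean nearest with lowest-label ties: gather every interior
        # pixel at the minimal distance and take the smallest component label
        for (r, c), d in zip(bpx, dmin):
            idx = tree.query_ball_point((r, c), d + 1e-9)
            out[r, c] = min(comp[ipx[i][0], ipx[i][1]] for i in idx)
    return out, report


def _rasterize_polyline(points: list[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = [(int(r), int(c)) for r, c in points]
    if len(pts) == 1:
        mask[pts[0]] = True
        return mask
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def _contour_interior(contour: list[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    rows = np.array([p[0] for p in contour])
    cols = np.array([p[1] for p in contour])
    rr, cc = _draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def apply_edit_overlay(
    result: NuclearSegResult,
    edits: EditOverlay,
    removal_overlap: float = 0.5,
    connectivity: int = 4,
) -> tuple[NuclearSegResult, dict]:
    """Apply recorded human corrections to a segmentation result.

    Split polylines are rasterized as boundary pixels and the instances are
    recomputed, so objects crossed by a line fall apart into their connected
    components. Objects whose area overlaps a removal-contour interior by more
    than ``removal_overlap`` are deleted. An empty overlay returns the input
    unchanged; edits touching no object log a warning and are no-ops.
    """
    if edits.is_empty():
        return result, {"split_lines": 0, "removed_objects": 0}
    shape = result.instances.shape
    edits.validate_bounds(shape)

    tc = result.three_class.copy()
    touched = 0
    for pl in edits.split_lines:
        line_mask = _rasterize_polyline(pl, shape)
        hits = line_mask & (result.instances > 0)
        if not hits.any():
            logger.warning("split line touches no object; ignored")
        else:
            touched += 1
        tc[line_mask & (tc != BACKGROUND)] = BOUNDARY

    instances, _ = three_class_to_instances(tc, connectivity=connectivity)

    removed = 0
    for ct in edits.removal_contours:
        interior = _contour_interior(ct, shape)
        ids = np.unique(instances[(instances > 0)])
        hit_any = False
        for oid in ids:
            obj = instances == oid
            overlap = np.count_nonzero(obj & interior) / np.count_nonzero(obj)
            if overlap > removal_overlap:
                instances[obj] = 0
                removed += 1
                hit_any = True
        if not hit_any:
            logger.warning("removal contour matches no object; ignored")

    # relabel compactly, deterministic by first-pixel order
    ids = np.unique(instances[instances > 0])
    remap = np.zeros(int(instances.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    instances = remap[instances]
    three = instances_to_three_class(instances, connectivity=connectivity)
    return NuclearSegResult(instances=instances, three_class=three), {
        "split_lines": touched,
        "removed_objects": removed,
    }


def segment_nuclei_classic(
    dapi: IntensityRaster,
    min_seed_distance: int = 5,
    connectivity: int = 4,
) -> NuclearSegResult:
    """Classical nuclear segmentation: Otsu -> fill holes -> seeded watershed.

    The watershed elevation is the inverted Euclidean distance transform of
    the thresholded foreground, seeded at distance maxima and masked to the
    foreground.
    """
    thr, degenerate = otsu_threshold(dapi)
    fg = dapi.pixels > thr
    if degenerate or not fg.any():
        empty = np.zeros(dapi.shape, dtype=np.int32)
        return NuclearSegResult(instances=empty, three_class=instances_to_three_class(empty))
    fg = ndi.binary_fill_holes(fg)
    markers = distance_seeds(fg, min_distance=min_seed_distance)
    if not (markers > 0).any():
        empty = np.zeros(dapi.shape, dtype=np.int32)
        return NuclearSegResult(instances=empty, three_class=instances_to_three_class(empty))
    elevation = -ndi.distance_transform_edt(fg)
    instances = seeded_watershed(elevation, markers, mask=fg)
    return NuclearSegResult(
        instances=instances,
        three_class=instances_to_three_class(instances, connectivity=connectivity),
    )


def three_class_to_rgb(three_class: np.ndarray, palette: dict | None = None) -> np.ndarray:
    """Render a three-class map with the nuclear (default) or cell palette."""
    palette = NUCLEAR_COLORS if palette is None else palette
    tc = np.asarray(three_class)
    rgb = np.zeros(tc.shape + (3,), dtype=np.uint8)
    for code, color in palette.items():
        rgb[tc == code] = color
    return rgb


def rgb_to_three_class(rgb: np.ndarray, palette: dict | None = None) -> np.ndarray:
    palette = NUCLEAR_COLORS if palette is None else palette
    rgb = np.asarray(rgb)
    tc = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for code, color in palette.items():
        tc[np.all(rgb == np.array(color, dtype=np.uint8), axis=-1)] = code
    return tc
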