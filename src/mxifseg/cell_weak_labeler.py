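"""Cell-boundary weak labels: eroded nuclear markers + membrane watershed.

Nuclear interiors are shrunk with a 3x3 structuring element and used to seed
an unmasked watershed over the membrane channel (bright membrane = barrier);
oversized regions — large background basins — are then removed by a size
filter (default: regions of 1400 pixels or more, applied at the original
resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .nuclear_weak_labeler import (
    CELL_COLORS,
    NuclearSegResult,
    instances_to_three_class,
    seeded_watershed,
    three_class_to_rgb,
)
from .raster_core import IntensityRaster

__all__ = [
    "CellWeakLabels",
    "erode_markers",
    "cell_watershed",
    "size_filter_background",
    "make_cell_map",
    "instances_to_mask_stack",
    "mask_stack_to_instances",
    "generate_weak_labels",
]

DEFAULT_MAX_AREA = 1400

# 3x3 "disk" = 4-connected disk of radius 1 (a cross); the full square is the
# alternative reading of a 3x3 disk.
_SELEM = {
    "cross": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    "square": np.ones((3, 3), dtype=bool),
}


@dataclass
class CellWeakLabels:
    instances: np.ndarray
    cell_map: np.ndarray  # three-class codes; render with the cell palette
    mask_stack: list[np.ndarray] = field(default_factory=list)

    def cell_map_rgb(self) -> np.ndarray:
        return three_class_to_rgb(self.cell_map, palette=CELL_COLORS)


def erode_markers(nuclear_interiors: np.ndarray, selem: str = "cross") -> np.ndarray:
    """Shrink each nuclear object by one morphological erosion.

    Objects that erode to nothing are retained as their single centroid pixel
    so every nucleus still seeds a cell.
    """
    labels = np.asarray(nuclear_interiors)
    out = np.zeros_like(labels, dtype=np.int32)
    struct = _SELEM[selem]
    for oid in np.unique(labels[labels > 0]):
        obj = labels == oid
        eroded = ndi.binary_erosion(obj, structure=struct, border_value=0)
        if eroded.any():
            out[eroded] = oid
        else:
            rows, cols = np.nonzero(obj)
            r = int(np.round(rows.mean()))
            c = int(np.round(cols.mean()))
            if not obj[r, c]:  # centroid off-object for odd shapes: snap to nearest pixel
                d2 = (rows - rows.mean()) ** 2 + (cols - cols.mean()) ** 2
                i = int(np.argmin(d2))
                r, c = int(rows[i]), int(cols[i])
            out[r, c] = oid
    return out


def cell_watershed(mem: IntensityRaster | np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Unmasked seeded watershed over the full frame on membrane intensity.

    Raw membrane intensity is the elevation, so bright membrane ridges act as
    barriers; every pixel ends up labeled. Tie-breaking is shared with
    :func:`mxifseg.nuclear_weak_labeler.seeded_watershed`.
    """
    elev = mem.pixels if isinstance(mem, IntensityRaster) else np.asarray(mem)
    if not (np.asarray(markers) > 0).any():
        return np.zeros(elev.shape, dtype=np.int32)
    return seeded_watershed(elev.astype(np.float64), markers, mask=None)


def size_filter_background(instances: np.ndarray, max_area: int = DEFAULT_MAX_AREA) -> np.ndarray:
    """Relabel every region of area >= max_area (inclusive) to background."""
    if max_area <= 0:
        raise ValueError("max_area must be positive")
    instances = np.asarray(instances)
    out = instances.copy()
    ids, counts = np.unique(instances[instances > 0], return_counts=True)
    for oid, area in zip(ids, counts):
        if area >= max_area:
            out[instances == oid] = 0
    return out


def make_cell_map(instances: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Three-class cell map: inner cell / cell boundary / background codes."""
    return instances_to_three_class(instances, connectivity=connectivity)


def instances_to_mask_stack(instances: np.ndarray) -> tuple[list[np.ndarray], list[int]]:
    """Split an instance map into one binary mask per object (plus its label)."""
    instances = np.asarray(instances)
    ids = [int(i) for i in np.unique(instances[instances > 0])]
    return [instances == i for i in ids], ids


def mask_stack_to_instances(
    masks: list[np.ndarray], ids: list[int] | None = None, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Reassemble a mask stack into an instance map (inverse of the split)."""
    if not masks:
        if shape is None:
            raise ValueError("shape required for an empty stack")
        return np.zeros(shape, dtype=np.int32)
    ids = ids or list(range(1, len(masks) + 1))
    out = np.zeros(np.asarray(masks[0]).shape, dtype=np.int32)
    for m, i in zip(masks, ids):
        out[np.asarray(m, dtype=bool)] = i
    return out


def generate_weak_labels(
    dapi: IntensityRaster,
    mem: IntensityRaster,
    nuclear_result: NuclearSegResult,
    max_area: int = DEFAULT_MAX_AREA,
    selem: str = "cross",
) -> CellWeakLabels:
    """Cell weak labels from nuclear instances and the membrane channel.

    erode markers -> membrane watershed -> size filter -> cell map + mask
    stack. The output never contains more cells than input nuclei.
    """
    if dapi.shape != mem.shape:
        raise ValueError("dapi/mem shape mismatch")
    nuclei = nuclear_result.instances
    if not (np.asarray(nuclei) > 0).any():
        empty = np.zeros(mem.shape, dtype=np.int32)
        return CellWeakLabels(instances=empty, cell_map=make_cell_map(empty), mask_stack=[])
    markers = erode_markers(nuclei, selem=selem)
    cells = cell_watershed(mem, markers)
    cells = size_filter_background(cells, max_area=max_area)
    masks, _ = instances_to_mask_stack(cells)
    return CellWeakLabels(instances=cells, cell_map=make_cell_map(cells), mask_stack=masks)
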