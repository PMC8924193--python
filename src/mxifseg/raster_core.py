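"""Image data model, TIFF/PNG I/O, channel stacking, bit conversion and augmentation.

Conventions used throughout the package: arrays are row-major, 0-based,
origin at the top-left corner; rotations are counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage as ndi

DEFAULT_PIXEL_SIZE_UM = 0.293

__all__ = [
    "IntensityRaster",
    "StackedColorImage",
    "AugmentationPolicy",
    "convert_16_to_8",
    "stack_dapi_mem",
    "upscale_2x_nearest",
    "downscale_2x_block",
    "normalize_channels",
    "augment",
    "read_raster",
    "write_raster",
    "read_label_map",
    "write_label_map",
    "write_rgb_png",
    "read_rgb_png",
]


@dataclass(frozen=True)
class IntensityRaster:
    """Single-channel 2-D grid of non-negative integer intensities.

    Parameters
    ----------
    pixels
        2-D unsigned integer array.
    bit_depth
        8 or 16; all pixel values must be < 2**bit_depth.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("raster must be non-empty")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        if px.dtype != dtype:
            if px.min() < 0 or px.max() >= 2**self.bit_depth:
                raise ValueError("pixel values outside bit-depth range")
            px = px.astype(dtype)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class StackedColorImage:
    """Three 8-bit channels where R and B both carry the nuclear channel.

    Channel semantics are fixed: ``(nuclear, membrane, nuclear)``.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    channel_semantics: tuple[str, str, str] = ("nuclear", "membrane", "nuclear")

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("channel shape mismatch")
        if not np.array_equal(self.r, self.b):
            raise ValueError("R and B channels must both carry the nuclear image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    def as_array(self) -> np.ndarray:
        """Return an (H, W, 3) uint8 array."""
        return np.stack([self.r, self.g, self.b], axis=-1)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic training-time augmentation parameters.

    ``flip_probability`` is the chance of applying exactly one flip
    (axis picked uniformly), ``blur_probability`` / ``rotation_probability``
    gate the Gaussian blur and the right-angle rotation draws.
    """

    flip_probability: float = 0.5
    blur_sigma: float = 5.0
    blur_probability: float = 0.5
    intensity_scale_range: tuple[float, float] = (0.8, 1.5)
    rotation_angles: tuple[int, ...] = (90, 180, 270)
    rotation_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        lo, hi = self.intensity_scale_range
        if lo > hi:
            raise ValueError("intensity_scale_range min must be <= max")
        if any(a % 90 != 0 for a in self.rotation_angles):
            raise ValueError("rotation angles must be multiples of 90 degrees")


def convert_16_to_8(raster: IntensityRaster, mode: str = "divide") -> IntensityRaster:
    """Convert a 16-bit raster to 8 bits.

    ``mode="divide"`` (default) divides by 256 with truncation; this is
    deterministic and dataset-independent. ``mode="minmax"`` maps the observed
    minimum to 0 and maximum to 255 (constant images map to 0). Both mappings
    are monotone non-decreasing.
    """
    if raster.bit_depth != 16:
        raise ValueError("convert_16_to_8 requires a 16-bit raster")
    px = raster.pixels
    if mode == "divide":
        out = (px // 256).astype(np.uint8)
    elif mode == "minmax":
        lo = int(px.min())
        hi = int(px.max())
        if hi == lo:
            out = np.zeros_like(px, dtype=np.uint8)
        else:
            out = ((px.astype(np.float64) - lo) * 255.0 / (hi - lo)).astype(np.uint8)
    else:
        raise ValueError(f"unknown conversion mode {mode!r}")
    return IntensityRaster(out, bit_depth=8, pixel_size_um=raster.pixel_size_um)


def stack_dapi_mem(dapi: IntensityRaster, mem: IntensityRaster) -> StackedColorImage:
    """Stack nuclear and membrane channels into RGB in DAPI-MEM-DAPI order."""
    if dapi.bit_depth != 8 or mem.bit_depth != 8:
        raise ValueError("stacking requires 8-bit inputs")
    if dapi.shape != mem.shape:
        raise ValueError(f"shape mismatch: {dapi.shape} vs {mem.shape}")
    return StackedColorImage(r=dapi.pixels.copy(), g=mem.pixels.copy(), b=dapi.pixels.copy())


def upscale_2x_nearest(arr: np.ndarray) -> np.ndarray:
    """Double both spatial dimensions by 2x2 block replication of each pixel."""
    arr = np.asarray(arr)
    return np.repeat(np.repeat(arr, 2, axis=0), 2, axis=1)


def downscale_2x_block(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`upscale_2x_nearest`: keep the top-left pixel of each 2x2 block."""
    return np.asarray(arr)[::2, ::2]


def normalize_channels(
    image: StackedColorImage, mode: str = "center", stats: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Per-channel affine normalization of a stacked color image.

    ``mode="center"`` subtracts each channel's mean; ``mode="zscore"``
    additionally divides by the channel standard deviation (zero-variance
    channels are left as zeros, no division by zero). Per-image statistics are
    used unless precomputed ``stats`` (``{"mean": (3,), "std": (3,)}``) are
    supplied for dataset-level normalization.

    Returns the float array of shape (H, W, 3) and a metadata dict recording
    the mode and the statistics actually applied.
    """
    if mode not in ("center", "zscore"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    arr = image.as_array().astype(np.float64)
    if stats is None:
        mean = arr.mean(axis=(0, 1))
        std = arr.std(axis=(0, 1))
    else:
        mean = np.asarray(stats["mean"], dtype=np.float64)
        std = np.asarray(stats["std"], dtype=np.float64)
    out = arr - mean
    if mode == "zscore":
        safe = np.where(std > 0, std, 1.0)
        out = out / safe
        out[:, :, std == 0] = 0.0
    meta = {"mode": mode, "mean": mean.tolist(), "std": std.tolist()}
    return out, meta


def _rot90_ccw(arr: np.ndarray, quarter_turns: int) -> np.ndarray:
    return np.rot90(arr, k=quarter_turns % 4, axes=(0, 1))


def augment(
    image: np.ndarray,
    masks: Sequence[np.ndarray],
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray], dict]:
    """Apply one stochastic augmentation draw to an image and aligned masks.

    Order is fixed: flip -> blur -> intensity scale -> right-angle rotation.
    Geometric transforms (flip, rotation) are applied identically to image and
    masks; blur and intensity scaling touch the image only. Intensity scaling
    clips to the 8-bit range for integer images. Fully reproducible from the
    generator state. Returns (image, masks, transform record).
    """
    img = np.asarray(image)
    out_masks = [np.asarray(m) for m in masks]
    for m in out_masks:
        if m.shape[:2] != img.shape[:2]:
            raise ValueError("mask not aligned with image")
    record: dict = {}

    if rng.random() < policy.flip_probability:
        axis = int(rng.integers(0, 2))  # 0 = vertical flip (rows), 1 = horizontal
        img = np.flip(img, axis=axis)
        out_masks = [np.flip(m, axis=axis) for m in out_masks]
        record["flip_axis"] = axis

    if policy.blur_sigma > 0 and rng.random() < policy.blur_probability:
        sigma = (policy.blur_sigma, policy.blur_sigma) + (0,) * (img.ndim - 2)
        blurred = ndi.gaussian_filter(img.astype(np.float64), sigma=sigma)
        img = blurred if np.issubdtype(np.asarray(image).dtype, np.floating) else np.clip(
            np.rint(blurred), 0, 255
        ).astype(np.asarray(image).dtype)
        record["blur_sigma"] = policy.blur_sigma

    lo, hi = policy.intensity_scale_range
    scale = float(rng.uniform(lo, hi))
    scaled = img.astype(np.float64) * scale
    if np.issubdtype(np.asarray(image).dtype, np.floating):
        img = scaled
    else:
        img = np.clip(np.rint(scaled), 0, 255).astype(np.asarray(image).dtype)
    record["intensity_scale"] = scale

    if policy.rotation_angles and rng.random() < policy.rotation_probability:
        angle = int(rng.choice(policy.rotation_angles))
        k = angle // 90
        img = _rot90_ccw(img, k)
        out_masks = [_rot90_ccw(m, k) for m in out_masks]
        record["rotation_deg"] = angle

    return np.ascontiguousarray(img), [np.ascontiguousarray(m) for m in out_masks], record


# ---------------------------------------------------------------------------
# I/O


def write_raster(path: str | Path, raster: IntensityRaster) -> None:
    tifffile.imwrite(str(path), raster.pixels)


def read_raster(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> IntensityRaster:
    arr = tifffile.imread(str(path))
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported raster dtype {arr.dtype}")
    return IntensityRaster(arr, bit_depth=depth, pixel_size_um=pixel_size_um)


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label maps are non-negative")
    if labels.max() >= 2**16:
        raise ValueError("label map exceeds 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path)))
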