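"""CT volume -> model-ready composites and auxiliary label pyramids.

The pipeline is: HU windowing, centroid-centred ROI extraction, 3-slice
pseudo-color encoding (previous/current/next axial slice in R/G/B), mask
boundary extraction, and max-pool label pyramids for deep supervision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.feature import canny
from skimage.measure import block_reduce
from scipy.ndimage import binary_erosion

from .errors import ConfigurationError, EmptyMaskError, ShapeError

__all__ = [
    "WindowSpec", "PseudoColorImage", "LabelPyramid",
    "window_hu", "mask_moment_center", "extract_roi", "encode_pseudocolor",
    "extract_edge_map", "build_pyramid", "composite_from_volume",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class WindowSpec:
    """HU display window, ``level`` center and total ``width``.

    The default (-600, 1200) is the standard lung window mapping
    HU in [-1200, 0] onto [0, 1].
    """

    level: float = -600.0
    width: float = 1200.0

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigurationError(f"window width must be > 0, got {self.width}")

    @property
    def floor(self) -> float:
        return self.level - self.width / 2

    @property
    def ceiling(self) -> float:
        return self.level + self.width / 2


@dataclass
class PseudoColorImage:
    """3-channel composite; channel order is (previous, current, next) slice."""

    pixels: np.ndarray  # (H, W, 3) in [0, 1]
    source: dict = field(default_factory=dict)

    def as_nchw(self) -> np.ndarray:
        """(3, H, W) view for the networks."""
        return np.ascontiguousarray(self.pixels.transpose(2, 0, 1))


@dataclass
class LabelPyramid:
    """Four binary maps at full, 1/2, 1/4 and 1/8 resolution."""

    levels: list[np.ndarray]
    kind: Literal["mask", "edge"]

    def __post_init__(self):
        for lv in self.levels:
            vals = np.unique(lv)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("pyramid levels must be binary")


def window_hu(volume: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Linearly map ``[floor, ceiling]`` HU onto [0, 1], clipping outside."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite HU values")
    return np.clip((volume - spec.floor) / spec.width, 0.0, 1.0)


def mask_moment_center(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (row, col) from raw image moments m10/m00, m01/m00."""
    mask = np.asarray(mask)
    m00 = mask.sum()
    if m00 == 0:
        raise EmptyMaskError("cannot compute the centroid of an empty mask")
    rows, cols = np.nonzero(mask)
    weights = mask[rows, cols].astype(np.float64)
    return (float((rows * weights).sum() / m00),
            float((cols * weights).sum() / m00))


def extract_roi(slice_grid: np.ndarray, center: tuple[float, float],
                size: int = 128) -> np.ndarray:
    """``size``x``size`` crop centred on the rounded centroid, zero-padded."""
    if size < 16 or size % 2:
        raise ConfigurationError(f"ROI size must be even and >= 16, got {size}")
    slice_grid = np.asarray(slice_grid)
    h, w = slice_grid.shape
    r0 = int(round(center[0])) - size // 2
    c0 = int(round(center[1])) - size // 2
    out = np.zeros((size, size), dtype=slice_grid.dtype)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = slice_grid[rs:re, cs:ce]
    return out


def encode_pseudocolor(volume01: np.ndarray, slice_index: int,
                       center: tuple[float, float], size: int = 128,
                       source: dict | None = None) -> PseudoColorImage:
    """Crop slices (i-1, i, i+1) into the R/G/B channels.

    Slices past either end of the volume are replaced by the boundary slice,
    so every annotated slice stays usable.
    """
    n_slices = volume01.shape[0]
    if not 0 <= slice_index < n_slices:
        raise IndexError(f"slice {slice_index} outside volume of {n_slices}")
    channels = []
    for offset in (-1, 0, 1):
        idx = int(np.clip(slice_index + offset, 0, n_slices - 1))
        channels.append(extract_roi(volume01[idx], center, size))
    pixels = np.stack(channels, axis=-1).astype(np.float64)
    meta = dict(source or {})
    meta.update(slice_index=slice_index,
                roi_origin=(int(round(center[0])) - size // 2,
                            int(round(center[1])) - size // 2))
    return PseudoColorImage(pixels=pixels, source=meta)


def extract_edge_map(mask: np.ndarray, method: str = "boundary") -> np.ndarray:
    """1-pixel boundary of a binary mask.

    ``boundary`` marks mask pixels with at least one 4-neighbour outside the
    mask (exact and deterministic, the step-edge equivalent of Canny).
    ``canny`` runs scikit-image Canny (sigma 1, hysteresis 0.1/0.2).
    """
    mask = np.asarray(mask).astype(bool)
    if method == "canny":
        return canny(mask.astype(np.float64), sigma=1.0,
                     low_threshold=0.1, high_threshold=0.2).astype(np.uint8)
    if method != "boundary":
        raise ConfigurationError(f"unknown edge method {method!r}")
    eroded = binary_erosion(mask, structure=_CROSS, border_value=0)
    return (mask & ~eroded).astype(np.uint8)


def build_pyramid(map2d: np.ndarray, levels: int = 4,
                  kind: Literal["mask", "edge"] = "mask") -> LabelPyramid:
    """Max-pool downsampling by 1, 2, 4, ... per level; stays binary."""
    map2d = np.asarray(map2d)
    h, w = map2d.shape
    factor = 2 ** (levels - 1)
    if h % factor or w % factor:
        raise ShapeError(
            f"shape {h}x{w} not divisible by 2^{levels - 1} = {factor}")
    out = [map2d.astype(np.uint8)]
    for k in range(1, levels):
        f = 2 ** k
        out.append(block_reduce(map2d, (f, f), np.max).astype(np.uint8))
    return LabelPyramid(levels=out, kind=kind)


def composite_from_volume(volume_hu: np.ndarray, mask_volume: np.ndarray,
                          slice_index: int | None = None, *, size: int = 128,
                          spec: WindowSpec = WindowSpec(),
                          edge_method: str = "boundary",
                          source: dict | None = None):
    """Full preprocessing of one annotated slice.

    Returns ``(PseudoColorImage, mask crop, mask pyramid, edge pyramid)``.
    ``slice_index`` defaults to the slice with the largest mask area.
    """
    if volume_hu.shape != mask_volume.shape:
        raise ShapeError("volume and mask shapes differ")
    if slice_index is None:
        slice_index = int(mask_volume.reshape(mask_volume.shape[0], -1)
                          .sum(axis=1).argmax())
    mask_slice = mask_volume[slice_index]
    center = mask_moment_center(mask_slice)
    volume01 = window_hu(volume_hu, spec)
    image = encode_pseudocolor(volume01, slice_index, center, size, source)
    mask_crop = extract_roi(mask_slice.astype(np.uint8), center, size)
    y_d = build_pyramid(mask_crop, kind="mask")
    y_g = build_pyramid(extract_edge_map(mask_crop, edge_method), kind="edge")
    return image, mask_crop, y_d, y_g
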