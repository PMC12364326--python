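"""Synthetic thoracic-CT-like phantoms with known nodule masks.

Volumes mimic the traits the downstream pipeline relies on: HU-valued
slices with lung-like background texture, tubular vessels whose axes cross
at least three consecutive slices, and a single approximately spherical
nodule concentrated on one slice, with either a sharp (solid) or diffuse
(GGO-like) edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]

# anisotropy of the nodule ellipsoid along the slice axis, chosen so that
# >= 60% of mask voxels fall on the central slice with margin to spare
_NODULE_Z_SEMIAXIS = 1.1
_VESSEL_HU = 40.0
_DEFAULT_SOLID_HU = 50.0
_DEFAULT_GGO_HU = -450.0


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic volume; fully determines the sample."""

    volume_shape: tuple[int, int, int] = (8, 128, 128)
    nodule_radius_range: tuple[float, float] = (3.0, 15.0)
    nodule_kind: Literal["solid", "ggo"] = "solid"
    n_vessels: int = 3
    vessel_radius_range: tuple[float, float] = (1.5, 3.0)
    background_hu: tuple[float, float] = (-800.0, 60.0)
    nodule_hu: float | None = None
    seed: int = 0

    def __post_init__(self):
        n_slices, height, width = self.volume_shape
        if n_slices < 3:
            raise ConfigurationError(
                f"need >= 3 slices for a 3-slice composite, got {n_slices}")
        if height < 16 or width < 16:
            raise ConfigurationError(
                f"in-plane extent must be >= 16, got {height}x{width}")
        rmin, rmax = self.nodule_radius_range
        if not 0 < rmin <= rmax:
            raise ConfigurationError(f"bad radius range ({rmin}, {rmax})")
        if rmax > min(height, width) / 2:
            raise ConfigurationError(
                f"max nodule radius {rmax} exceeds half the in-plane extent")
        if self.n_vessels < 0:
            raise ConfigurationError("n_vessels must be >= 0")
        if self.nodule_kind not in ("solid", "ggo"):
            raise ConfigurationError(f"unknown nodule_kind {self.nodule_kind!r}")

    @property
    def effective_nodule_hu(self) -> float:
        if self.nodule_hu is not None:
            return self.nodule_hu
        return _DEFAULT_SOLID_HU if self.nodule_kind == "solid" else _DEFAULT_GGO_HU


@dataclass
class PhantomSample:
    volume: np.ndarray          # (S, H, W) float64 HU
    mask_volume: np.ndarray     # (S, H, W) uint8, 1 = nodule
    vessel_volume: np.ndarray   # (S, H, W) uint8, 1 = vessel
    nodule_center: tuple[int, int, int]
    nodule_radius: float
    metadata: dict = field(default_factory=dict)


def _background(rng: np.random.Generator, shape, mean: float, sd: float) -> np.ndarray:
    coarse = gaussian_filter(rng.normal(0.0, sd, shape), sigma=(0.6, 3.0, 3.0))
    fine = gaussian_filter(rng.normal(0.0, sd, shape), sigma=(0.0, 0.8, 0.8))
    # smoothing shrinks the variance; rescale so the texture stays visible
    vol = mean + 2.5 * coarse + 0.5 * fine
    return vol


def _paint_vessel(rng: np.random.Generator, volume, vessel_mask,
                  start_rc, radius: float) -> None:
    n_slices, h, w = volume.shape
    drift = rng.uniform(-1.5, 1.5, size=2)
    yy, xx = np.mgrid[0:h, 0:w]
    for z in range(n_slices):
        cy = float(np.clip(start_rc[0] + z * drift[0], radius, h - 1 - radius))
        cx = float(np.clip(start_rc[1] + z * drift[1], radius, w - 1 - radius))
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        volume[z][disc] = _VESSEL_HU + rng.normal(0.0, 8.0, int(disc.sum()))
        vessel_mask[z][disc] = 1


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Build one seeded phantom volume; pure function of ``config``."""
    rng = np.random.default_rng(config.seed)
    n_slices, h, w = config.volume_shape
    bg_mean, bg_sd = config.background_hu

    volume = _background(rng, config.volume_shape, bg_mean, bg_sd)
    vessel_mask = np.zeros(config.volume_shape, dtype=np.uint8)
    mask = np.zeros(config.volume_shape, dtype=np.uint8)

    # nodule geometry drawn first so vessels can avoid it
    rmin, rmax = config.nodule_radius_range
    radius = float(rng.uniform(rmin, rmax))
    margin = int(np.ceil(radius)) + 2
    cz = int(rng.integers(1, n_slices - 1))
    cy = float(rng.uniform(margin, h - 1 - margin))
    cx = float(rng.uniform(margin, w - 1 - margin))

    for _ in range(config.n_vessels):
        for _attempt in range(64):
            start = rng.uniform([4.0, 4.0], [h - 5.0, w - 5.0])
            vr = float(rng.uniform(*config.vessel_radius_range))
            if np.hypot(start[0] - cy, start[1] - cx) > radius + vr + 10:
                break
        _paint_vessel(rng, volume, vessel_mask, start, vr)

    zz, yy, xx = np.mgrid[0:n_slices, 0:h, 0:w]
    rho = np.sqrt(((zz - cz) / _NODULE_Z_SEMIAXIS) ** 2
                  + ((yy - cy) / radius) ** 2 + ((xx - cx) / radius) ** 2)
    mask[rho <= 1.0] = 1

    nod_hu = config.effective_nodule_hu
    if config.nodule_kind == "solid":
        inside = mask.astype(bool)
        volume[inside] = nod_hu + rng.normal(0.0, 10.0, int(inside.sum()))
    else:
        # smooth raised-cosine falloff reaching background at rho = 1.5
        weight = 0.5 * (1.0 + np.cos(np.pi * np.minimum(rho / 1.5, 1.0)))
        volume = volume + (nod_hu - bg_mean) * weight

    return PhantomSample(
        volume=volume,
        mask_volume=mask,
        vessel_volume=vessel_mask,
        nodule_center=(cz, int(round(cy)), int(round(cx))),
        nodule_radius=radius,
        metadata={"seed": config.seed, "config": asdict(config)},
    )


def generate_dataset(n_samples: int, config: PhantomConfig,
                     seed: int | None = None) -> list[PhantomSample]:
    """Draw ``n_samples`` independent phantoms.

    Per-sample seeds are ``master_seed + index`` so any sample can be
    regenerated in isolation.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    master = config.seed if seed is None else seed
    return [generate_phantom(replace(config, seed=master + i))
            for i in range(n_samples)]
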