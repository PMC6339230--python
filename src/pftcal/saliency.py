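"""Probable-fixation-target extraction from saliency maps.

A saliency model scores each scene pixel for how likely it is to attract
gaze.  To turn the resulting 8-bit grayscale map into a short list of
candidate targets the map goes through an image cascade: histogram
equalization, binarization at a high threshold (default 240 of 255), a
series of morphological dilations/erosions to clean speckle and fill holes,
and connected-component extraction; each surviving component contributes its
center of mass as one target, in scene-percent coordinates.

The centroid is taken over the *filled* component (holes included in the
mass), which for non-convex blobs differs from the centroid of the boundary
contour.  Typical maps yield between 1 and 16 targets; a count outside that
range triggers a warning but is not an error.

The CENTER baseline — every fixation assumed to look at the scene center —
is the degenerate single-target case: (50, 50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure

__all__ = [
    "SaliencyMap",
    "RegionBlob",
    "SaliencyConfig",
    "binarize_map",
    "clean_mask",
    "extract_blobs",
    "saliency_to_targets",
    "center_target",
]

_EXPECTED_MAX_TARGETS = 16  # sanity bound observed across saliency models


@dataclass(frozen=True)
class SaliencyMap:
    """8-bit grayscale saliency (or fixation-density) map for one scene."""

    grid: np.ndarray
    scene_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise ValueError("saliency map must be a 2-D H x W array")
        if g.min() < 0 or g.max() > 255:
            raise ValueError("saliency intensities must lie in [0, 255]")
        object.__setattr__(self, "grid", g.astype(np.uint8))


@dataclass(frozen=True)
class RegionBlob:
    """One connected foreground component of the binarized map."""

    label: int
    area: int
    centroid: np.ndarray  # (x, y) scene-percent

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


@dataclass(frozen=True)
class SaliencyConfig:
    """Cascade knobs; the paper-style defaults are threshold 240 and a 3x3
    square element with two closing and two opening passes."""

    threshold: int = 240
    open_close_iterations: int = 2
    kernel_radius: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if self.open_close_iterations < 0 or self.kernel_radius < 0:
            raise ValueError("iterations and kernel radius must be >= 0")


def binarize_map(smap: SaliencyMap, threshold: int = 240) -> np.ndarray:
    """Histogram-equalize then threshold: keep pixels with equalized
    intensity strictly above ``threshold``.

    Equalization absorbs any uniform intensity gain, so the mask depends
    only on the intensity ranks.  A constant map carries no saliency
    information and yields an all-background mask (degenerate case).
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    g = smap.grid
    if g.min() == g.max():
        return np.zeros_like(g, dtype=bool)
    eq = exposure.equalize_hist(g, nbins=256) * 255.0
    return eq > threshold


def clean_mask(
    mask: np.ndarray, open_close_iterations: int = 2, kernel_radius: int = 1
) -> np.ndarray:
    """Morphological closing then opening with a square element.

    Closing fills holes up to the kernel scale; opening removes speckles
    smaller than the kernel.  ``open_close_iterations == 0`` (or a zero
    kernel) is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if open_close_iterations == 0 or kernel_radius == 0:
        return mask.copy()
    size = 2 * kernel_radius + 1
    structure = np.ones((size, size), dtype=bool)
    out = ndimage.binary_closing(mask, structure=structure,
                                 iterations=open_close_iterations)
    out = ndimage.binary_opening(out, structure=structure,
                                 iterations=open_close_iterations)
    return out


def extract_blobs(mask: np.ndarray) -> list[RegionBlob]:
    """Connected foreground components (8-connectivity) with filled-region
    centroids in scene-percent coordinates."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    filled = ndimage.binary_fill_holes(mask)
    labels = measure.label(filled, connectivity=2)
    blobs = []
    for region in measure.regionprops(labels):
        r, c = region.centroid  # pixel-center row/col means
        x = 100.0 * (c + 0.5) / W
        y = 100.0 * (r + 0.5) / H
        blobs.append(
            RegionBlob(label=region.label, area=int(region.area),
                       centroid=np.array([x, y]))
        )
    return blobs


def saliency_to_targets(
    smap: SaliencyMap, config: SaliencyConfig | None = None
) -> np.ndarray:
    """Full cascade: binarize -> clean -> extract; returns an (m, 2) array
    of target coordinates in scene-percent (possibly empty, with a
    warning)."""
    config = config or SaliencyConfig()
    mask = binarize_map(smap, threshold=config.threshold)
    mask = clean_mask(
        mask,
        open_close_iterations=config.open_close_iterations,
        kernel_radius=config.kernel_radius,
    )
    blobs = extract_blobs(mask)
    if not blobs:
        warnings.warn(
            f"no salient region survived the cascade for scene "
            f"{smap.scene_id!r}; empty target list",
            stacklevel=2,
        )
        return np.empty((0, 2))
    if len(blobs) > _EXPECTED_MAX_TARGETS:
        warnings.warn(
            f"{len(blobs)} targets extracted for scene {smap.scene_id!r}; "
            f"saliency maps typically yield 1-{_EXPECTED_MAX_TARGETS} — "
            "consider a larger cleaning kernel",
            stacklevel=2,
        )
    return np.array([b.centroid for b in blobs])


def center_target() -> np.ndarray:
    """The CENTER baseline target: the middle of the scene, (50, 50)."""
    return np.array([50.0, 50.0])
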