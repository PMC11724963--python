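"""Tile preprocessing: tissue masking, grid tiling and the 80 %-tissue filter.

Works on RGB tile images (a desk-scale stand-in for whole-slide preprocessing;
inputs are assumed to be already at the target resolution, 0.5 microns per
pixel by default).  The tiling grid is non-overlapping with 256-px patches;
partial edge tiles are dropped so every patch has the same physical area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping tiling grid anchored at the image origin."""

    patch_size: int = 256
    target_mpp: float = 0.5

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")

    @property
    def stride(self) -> int:
        return self.patch_size


# Saturation/value limits for the background heuristics: glass background is
# bright and desaturated, pen/scan artefacts near-black.
_WHITE_V, _WHITE_S = 0.85, 0.15
_BLACK_V = 0.10
_SAT_FLOOR = 0.05
_SAT_CAP = 0.25


def compute_tissue_mask(rgb_image: np.ndarray) -> np.ndarray:
    """Boolean tissue mask of an RGB tile (True = tissue).

    Saturation-intensity thresholding: bright desaturated (glass) and
    near-black pixels are background; among the rest, Otsu's threshold on the
    saturation channel (capped so weakly stained tissue is not discarded)
    separates residual background.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.dtype != np.float64 and img.dtype != np.float32:
        img = img.astype(np.float64) / 255.0
    hsv = rgb2hsv(img)
    sat, val = hsv[..., 1], hsv[..., 2]
    white = (val > _WHITE_V) & (sat < _WHITE_S)
    black = val < _BLACK_V
    candidate = ~white & ~black
    if not candidate.any():
        return np.zeros(img.shape[:2], dtype=bool)
    sat_cand = sat[candidate]
    if np.ptp(sat_cand) > 1e-6:
        thr = min(float(threshold_otsu(sat_cand)), _SAT_CAP)
    else:
        thr = _SAT_FLOOR
    thr = max(thr, _SAT_FLOOR)
    return candidate & (sat >= thr)


def tile_and_filter(
    rgb_image: np.ndarray,
    mask: np.ndarray,
    grid: TileGrid = TileGrid(),
    min_tissue_fraction: float = 0.8,
) -> list[tuple[tuple[int, int, int, int], np.ndarray]]:
    """Tile an image on a non-overlapping grid, keeping tissue-rich patches.

    A patch is kept only if its mask coverage is *strictly greater* than
    ``min_tissue_fraction`` (default 0.8).  Returns ``[((x, y, w, h), patch)]``
    with 0-based, half-open coordinates; partial edge tiles are dropped.
    """
    img = np.asarray(rgb_image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[:2]}")
    if not 0.0 < min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in (0, 1]")
    ps = grid.patch_size
    h, w = mask.shape
    if h < ps or w < ps:
        warnings.warn(f"image {w}x{h} smaller than one {ps}-px patch; no tiles", stacklevel=2)
        return []
    out = []
    for y in range(0, h - ps + 1, ps):
        for x in range(0, w - ps + 1, ps):
            frac = mask[y:y + ps, x:x + ps].mean()
            if frac > min_tissue_fraction:
                out.append(((x, y, ps, ps), img[y:y + ps, x:x + ps]))
    return out
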