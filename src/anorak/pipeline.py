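"""Slide-level inference: tiling, color normalization, patch prediction,
stitching, majority downsampling to analysis resolution, and
small-component postprocessing.

A slide at x20 (~0.45 um/px) is divided into non-overlapping 2000-px tiles
(edge tiles anchored to the slide edge), each tile is Reinhard-normalized to
a target image, predicted patch-by-patch, and the stitched x20 label raster
is downsampled 16-fold (majority vote per block) to ~7.2 um/px before small
lepidic/papillary/cribriform/solid components are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.color import lab2rgb, rgb2lab

from .config import FilterThresholds, MASK_DOWNSAMPLE, N_CLASSES, PATCH_SIZE, TILE_SIZE
from .mask import LabelMask, SlideRaster
from .model import Network, predict_patch

__all__ = [
    "Tile", "NormalizationStats", "DEFAULT_TARGET_STATS",
    "tile_image", "stitch_tiles", "normalize_tile", "infer_slide",
    "downsample_mask", "remove_small_components",
]


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tile:
    origin: tuple          # (y, x) in slide coordinates
    pixels: np.ndarray
    padded: bool = False


def _origins(extent: int, tile: int):
    if extent <= tile:
        return [0]
    out = list(range(0, extent - tile + 1, tile))
    if out[-1] + tile < extent:
        out.append(extent - tile)      # edge tile anchored to the slide edge
    return out


def tile_image(slide, tile_px: int = TILE_SIZE):
    """Non-overlapping tile grid; bottom/right edge tiles are anchored to
    the edge (and may overlap their neighbours).  A slide smaller than one
    tile yields a single background-padded tile flagged ``padded``."""
    pixels = slide.pixels if isinstance(slide, SlideRaster) else np.asarray(slide)
    h, w = pixels.shape[:2]
    if h < tile_px or w < tile_px:
        pad_shape = (tile_px, tile_px) + pixels.shape[2:]
        padded = np.zeros(pad_shape, dtype=pixels.dtype)
        padded[:h, :w] = pixels
        return [Tile((0, 0), padded, padded=True)]
    return [Tile((y, x), pixels[y:y + tile_px, x:x + tile_px])
            for y in _origins(h, tile_px) for x in _origins(w, tile_px)]


def stitch_tiles(tiles, shape):
    """Reassemble tiles into a raster of ``shape`` (origins honoured;
    overlapping edge tiles overwrite, which restores the original raster)."""
    first = tiles[0].pixels
    out = np.zeros(tuple(shape) + first.shape[2:], dtype=first.dtype)
    for t in tiles:
        y, x = t.origin
        th = min(t.pixels.shape[0], shape[0] - y)
        tw = min(t.pixels.shape[1], shape[1] - x)
        out[y:y + th, x:x + tw] = t.pixels[:th, :tw]
    return out


# ---------------------------------------------------------------------------
# color normalization (Reinhard-style statistics matching in CIELAB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean/std of a target image in CIELAB."""

    mean: tuple
    std: tuple

    def __post_init__(self):
        if any(s <= 0 for s in self.std):
            raise ValueError("channel spreads must be positive")

    @classmethod
    def from_image(cls, rgb: np.ndarray) -> "NormalizationStats":
        lab = rgb2lab(np.asarray(rgb, dtype=np.float64) / 255.0)
        return cls(tuple(lab.reshape(-1, 3).mean(axis=0)),
                   tuple(lab.reshape(-1, 3).std(axis=0)))


#: Default normalization target: a gamut-safe Lab location/spread chosen
#: near the center of the synthetic H&E tile family, so that matching keeps
#: virtually all pixels inside the sRGB gamut (clipping would break the
#: fixed-point property of the mapping).
DEFAULT_TARGET_STATS = NormalizationStats(
    mean=(78.0, 12.0, -9.0), std=(10.0, 8.0, 7.0))

_MIN_SPREAD = 1e-3


def normalize_tile(tile: np.ndarray,
                   target: NormalizationStats = DEFAULT_TARGET_STATS) -> np.ndarray:
    """Match the tile's per-channel Lab location/spread to the target.

    Blank tiles (near-zero variance in every channel) are returned
    unchanged.  The mapping is deterministic and idempotent up to uint8
    rounding.
    """
    tile = np.asarray(tile)
    lab = rgb2lab(tile.astype(np.float64) / 255.0)
    flat = lab.reshape(-1, 3)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    if np.all(std < _MIN_SPREAD):
        return tile.copy()
    std = np.maximum(std, _MIN_SPREAD)
    out = (lab - mean) / std * np.asarray(target.std) + np.asarray(target.mean)
    rgb = np.clip(lab2rgb(out), 0.0, 1.0)
    return np.round(rgb * 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# mask postprocessing
# ---------------------------------------------------------------------------

def downsample_mask(mask: LabelMask, factor: int = MASK_DOWNSAMPLE) -> LabelMask:
    """Block-majority downsampling; ties go to the lowest class index."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return mask.copy()
    labels = mask.labels
    h, w = labels.shape
    ho, wo = -(-h // factor), -(-w // factor)
    yy = np.arange(h) // factor
    xx = np.arange(w) // factor
    block = (yy[:, None] * wo + xx[None, :]).ravel()
    counts = np.zeros((ho * wo, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (block, labels.ravel()), 1)
    out = counts.argmax(axis=1).astype(np.uint8).reshape(ho, wo)
    return LabelMask(out, mask.mpp * factor if mask.mpp else None)


def remove_small_components(mask: LabelMask,
                            thresholds: FilterThresholds | None = None) -> LabelMask:
    """Relabel to non-tumor every connected component whose area falls
    strictly below its class threshold; classes without a threshold
    (acinar, micropapillary) are never touched.  Idempotent."""
    if mask.mpp is None:
        raise ValueError("mask has no mpp; cannot convert areas to mm^2")
    thresholds = thresholds or FilterThresholds()
    px_area = mask.pixel_area_mm2()
    out = mask.labels.copy()
    for cls, min_mm2 in thresholds.min_area_mm2.items():
        binary = out == cls
        if not binary.any():
            continue
        comp = measure.label(binary, connectivity=2)
        areas = np.bincount(comp.ravel())
        small = np.flatnonzero(areas * px_area < min_mm2)
        small = small[small > 0]
        if small.size:
            out[np.isin(comp, small)] = 0
    return LabelMask(out, mask.mpp)


# ---------------------------------------------------------------------------
# whole-slide inference
# ---------------------------------------------------------------------------

def infer_slide(network: Network, slide: SlideRaster,
                target: NormalizationStats = DEFAULT_TARGET_STATS,
                thresholds: FilterThresholds | None = None,
                tile_px: int = TILE_SIZE, patch_px: int = PATCH_SIZE,
                context_px: int = 0, normalize: bool = True,
                postprocess: bool = True) -> LabelMask:
    """Segment a slide at x20 and return the analysis-resolution LabelMask.

    ``patch_px`` is the network input size; it defaults to the 768-px
    training patch and must be divisible by 64.  ``context_px`` adds a
    reflect-padded halo around each patch that is predicted but discarded,
    suppressing seam artifacts at patch borders (patch_px + 2*context_px
    must stay divisible by 64).  The output mpp is 16 x the slide mpp.
    """
    if slide.mpp is None:
        raise ValueError("slide has no mpp metadata; refusing to guess")
    h, w = slide.pixels.shape[:2]
    c = int(context_px)
    label_tiles = []
    for tile in tile_image(slide, tile_px):
        pix = normalize_tile(tile.pixels, target) if normalize else tile.pixels
        patches = tile_image(pix, patch_px)
        if c:
            padded = np.pad(pix, ((c, c), (c, c), (0, 0)), mode="reflect")
        pred_patches = []
        for p in patches:
            if c:
                y, x = p.origin
                window = padded[y:y + patch_px + 2 * c, x:x + patch_px + 2 * c]
                _, lab = predict_patch(network, window)
                lab = lab[c:c + patch_px, c:c + patch_px]
            else:
                _, lab = predict_patch(network, p.pixels)
            pred_patches.append(Tile(p.origin, lab))
        tile_lab = stitch_tiles(pred_patches, pix.shape[:2])
        label_tiles.append(Tile(tile.origin, tile_lab))
    full = stitch_tiles(label_tiles, (max(h, tile_px), max(w, tile_px)))[:h, :w]
    mask20 = LabelMask(full, slide.mpp)
    mask = downsample_mask(mask20, MASK_DOWNSAMPLE)
    if postprocess:
        mask = remove_small_components(mask, thresholds)
    return mask
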