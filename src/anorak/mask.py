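"""Pixel-label raster with resolution metadata.

The interchange object between segmentation and the analytics layer: an
HxW uint8 raster over the seven-class codebook plus the microns-per-pixel
at which it was produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import N_CLASSES

__all__ = ["LabelMask", "SlideRaster"]


@dataclass
class LabelMask:
    labels: np.ndarray
    mpp: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("labels outside the 7-class codebook")
        if self.mpp is not None and self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self):
        return self.labels.shape

    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm^2."""
        return (self.mpp / 1000.0) ** 2

    def class_counts(self) -> np.ndarray:
        """Pixel count per class id, length 7."""
        return np.bincount(self.labels.ravel(), minlength=N_CLASSES)[:N_CLASSES]

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.mpp)


@dataclass
class SlideRaster:
    """RGB slide (or slide region) with its native microns-per-pixel."""

    pixels: np.ndarray
    mpp: float | None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3 RGB")

    @property
    def shape(self):
        return self.pixels.shape
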