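"""Island morphometry and the acinar scattering score.

An *island* is a connected component (8-connectivity) of one pattern class
in the analysis-resolution label mask.  Island shape is summarized by its
pixel area and solidity (pixel count over convex-hull pixel count); the
spatial dispersion of a slide's acinar islands is the standard distance

    d = sqrt( (sum_i (x_i - x_0)^2 + sum_i (y_i - y_0)^2) / (n * N) )

with island centroids (x_i, y_i), their mean center (x_0, y_0), island
count n and tissue pixel area N.  Tumor-level: mean area/solidity over all
islands of all slides, and the median of per-slide d, dichotomized at the
fixed cutoff 0.36 (strictly greater is "high").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from math import gcd

from scipy.spatial import Delaunay, QhullError

from .config import CLASS_IDS
from .mask import LabelMask

__all__ = [
    "Island", "IslandSet", "TumorSpatialSummary",
    "extract_islands", "island_morphology", "acinar_scattering",
    "tumor_spatial_summary", "hull_pixel_count", "SCATTERING_CUTOFF",
]

#: Dichotomization cutoff for the tumor-level acinar scattering score.
SCATTERING_CUTOFF = 0.36


@dataclass(frozen=True)
class Island:
    class_id: int
    pixel_count: int
    area_mm2: float
    centroid: tuple                  # (x, y) = (col, row) pixel-center mean
    convex_hull_pixel_count: int
    solidity: float


@dataclass
class IslandSet:
    """Islands of one class on one slide plus the tissue area N (pixels)."""

    islands: list
    tissue_area: int
    mpp: float
    class_id: int

    @property
    def n(self) -> int:
        return len(self.islands)

    @property
    def mean_center(self) -> tuple:
        if not self.islands:
            raise ValueError("mean center undefined for an empty island set")
        xs = [i.centroid[0] for i in self.islands]
        ys = [i.centroid[1] for i in self.islands]
        return (float(np.mean(xs)), float(np.mean(ys)))


@dataclass(frozen=True)
class TumorSpatialSummary:
    mean_acinar_area_mm2: float | None
    mean_solidity: float | None
    morphology_eligible: bool
    scattering_d: float | None
    scattering_class: str | None     # "low" / "high", None when undefined
    n_islands_total: int


def hull_pixel_count(coords: np.ndarray) -> int:
    """Pixels whose centers lie in the convex hull of the given pixel centers.

    This is the rasterized-hull denominator of the solidity index.  For
    degenerate (single-pixel or collinear) islands the hull is the segment
    between the extreme members, which passes through gcd(|dy|,|dx|)+1
    integer centers.
    """
    coords = np.unique(np.asarray(coords, dtype=np.int64), axis=0)
    if len(coords) == 1:
        return 1
    try:
        tri = Delaunay(coords)
    except QhullError:                       # collinear members
        d = coords.max(axis=0) - coords.min(axis=0)
        return gcd(int(d[0]), int(d[1])) + 1
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    yy, xx = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1]
    centers = np.stack([yy.ravel(), xx.ravel()], axis=1)
    return int((tri.find_simplex(centers) >= 0).sum())


def extract_islands(mask: LabelMask, class_id, connectivity: int = 8,
                    tissue_area: int | None = None) -> IslandSet:
    """Connected components of one class with centroid/area/solidity.

    ``tissue_area`` N defaults to the count of non-background pixels in the
    mask; pass an explicit value when a tissue mask from the original image
    is available.  An absent class yields an empty set (not an error).
    """
    if mask.mpp is None:
        raise ValueError("mask has no mpp")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    cid = CLASS_IDS[class_id] if isinstance(class_id, str) else int(class_id)
    labels = mask.labels
    if tissue_area is None:
        tissue_area = int((labels > 0).sum())
    comp = measure.label(labels == cid, connectivity=2 if connectivity == 8 else 1)
    px_area = mask.pixel_area_mm2()
    islands = []
    for region in measure.regionprops(comp):
        hull = hull_pixel_count(region.coords)
        row, col = region.centroid
        islands.append(Island(
            class_id=cid,
            pixel_count=int(region.area),
            area_mm2=float(region.area) * px_area,
            centroid=(float(col), float(row)),
            convex_hull_pixel_count=hull,
            solidity=float(region.area) / hull,
        ))
    return IslandSet(islands=islands, tissue_area=tissue_area,
                     mpp=mask.mpp, class_id=cid)


def island_morphology(island: Island):
    """(area in mm^2, solidity) of one island."""
    return island.area_mm2, island.solidity


def acinar_scattering(islands: IslandSet) -> float:
    """Standard distance of the island centroids, normalized by n x N.

    Dimensionless; 0 for a single island.  Undefined (raises) for an empty
    set — callers must distinguish "no acinar" from "not scattered".
    """
    if islands.n == 0:
        raise ValueError("scattering undefined: no islands")
    if islands.tissue_area <= 0:
        raise ValueError("tissue area must be positive")
    x0, y0 = islands.mean_center
    ss = 0.0
    for isl in islands.islands:
        ss += (isl.centroid[0] - x0) ** 2 + (isl.centroid[1] - y0) ** 2
    return float(np.sqrt(ss / (islands.n * islands.tissue_area)))


def tumor_spatial_summary(per_slide, acinar_fraction: float | None = None,
                          min_acinar_fraction: float = 0.05,
                          cutoff: float = SCATTERING_CUTOFF
                          ) -> TumorSpatialSummary:
    """Aggregate per-slide acinar island sets to tumor level.

    Morphology features are unweighted means over all islands pooled across
    slides, reported only when the tumor's acinar proportion reaches
    ``min_acinar_fraction`` (pass ``acinar_fraction=None`` to skip the
    eligibility test).  The scattering score is the median of per-slide d
    over slides with at least one island; slides without acinar islands are
    excluded rather than imputed.  The class is "high" iff d > cutoff.
    """
    per_slide = list(per_slide)
    if not per_slide:
        raise ValueError("at least one slide is required")
    pooled = [i for s in per_slide for i in s.islands]

    eligible = acinar_fraction is None or acinar_fraction >= min_acinar_fraction
    if pooled and eligible:
        mean_area = float(np.mean([i.area_mm2 for i in pooled]))
        mean_sol = float(np.mean([i.solidity for i in pooled]))
    else:
        mean_area = mean_sol = None

    ds = [acinar_scattering(s) for s in per_slide if s.n >= 1]
    if ds:
        d_med = float(np.median(ds))
        s_class = "high" if d_med > cutoff else "low"
    else:
        d_med, s_class = None, None

    return TumorSpatialSummary(
        mean_acinar_area_mm2=mean_area,
        mean_solidity=mean_sol,
        morphology_eligible=bool(eligible),
        scattering_d=d_med,
        scattering_class=s_class,
        n_islands_total=len(pooled),
    )
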