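"""Deterministic synthetic data: pattern-caricature tiles, island layouts
and multi-slide tumors.

The tile textures are *caricatures* of the six LUAD growth patterns — each
pattern gets a procedural texture whose nuclear density, lumen geometry and
stroma coloring echo the defining morphology (solid sheets, acinar glands
around lumina, cribriform sieve plates, papillary fronds, micropapillary
tufts, lepidic septa).  They are sufficient for overfit and round-trip
testing of the segmentation and analytics layers; they are not
histologically realistic and must not be used as a benchmark.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .config import CLASS_IDS, CLASS_NAMES, MPP_ANALYSIS, MPP_X20, PATTERN_IDS
from .mask import LabelMask, SlideRaster

__all__ = [
    "IslandSpec", "TumorSpec",
    "generate_pattern_tile", "generate_island_layout", "generate_tumor_masks",
    "render_slide_from_mask", "white_fraction",
]

# H&E caricature palette
_BG = np.array([244, 242, 246], dtype=np.float32)        # glass / airspace
_LUMEN = np.array([250, 249, 252], dtype=np.float32)     # gland lumina
_AIR = np.array([239, 224, 234], dtype=np.float32)       # intratumoral airspace
_AIR_COOL = np.array([228, 236, 244], dtype=np.float32)  # retraction cleft airspace
_PINK = np.array([228, 158, 192], dtype=np.float32)      # eosinophilic stroma
_CYTO = np.array([186, 138, 196], dtype=np.float32)      # pale cytoplasm
_CYTO_DARK = np.array([150, 108, 170], dtype=np.float32)
_NUC = np.array([64, 42, 110], dtype=np.float32)         # hematoxylin nuclei

_WHITE_LUM_THRESHOLD = 225.0


def white_fraction(img: np.ndarray, region: np.ndarray | None = None) -> float:
    """Fraction of (region) pixels brighter than the white-lumen threshold."""
    lum = img.astype(np.float32) @ np.array([0.299, 0.587, 0.114], np.float32)
    sel = lum if region is None else lum[region]
    return float(np.mean(sel > _WHITE_LUM_THRESHOLD))


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------

_FOOTPRINTS: dict = {}


def _disc(r: int) -> np.ndarray:
    fp = _FOOTPRINTS.get(("d", r))
    if fp is None:
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        fp = yy * yy + xx * xx <= r * r
        _FOOTPRINTS[("d", r)] = fp
    return fp


def _annulus(r_out: int, r_in: int) -> np.ndarray:
    fp = _FOOTPRINTS.get(("a", r_out, r_in))
    if fp is None:
        yy, xx = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1]
        d2 = yy * yy + xx * xx
        fp = (d2 <= r_out * r_out) & (d2 > r_in * r_in)
        _FOOTPRINTS[("a", r_out, r_in)] = fp
    return fp


def _stamp(img, region, cy, cx, fp, color):
    """Paint ``fp`` centered at (cy, cx), clipped to bounds and region."""
    r = fp.shape[0] // 2
    h, w = region.shape
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    sub = fp[y0 - (cy - r):y1 - (cy - r), x0 - (cx - r):x1 - (cx - r)]
    sel = sub & region[y0:y1, x0:x1]
    img[y0:y1, x0:x1][sel] = color


def _random_centers(rng, region, count):
    """Sample ~count points uniformly inside the region."""
    h, w = region.shape
    n_try = int(count * 1.6) + 8
    ys = rng.integers(0, h, n_try)
    xs = rng.integers(0, w, n_try)
    keep = region[ys, xs]
    return ys[keep][:count], xs[keep][:count]


def _walk(rng, start, n_steps, step=2.0, wiggle=0.35):
    """Curvilinear random walk returning integer path coordinates."""
    y, x = float(start[0]), float(start[1])
    theta = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps, 2), dtype=np.int64)
    for i in range(n_steps):
        theta += rng.normal(0.0, wiggle)
        y += step * np.sin(theta)
        x += step * np.cos(theta)
        pts[i] = (int(round(y)), int(round(x)))
    return pts


# ---------------------------------------------------------------------------
# pattern textures (draw in place within a boolean region)
# ---------------------------------------------------------------------------

def _texture_solid(img, region, rng):
    """Dense sheet of packed dark nuclei, almost no lumina."""
    img[region] = _NUC
    area = int(region.sum())
    ys, xs = _random_centers(rng, region, int(area * 0.004))
    for cy, cx in zip(ys, xs):
        _stamp(img, region, cy, cx, _disc(2), _CYTO)
    ys, xs = _random_centers(rng, region, int(area * 0.0004))
    for cy, cx in zip(ys, xs):
        _stamp(img, region, cy, cx, _disc(2), _LUMEN)


def _texture_cribriform(img, region, rng):
    """Large nuclear mass punched by many small lumina (sieve plate)."""
    img[region] = _CYTO_DARK
    area = int(region.sum())
    ys, xs = _random_centers(rng, region, int(area * 0.012))
    for cy, cx in zip(ys, xs):
        _stamp(img, region, cy, cx, _disc(2), _NUC)
    ys, xs = _random_centers(rng, region, int(area * 0.0022))
    for cy, cx in zip(ys, xs):
        _stamp(img, region, cy, cx, _disc(4), _LUMEN)


_LUMEN_SECRETION = np.array([247, 236, 242], dtype=np.float32)


def _texture_acinar(img, region, rng):
    """Nucleus rings around small round lumina embedded in pink stroma.

    Lumina carry a faint eosinophilic secretion tint so they read as gland
    interiors rather than glass."""
    img[region] = _PINK
    h, w = region.shape
    spacing = 26
    for gy in range(spacing // 2, h, spacing):
        for gx in range(spacing // 2, w, spacing):
            cy = gy + int(rng.integers(-6, 7))
            cx = gx + int(rng.integers(-6, 7))
            if 0 <= cy < h and 0 <= cx < w and region[cy, cx]:
                _stamp(img, region, cy, cx, _annulus(11, 7), _NUC)
                _stamp(img, region, cy, cx, _disc(7), _LUMEN_SECRETION)


def _texture_papillary(img, region, rng):
    """Branching pink fibrovascular cores lined by nuclei, in open space."""
    img[region] = _AIR
    area = int(region.sum())
    n_paths = max(2, area // 6000)
    ys, xs = _random_centers(rng, region, n_paths)
    for cy, cx in zip(ys, xs):
        pts = _walk(rng, (cy, cx), n_steps=180, step=2.0, wiggle=0.2)
        for k, (py, px) in enumerate(pts):
            if k % 2 == 0:
                _stamp(img, region, py, px, _annulus(10, 6), _NUC)
        for py, px in pts:
            _stamp(img, region, py, px, _disc(6), _PINK)


def _texture_micropapillary(img, region, rng):
    """Small detached nuclear tufts floating in cleft-like white space."""
    img[region] = _AIR_COOL
    area = int(region.sum())
    ys, xs = _random_centers(rng, region, int(area * 0.005))
    for cy, cx in zip(ys, xs):
        _stamp(img, region, cy, cx, _annulus(5, 2), _NUC)
        _stamp(img, region, cy, cx, _disc(2), _CYTO)


def _texture_lepidic(img, region, rng):
    """Thin curvilinear septa dotted with nuclei; mostly airspace."""
    img[region] = _AIR
    area = int(region.sum())
    n_curves = max(1, area // 18000)
    ys, xs = _random_centers(rng, region, n_curves)
    for cy, cx in zip(ys, xs):
        pts = _walk(rng, (cy, cx), n_steps=260, step=2.0, wiggle=0.18)
        for py, px in pts:
            _stamp(img, region, py, px, _disc(1), _PINK)
        for k, (py, px) in enumerate(pts):
            if k % 6 == 0:
                _stamp(img, region, py, px, _disc(2), _NUC)


_TEXTURES = {
    CLASS_IDS["solid"]: _texture_solid,
    CLASS_IDS["cribriform"]: _texture_cribriform,
    CLASS_IDS["acinar"]: _texture_acinar,
    CLASS_IDS["papillary"]: _texture_papillary,
    CLASS_IDS["micropapillary"]: _texture_micropapillary,
    CLASS_IDS["lepidic"]: _texture_lepidic,
}


def _blob_region(rng, size: int) -> np.ndarray:
    """Wobbly ellipse covering roughly half the tile."""
    r0 = 0.42 * size
    amps = rng.uniform(0.03, 0.08, 3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - size / 2.0, xx - size / 2.0
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = r0 * (1.0 + sum(a * np.sin((k + 2) * theta + p)
                               for k, (a, p) in enumerate(zip(amps, phases))))
    return rr < boundary


def generate_pattern_tile(pattern, size: int = 768, seed: int = 0,
                          full_region: bool = False):
    """Render one growth-pattern caricature tile with its ground-truth mask.

    Parameters
    ----------
    pattern : str or int
        Growth-pattern name or class id (1-6).
    size : int
        Tile edge in pixels at x20 (~0.45 um/px).
    seed : int
        Generator seed; identical seeds give bit-identical tiles.
    full_region : bool
        Texture the whole tile instead of a central blob.

    Returns
    -------
    (image, mask) : HxWx3 uint8 RGB and HxW uint8 labels in {0, pattern}.
    """
    cls = CLASS_IDS[pattern] if isinstance(pattern, str) else int(pattern)
    if cls != 0 and cls not in _TEXTURES:
        raise ValueError(f"unknown growth pattern {pattern!r}")
    rng = np.random.default_rng([seed, cls, size])
    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = _BG
    if cls == 0:
        region = np.zeros((size, size), bool)   # bare glass tile
    else:
        region = np.ones((size, size), bool) if full_region else _blob_region(rng, size)
        _TEXTURES[cls](img, region, rng)
    img += rng.normal(0.0, 3.0, img.shape).astype(np.float32)
    img = np.clip(img, 0, 255).astype(np.uint8)
    mask = np.where(region, cls, 0).astype(np.uint8)
    return img, mask


def generate_mosaic_tile(size: int = 128, seed: int = 0, n_cells: int = 4):
    """Render a multi-pattern tile: a Voronoi mosaic of random patterns.

    Cells are textured like :func:`generate_pattern_tile` regions;
    occasionally one cell is background glass.  Mosaics expose the network
    to pattern borders during training, which single-pattern tiles cannot.
    Returns ``(image, mask)``.
    """
    rng = np.random.default_rng([seed, 31])
    pts = rng.uniform(0, size, (n_cells, 2))
    cls = rng.integers(1, 7, n_cells)
    if rng.random() < 0.3:
        cls[0] = 0
    yy, xx = np.mgrid[0:size, 0:size]
    d = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    mask = cls[np.argmin(d, axis=2)].astype(np.uint8)
    slide = render_slide_from_mask(mask, seed=seed)
    return slide.pixels, mask


def render_slide_from_mask(mask20: np.ndarray, mpp: float = MPP_X20,
                           seed: int = 0) -> SlideRaster:
    """Render an H&E-caricature slide from a x20 label raster.

    Each labeled region is textured with its pattern caricature; class 0 is
    left as background glass.  Used to build end-to-end test slides whose
    ground truth is known exactly.
    """
    mask20 = np.asarray(mask20)
    rng = np.random.default_rng([seed, 97])
    img = np.empty(mask20.shape + (3,), dtype=np.float32)
    img[:] = _BG
    for cls in np.unique(mask20):
        if cls == 0:
            continue
        _TEXTURES[int(cls)](img, mask20 == cls, rng)
    img += rng.normal(0.0, 3.0, img.shape).astype(np.float32)
    return SlideRaster(np.clip(img, 0, 255).astype(np.uint8), mpp)


# ---------------------------------------------------------------------------
# island layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandSpec:
    """One island to place: class, target area (px), shape and centroid."""

    class_id: int
    target_pixel_count: int
    shape: str = "square"            # square | disc | L | ellipse
    centroid: tuple = (0.0, 0.0)     # (x, y) in mask pixel coordinates


def _float_disc(ry: float, rx: float, oy: float = 0.0, ox: float = 0.0) -> np.ndarray:
    """Rasterized ellipse with float semi-axes (pixel-center inclusion).

    ``oy``/``ox`` offset the center by a sub-pixel amount, which breaks the
    4-fold symmetry and makes the achievable pixel counts much denser.
    """
    by, bx = int(np.ceil(ry + abs(oy))), int(np.ceil(rx + abs(ox)))
    yy, xx = np.mgrid[-by:by + 1, -bx:bx + 1]
    return ((yy - oy) / ry) ** 2 + ((xx - ox) / rx) ** 2 <= 1.0


def _best_radius_footprint(target: int, make) -> np.ndarray:
    """Fine-scan size and sub-pixel center to approach the target count."""
    r0 = np.sqrt(target / np.pi)
    best, best_err = None, None
    for oy, ox in ((0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5),
                   (0.25, 0.0), (0.0, 0.25)):
        for r in np.arange(max(0.7, r0 - 1.5), r0 + 1.5, 0.01):
            fp = make(r, oy, ox)
            err = abs(int(fp.sum()) - target)
            if best_err is None or err < best_err:
                best, best_err = fp, err
                if err == 0:
                    return best
    return best


def _shape_footprint(shape: str, target: int) -> np.ndarray:
    if shape == "square":
        s = max(1, round(np.sqrt(target)))
        return np.ones((s, s), bool)
    if shape == "disc":
        return _best_radius_footprint(
            target, lambda r, oy, ox: _float_disc(r, r, oy, ox))
    if shape == "ellipse":
        return _best_radius_footprint(
            target, lambda r, oy, ox: _float_disc(r / np.sqrt(2),
                                                  r * np.sqrt(2), oy, ox))
    if shape == "L":
        # vertical arm a x h plus horizontal arm w x b sharing an a x b
        # corner: area = a*h + b*w - a*b.  Unequal thicknesses make every
        # target attainable exactly with balanced arms.
        t0 = max(2, round(np.sqrt(target / 3.0)))
        best = None
        for a, b in ((t0, t0), (t0, t0 + 1), (t0 + 1, t0),
                     (max(2, t0 - 1), t0), (t0, max(2, t0 - 1))):
            for h in range(b + 2, 6 * t0 + 4):
                rem = target + a * b - a * h
                if rem <= 0 or rem % b:
                    continue
                w = rem // b
                if w <= a + 1:
                    continue
                if best is None or abs(h - w) < best[0]:
                    best = (abs(h - w), a, b, h, w)
        if best is not None:
            _, a, b, h, w = best
            fp = np.zeros((h, w), bool)
            fp[:, :a] = True
            fp[-b:, :] = True
            return fp
        t = t0
        w = max(t + 1, round((target + t * t) / (2.0 * t)))
        fp = np.zeros((w, w), bool)
        fp[:, :t] = True
        fp[-t:, :] = True
        return fp
    raise ValueError(f"unknown island shape {shape!r}")


def generate_island_layout(specs, canvas, mpp: float = MPP_ANALYSIS,
                           seed: int = 0, tolerance: float = 0.02):
    """Place the specified islands on an empty canvas.

    Returns ``(LabelMask, ground_truth)`` where ground_truth is a list of
    dicts with the realized pixel_count, centroid (x, y), convex-hull pixel
    count and solidity of every island, computed directly from the placed
    footprints (integer geometry).

    Raises ``ValueError`` for out-of-canvas or overlapping placements, or a
    realized area deviating more than ``tolerance`` from target (squares and
    L-shapes aside, rasterization makes exact targets unattainable).
    """
    h, w = canvas
    labels = np.zeros((h, w), dtype=np.uint8)
    occupied = np.zeros((h, w), bool)
    truth = []
    for spec in specs:
        fp = _shape_footprint(spec.shape, spec.target_pixel_count)
        realized = int(fp.sum())
        if abs(realized - spec.target_pixel_count) > tolerance * spec.target_pixel_count:
            raise ValueError(
                f"{spec.shape} island of {spec.target_pixel_count} px cannot be "
                f"rasterized within {tolerance:.0%} (got {realized})")
        fh, fw = fp.shape
        cx, cy = spec.centroid
        ys, xs = np.nonzero(fp)
        # anchor so that the realized centroid lands on the requested one
        y0 = int(round(cy - ys.mean()))
        x0 = int(round(cx - xs.mean()))
        if y0 < 0 or x0 < 0 or y0 + fh > h or x0 + fw > w:
            raise ValueError(f"island at {spec.centroid} does not fit the canvas")
        window = occupied[y0:y0 + fh, x0:x0 + fw]
        if np.any(window & fp):
            raise ValueError(f"island at {spec.centroid} overlaps a previous one")
        labels[y0:y0 + fh, x0:x0 + fw][fp] = spec.class_id
        occupied[y0:y0 + fh, x0:x0 + fw] |= fp
        from .spatial import hull_pixel_count
        hull = hull_pixel_count(np.stack([ys, xs], axis=1))
        truth.append({
            "class_id": spec.class_id,
            "pixel_count": realized,
            "centroid": (x0 + xs.mean(), y0 + ys.mean()),
            "convex_hull_pixel_count": hull,
            "solidity": realized / hull,
        })
    return LabelMask(labels, mpp), truth


# ---------------------------------------------------------------------------
# multi-slide tumors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorSpec:
    """A multi-slide tumor with prescribed pooled pattern composition."""

    n_slides: int = 3
    proportions: dict = field(default_factory=dict)   # pattern name/id -> g_j
    seed: int = 0
    slide_shape: tuple = (200, 300)
    tumor_pixels_per_slide: int = 30000

    def __post_init__(self):
        total = float(np.sum(list(self.proportions.values())))
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"proportions must sum to 1, got {total}")


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer apportionment of ``total`` by weights."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(np.int64)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_tumor_masks(spec: TumorSpec):
    """Build per-slide label masks whose *pooled* composition matches the
    target proportions (within rounding of one pixel in the total).

    Per-slide mixes are deliberately uneven, so pooling pixel counts across
    slides and averaging per-slide proportions give different answers — the
    discriminating case for the tumor-level proportion formula.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [CLASS_IDS[k] if isinstance(k, str) else int(k)
           for k in spec.proportions]
    for cid in ids:
        if cid not in PATTERN_IDS:
            raise ValueError(f"class {cid} is not a growth pattern")
    g = np.array(list(spec.proportions.values()), dtype=np.float64)
    total = spec.n_slides * spec.tumor_pixels_per_slide
    pooled = _apportion(g, total)

    h, w = spec.slide_shape
    if spec.tumor_pixels_per_slide > h * w:
        raise ValueError("tumor_pixels_per_slide exceeds slide capacity")
    # uneven split of each pattern across slides
    per_slide = np.zeros((spec.n_slides, len(ids)), dtype=np.int64)
    for j, cj in enumerate(pooled):
        wts = rng.dirichlet(np.full(spec.n_slides, 0.8)) + 1e-9
        per_slide[:, j] = _apportion(wts, int(cj))
    # rebalance any slide over capacity by moving pixels to the emptiest slide
    cap = h * w
    for _ in range(1000):
        load = per_slide.sum(axis=1)
        over = int(np.argmax(load))
        if load[over] <= cap:
            break
        under = int(np.argmin(load))
        j = int(np.argmax(per_slide[over]))
        move = min(per_slide[over, j], load[over] - cap)
        per_slide[over, j] -= move
        per_slide[under, j] += move

    masks = []
    for i in range(spec.n_slides):
        flat = np.zeros(h * w, dtype=np.uint8)
        pos = 0
        for j, cid in enumerate(ids):
            cnt = int(per_slide[i, j])
            flat[pos:pos + cnt] = cid
            pos += cnt
        masks.append(LabelMask(flat.reshape(h, w), MPP_ANALYSIS))
    return masks
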