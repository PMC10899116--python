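"""Island extraction, morphometry, and the acinar scattering score."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import MultiPoint, Point

from anorak.mask import LabelMask
from anorak.spatial import (IslandSet, acinar_scattering, extract_islands,
                            hull_pixel_count, island_morphology,
                            tumor_spatial_summary)

MPP = 7.2


def _mask(labels):
    return LabelMask(np.asarray(labels, np.uint8), MPP)


def _shapely_hull_count(coords):
    """Independent rasterized-hull oracle: pixel centers covered by the
    convex hull polygon of the member pixel centers."""
    hull = MultiPoint([tuple(map(float, c)) for c in coords]).convex_hull
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    count = 0
    for y in range(lo[0], hi[0] + 1):
        for x in range(lo[1], hi[1] + 1):
            if hull.covers(Point(float(y), float(x))):
                count += 1
    return count


class TestExtractIslands:
    def test_two_separated_squares(self):
        labels = np.zeros((20, 20))
        labels[2:7, 2:7] = 3
        labels[12:17, 12:17] = 3
        isl = extract_islands(_mask(labels), 3)
        assert isl.n == 2
        assert all(i.pixel_count == 25 for i in isl.islands)
        assert all(i.solidity == 1.0 for i in isl.islands)

    def test_diagonal_touch_merges_under_8_splits_under_4(self):
        labels = np.zeros((6, 6))
        labels[1, 1] = 3
        labels[2, 2] = 3
        assert extract_islands(_mask(labels), 3, connectivity=8).n == 1
        assert extract_islands(_mask(labels), 3, connectivity=4).n == 2

    def test_absent_class_yields_empty_set(self):
        isl = extract_islands(_mask(np.zeros((5, 5))), 3)
        assert isl.n == 0
        with pytest.raises(ValueError):
            acinar_scattering(isl)

    def test_pixel_counts_match_bruteforce_flood_fill(self, rng):
        labels = (rng.random((40, 40)) < 0.3).astype(np.uint8) * 3
        isl = extract_islands(_mask(labels), 3)
        # independent flood fill (8-neighbourhood)
        seen = np.zeros_like(labels, bool)
        sizes = []
        for sy, sx in np.argwhere(labels == 3):
            if seen[sy, sx]:
                continue
            stack, size = [(sy, sx)], 0
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < 40 and 0 <= nx < 40
                                and labels[ny, nx] == 3 and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            sizes.append(size)
        assert sorted(i.pixel_count for i in isl.islands) == sorted(sizes)

    def test_centroids_are_pixel_center_means(self):
        labels = np.zeros((10, 10))
        labels[2:4, 3:7] = 3                      # rows 2-3, cols 3-6
        isl = extract_islands(_mask(labels), 3)
        assert isl.islands[0].centroid == (4.5, 2.5)   # (x=col, y=row)


class TestMorphology:
    def test_square_area_and_solidity(self):
        labels = np.zeros((20, 20))
        labels[4:14, 4:14] = 3
        isl = extract_islands(_mask(labels), 3)
        area, solidity = island_morphology(isl.islands[0])
        assert area == pytest.approx(100 * (7.2 / 1000) ** 2)   # 0.005184 mm^2
        assert solidity == 1.0

    def test_l_shape_solidity_matches_hull_oracle(self):
        labels = np.zeros((20, 20))
        labels[5:15, 5:10] = 3                   # vertical 10x5 arm
        labels[10:15, 5:15] = 3                  # horizontal 5x10 arm
        isl = extract_islands(_mask(labels), 3)
        island = isl.islands[0]
        coords = np.argwhere(labels == 3)
        want_hull = _shapely_hull_count(coords)
        assert island.convex_hull_pixel_count == want_hull
        assert island.solidity == pytest.approx(island.pixel_count / want_hull)
        assert island.solidity < 1.0

    def test_random_blobs_match_hull_oracle(self, rng):
        for _ in range(5):
            m = np.zeros((25, 25), np.uint8)
            ys, xs = rng.integers(3, 22, 6), rng.integers(3, 22, 6)
            for y, x in zip(ys, xs):
                m[y - 1:y + 2, x - 1:x + 2] = 3
            isl = extract_islands(_mask(m), 3, connectivity=8)
            # compare the largest island against the oracle
            big = max(isl.islands, key=lambda i: i.pixel_count)
            from skimage import measure
            comp = measure.label(m == 3, connectivity=2)
            region = max(measure.regionprops(comp), key=lambda r: r.area)
            assert big.convex_hull_pixel_count == _shapely_hull_count(region.coords)

    def test_solidity_never_exceeds_one(self, rng):
        m = (rng.random((30, 30)) < 0.25).astype(np.uint8) * 3
        for island in extract_islands(_mask(m), 3).islands:
            assert 0 < island.solidity <= 1.0
            assert island.convex_hull_pixel_count >= island.pixel_count

    def test_degenerate_line_island(self):
        labels = np.zeros((8, 8))
        labels[2, 1:6] = 3                       # 1x5 line
        isl = extract_islands(_mask(labels), 3)
        assert isl.islands[0].solidity == 1.0
        assert hull_pixel_count(np.array([[0, 0], [2, 2]])) == 3


class TestScattering:
    def _set(self, centroids, n_tissue):
        from anorak.spatial import Island

        islands = [Island(3, 10, 1e-3, (x, y), 10, 1.0) for x, y in centroids]
        return IslandSet(islands=islands, tissue_area=n_tissue, mpp=MPP,
                         class_id=3)

    def test_single_island_scores_zero(self):
        assert acinar_scattering(self._set([(5.0, 5.0)], 100)) == 0.0

    def test_two_islands_analytic_value(self):
        # centroids (0,0) and (2,0), N=4: d = sqrt(2 / (2*4)) = 0.5
        d = acinar_scattering(self._set([(0, 0), (2, 0)], 4))
        assert d == pytest.approx(0.5)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_bruteforce_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (12, 2))
        n_tissue = int(rng.integers(50, 5000))
        d = acinar_scattering(self._set([tuple(p) for p in pts], n_tissue))
        x0, y0 = pts[:, 0].mean(), pts[:, 1].mean()
        ss = ((pts[:, 0] - x0) ** 2).sum() + ((pts[:, 1] - y0) ** 2).sum()
        assert d == pytest.approx(np.sqrt(ss / (len(pts) * n_tissue)))
        # permutation invariance
        perm = rng.permutation(len(pts))
        assert acinar_scattering(self._set([tuple(p) for p in pts[perm]],
                                           n_tissue)) == pytest.approx(d)
        # translation invariance
        shifted = pts + np.array([37.0, -12.0])
        assert acinar_scattering(self._set([tuple(p) for p in shifted],
                                           n_tissue)) == pytest.approx(d)
        # scaling coordinates by s with N by s^2 leaves d unchanged
        s = 3.0
        assert acinar_scattering(self._set([tuple(p * s) for p in pts],
                                           round(n_tissue * s * s))
                                 ) == pytest.approx(d, rel=1e-3)

    def test_contracting_centroids_never_increases_d(self, rng):
        pts = rng.uniform(0, 50, (8, 2))
        center = pts.mean(axis=0)
        last = np.inf
        for lam in (1.0, 0.7, 0.4, 0.1):
            moved = center + lam * (pts - center)
            d = acinar_scattering(self._set([tuple(p) for p in moved], 1000))
            assert d <= last + 1e-12
            last = d


class TestTumorSummary:
    def _single_island_set(self, centroids, n_tissue=1000):
        from anorak.spatial import Island

        islands = [Island(3, 100, 100 * (MPP / 1000) ** 2, c, 100, 1.0)
                   for c in centroids]
        return IslandSet(islands, n_tissue, MPP, 3)

    def test_median_of_per_slide_d_and_cutoff(self):
        # slides with d = 0.2 and 0.6 -> median 0.4 > 0.36 -> high
        s1 = self._single_island_set([(0, 0), (4, 0)], round(2 * 4 / 0.2 ** 2 / 4))
        d1 = acinar_scattering(s1)
        s2 = self._single_island_set([(0, 0), (12, 0)], round(2 * 36 / 0.6 ** 2 / 2))
        d2 = acinar_scattering(s2)
        summary = tumor_spatial_summary([s1, s2])
        assert summary.scattering_d == pytest.approx(np.median([d1, d2]))
        assert summary.scattering_class == "high"

    def test_single_island_tumor_is_low(self):
        summary = tumor_spatial_summary([self._single_island_set([(3, 3)])])
        assert summary.scattering_d == 0.0
        assert summary.scattering_class == "low"

    def test_slides_without_islands_excluded_from_median(self):
        empty = IslandSet([], 500, MPP, 3)
        with_islands = self._single_island_set([(0, 0)])
        summary = tumor_spatial_summary([empty, with_islands])
        assert summary.scattering_d == 0.0

    def test_no_acinar_anywhere_flagged_undefined(self):
        summary = tumor_spatial_summary([IslandSet([], 500, MPP, 3)])
        assert summary.scattering_d is None
        assert summary.scattering_class is None

    def test_morphology_requires_five_percent_acinar(self):
        s = self._single_island_set([(1, 1), (5, 5)])
        eligible = tumor_spatial_summary([s], acinar_fraction=0.08)
        assert eligible.morphology_eligible
        assert eligible.mean_acinar_area_mm2 == pytest.approx(100 * (MPP / 1000) ** 2)
        ineligible = tumor_spatial_summary([s], acinar_fraction=0.03)
        assert not ineligible.morphology_eligible
        assert ineligible.mean_acinar_area_mm2 is None

    def test_means_match_pooled_island_table(self, rng):
        from anorak.spatial import Island

        sets = []
        areas, sols = [], []
        for _ in range(3):
            islands = []
            for _ in range(4):
                a = float(rng.uniform(0.001, 0.01))
                s = float(rng.uniform(0.5, 1.0))
                areas.append(a)
                sols.append(s)
                islands.append(Island(3, 10, a, (1.0, 2.0), 12, s))
            sets.append(IslandSet(islands, 1000, MPP, 3))
        summary = tumor_spatial_summary(sets)
        assert summary.mean_acinar_area_mm2 == pytest.approx(np.mean(areas))
        assert summary.mean_solidity == pytest.approx(np.mean(sols))
        assert summary.n_islands_total == 12
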