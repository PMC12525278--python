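"""Morphometry operators against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from lysomorph.image import CellImage, LabelMask, segment_channel
from lysomorph.morphometry import (
    golgi_metrics,
    lysosome_diameter,
    lysosensor_relative_intensity,
    manders_m1,
    network_porosity,
    overlap_coefficient,
    p62_aggregate_density,
    profile_peak_distance,
    standard_curve_quantify,
)


class TestManders:
    def test_hand_example(self):
        ref = np.array([[1.0, 2.0, 3.0, 4.0]])
        mask = np.array([[True, True, False, False]])
        assert manders_m1(ref, None, mask) == pytest.approx(0.3)

    def test_full_mask_gives_one(self):
        ref = np.random.default_rng(0).random((5, 5))
        assert manders_m1(ref, None, np.ones((5, 5), bool)) == pytest.approx(1.0)

    def test_disjoint_gives_zero(self):
        ref = np.zeros((4, 4))
        ref[0, 0] = 5.0
        mask = np.zeros((4, 4), bool)
        mask[3, 3] = True
        assert manders_m1(ref, None, mask) == 0.0

    def test_empty_reference_returns_zero(self):
        assert manders_m1(np.zeros((3, 3)), None, np.ones((3, 3), bool)) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            manders_m1(np.zeros((3, 3)), None, np.ones((4, 4), bool))


class TestOverlapCoefficient:
    def test_hand_example(self):
        assert overlap_coefficient([1, 0, 1], [1, 1, 0]) == pytest.approx(0.5)

    def test_identical_channels_give_one(self):
        a = np.random.default_rng(1).random(20)
        assert overlap_coefficient(a, a) == pytest.approx(1.0)

    def test_orthogonal_supports_give_zero(self):
        assert overlap_coefficient([1, 1, 0, 0], [0, 0, 2, 3]) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        r = rng.random(50)
        g = rng.random(50)
        base = overlap_coefficient(r, g)
        for _ in range(100):
            a, b = rng.uniform(0.01, 100, size=2)
            assert overlap_coefficient(a * r, b * g) == pytest.approx(base, rel=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            overlap_coefficient([0, 0], [0, 0])


class TestDiameter:
    def test_profile_hand_example(self):
        profile = (0, 1, 5, 1, 0, 1, 5, 1, 0)
        nm, resolved = profile_peak_distance(profile, spacing_nm=100.0, smooth=1)
        assert resolved
        assert nm == pytest.approx(400.0)

    def test_single_peak_flagged_unresolved(self):
        profile = (0, 1, 5, 9, 5, 1, 0)
        nm, resolved = profile_peak_distance(profile, spacing_nm=100.0, smooth=1)
        assert not resolved
        assert nm > 0

    def test_short_profile_errors(self):
        with pytest.raises(ValueError):
            profile_peak_distance((1, 2), 100.0)

    @staticmethod
    def _ring_image(d_px: float, pixel_nm: float = 40.0) -> CellImage:
        size = int(d_px) + 30
        yy, xx = np.mgrid[0:size, 0:size]
        dist = np.hypot(yy - size / 2 + 0.3, xx - size / 2 - 0.2)
        img = 160 * np.exp(-((dist - d_px / 2) ** 2) / 2.0)
        return CellImage(channels={"LAMP1": img}, pixel_size_nm=pixel_nm)

    @pytest.mark.parametrize("d_px", range(4, 41, 4))
    def test_noiseless_ring_within_one_pixel(self, d_px):
        image = self._ring_image(d_px)
        mask = segment_channel(image, "LAMP1", min_object_px=4)
        assert mask.n_objects == 1
        nm, resolved = lysosome_diameter(image, mask, 1)
        assert resolved
        assert abs(nm / 40.0 - d_px) <= 1.0

    def test_tiny_object_errors(self):
        image = self._ring_image(10)
        labels = np.zeros(image.shape, dtype=np.int32)
        labels[2, 2] = 1
        with pytest.raises(ValueError):
            lysosome_diameter(image, LabelMask(labels=labels, n_objects=1), 1)


class TestNetworkPorosity:
    def test_fully_covered_tile_zero_porosity(self):
        mask = np.ones((60, 60), bool)
        tiles = network_porosity(mask, region=mask, tile_px=50)
        assert len(tiles) == 1
        assert tiles[0] == 0.0

    def test_checkerboard_half_porosity(self):
        yy, xx = np.mgrid[0:50, 0:50]
        mask = (yy + xx) % 2 == 0
        region = np.ones((50, 50), bool)
        tiles = network_porosity(mask, region=region, tile_px=50)
        assert tiles[0] == pytest.approx(50.0)

    def test_region_smaller_than_tile_errors(self):
        with pytest.raises(ValueError, match="smaller than one"):
            network_porosity(np.ones((20, 20), bool), region=np.ones((20, 20), bool), tile_px=50)

    def test_partial_tiles_dropped(self):
        region = np.zeros((120, 80), bool)
        region[:100, :60] = True  # one full 50x50 tile column, one partial
        mask = np.zeros_like(region)
        tiles = network_porosity(mask, region=region, tile_px=50)
        assert len(tiles) == 2  # 2 rows x 1 col fit fully inside

    def test_porosity_non_increasing_as_objects_added(self):
        rng = np.random.default_rng(4)
        region = np.zeros((120, 120), bool)
        region[10:110, 10:110] = True
        for _ in range(20):
            mask = np.zeros_like(region)
            prev = None
            for _ in range(15):  # add discs one at a time inside the region
                cy, cx = rng.integers(20, 100, size=2)
                yy, xx = np.mgrid[0:120, 0:120]
                mask |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= 49) & region
                mean_por = float(np.mean(network_porosity(mask, region=region, tile_px=50)))
                if prev is not None:
                    assert mean_por <= prev + 1e-9
                prev = mean_por


def _flood_fill_count(binary: np.ndarray) -> int:
    """4-connected component count by explicit flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    for sy in range(binary.shape[0]):
        for sx in range(binary.shape[1]):
            if binary[sy, sx] and not seen[sy, sx]:
                count += 1
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < binary.shape[0] and 0 <= nx < binary.shape[1]
                                and binary[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def golgi_bruteforce(golgi: np.ndarray, nucleus: np.ndarray, pixel_nm: float):
    """Explicit double-loop oracle for the farthest-point nucleus distance and
    a flood-fill fragment count."""
    ncoords = np.argwhere(nucleus)
    centroid = ncoords.mean(axis=0)
    best, best_d2 = None, -1.0
    for y, x in np.argwhere(golgi):  # row-major, strict > : first farthest pixel
        d2 = (y - centroid[0]) ** 2 + (x - centroid[1]) ** 2
        if d2 > best_d2:
            best, best_d2 = (y, x), d2
    dmin = min(np.hypot(best[0] - y, best[1] - x) for y, x in ncoords)
    return dmin * pixel_nm / 1000.0, _flood_fill_count(golgi)


class TestGolgiMetrics:
    def test_geometry_example(self):
        """Disc nucleus of radius 10 px; single Golgi pixel 30 px from the
        center; at 100 nm/px the edge distance is (30-10) px = 2 um."""
        size = 81
        yy, xx = np.mgrid[0:size, 0:size]
        nucleus = (yy - 40) ** 2 + (xx - 40) ** 2 <= 100
        golgi = np.zeros((size, size), bool)
        golgi[40, 70] = True
        g = golgi_metrics(golgi, nucleus, pixel_size_nm=100.0)
        assert g.nucleus_distance_um == pytest.approx(2.0, abs=0.01)
        assert g.fragment_count == 1

    def test_touching_golgi_zero_distance(self):
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        golgi = np.zeros((20, 20), bool)
        golgi[10, 15] = True  # adjacent to the nucleus edge
        g = golgi_metrics(golgi, nucleus, pixel_size_nm=100.0)
        assert g.nucleus_distance_um <= 0.1

    def test_three_separated_blobs(self):
        nucleus = np.zeros((64, 64), bool)
        nucleus[28:36, 28:36] = True
        golgi = np.zeros((64, 64), bool)
        for cy, cx in ((5, 5), (5, 55), (55, 30)):
            golgi[cy:cy + 3, cx:cx + 3] = True
        assert golgi_metrics(golgi, nucleus, pixel_size_nm=100.0).fragment_count == 3

    def test_empty_nucleus_errors(self):
        with pytest.raises(ValueError):
            golgi_metrics(np.ones((8, 8), bool), np.zeros((8, 8), bool), 100.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(16, 64))
        nucleus = np.zeros((size, size), bool)
        cy, cx = rng.integers(4, size - 4, size=2)
        yy, xx = np.mgrid[0:size, 0:size]
        nucleus |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.integers(4, 40)
        golgi = rng.random((size, size)) < 0.05
        if not golgi.any():
            golgi[0, 0] = True
        g = golgi_metrics(golgi, nucleus, pixel_size_nm=150.0)
        dist_oracle, count_oracle = golgi_bruteforce(golgi, nucleus, 150.0)
        assert g.nucleus_distance_um == pytest.approx(dist_oracle, abs=1e-6)
        assert g.fragment_count == count_oracle


class TestP62Density:
    def test_no_aggregates(self):
        cell = np.ones((50, 50), bool)
        assert p62_aggregate_density(np.zeros((50, 50)), cell, 200.0) == 0.0

    def test_planted_puncta_density(self):
        """5 puncta in a 100 um^2 cell -> 0.05 per um^2 (pixel 200 nm: a
        100 um^2 cell is 2500 px)."""
        cell = np.zeros((60, 60), bool)
        cell[5:55, 5:55] = True  # 2500 px -> 100 um^2
        p62 = np.zeros((60, 60))
        for cy, cx in ((10, 10), (10, 40), (30, 25), (45, 12), (45, 45)):
            p62[cy:cy + 2, cx:cx + 2] = 200.0  # 4 px = 0.16 um^2, inside band
        assert p62_aggregate_density(p62, cell, 200.0) == pytest.approx(0.05)

    def test_size_band_excludes_large_blobs(self):
        cell = np.zeros((60, 60), bool)
        cell[5:55, 5:55] = True
        p62 = np.zeros((60, 60))
        p62[10:40, 10:40] = 200.0  # 36 um^2 blob: excluded
        assert p62_aggregate_density(p62, cell, 200.0) == 0.0

    def test_empty_cell_errors(self):
        with pytest.raises(ValueError):
            p62_aggregate_density(np.zeros((8, 8)), np.zeros((8, 8), bool), 100.0)


class TestLysosensor:
    def test_control_self_normalizes_to_one(self):
        data = {"CT": [[10.0, 12.0], [8.0, 10.0], [11.0, 9.0]]}
        rel = lysosensor_relative_intensity(data)
        grand = np.concatenate([np.asarray(r) for r in rel["CT"]]).mean()
        assert grand == pytest.approx(1.0)

    def test_doubled_group_scores_two(self):
        data = {"CT": [[10.0, 10.0]], "PD": [[20.0, 20.0]]}
        rel = lysosensor_relative_intensity(data)
        assert np.mean(rel["PD"][0]) == pytest.approx(2.0)

    def test_zero_control_errors(self):
        with pytest.raises(ValueError):
            lysosensor_relative_intensity({"CT": [[0.0, 0.0]]})

    def test_missing_control_errors(self):
        with pytest.raises(ValueError):
            lysosensor_relative_intensity({"PD": [[1.0]]}, control_group="CT")


class TestStandardCurve:
    def test_exact_standard_recovered(self):
        standards = [(10.0, 6.25), (20.0, 12.5), (32.0, 20.0), (80.0, 50.0)]
        out = standard_curve_quantify([20.0], standards)
        assert out[0][0] == pytest.approx(12.5)
        assert out[0][1] is True

    def test_linear_interpolation_example(self):
        out = standard_curve_quantify([1.5], [(1.0, 10.0), (2.0, 20.0)])
        assert out[0][0] == pytest.approx(15.0)

    def test_out_of_range_flagged(self):
        out = standard_curve_quantify([5.0], [(1.0, 10.0), (2.0, 20.0)])
        assert out[0][1] is False

    def test_degenerate_standards_error(self):
        with pytest.raises(ValueError):
            standard_curve_quantify([1.0], [(2.0, 10.0), (2.0, 20.0)])

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(5)
        slopes = []
        true_slope = 0.625  # ng per intensity unit
        for _ in range(100):
            masses = np.array([6.25, 12.5, 20.0, 50.0])
            intensities = masses / true_slope + rng.normal(0, 1.5, size=4)
            fit = standard_curve_quantify([0.0], list(zip(intensities, masses)))
            # recover slope from two probe points on the fitted line
            lo = standard_curve_quantify([10.0], list(zip(intensities, masses)))[0][0]
            hi = standard_curve_quantify([11.0], list(zip(intensities, masses)))[0][0]
            slopes.append(hi - lo)
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - true_slope) <= 2 * sem + 1e-3
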