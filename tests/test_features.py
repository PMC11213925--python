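import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from omtscore import features as ft
from omtscore.io import NucleusClass, NucleusRecord
from oracles import brute_neighbor_counts, brute_shape_descriptor, brute_tile_vector


def _ellipse(cx, cy, a_px, b_px, theta=0.0, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ex, ey = a_px * np.cos(t), b_px * np.sin(t)
    xs = cx + ex * np.cos(theta) - ey * np.sin(theta)
    ys = cy + ex * np.sin(theta) + ey * np.cos(theta)
    return tuple(zip(xs, ys))


def _nucleus(i, x, y, cls=NucleusClass.EPITHELIAL, r=6.0):
    return NucleusRecord(i, (x, y), _ellipse(x, y, r, r, n=16), cls)


class TestShapeFeatures:
    def test_circle_symmetry(self):
        # 64-gon approximating a circle of radius 5 um = 10 px at 0.50 mpp
        d = ft.shape_features(_ellipse(50, 50, 10, 10))
        assert d.eccentricity < 0.05
        assert d.solidity == pytest.approx(1.0, abs=1e-9)
        assert d.equivalent_diameter == pytest.approx(10.0, rel=1e-3)
        assert d.extent == pytest.approx(np.pi / 4, rel=1e-2)

    def test_axis_aligned_square(self):
        # 10x10 um square = 20x20 px
        sq = ((0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0))
        d = ft.shape_features(sq)
        assert d.extent == 1.0
        assert d.bbox_aspect_ratio == 1.0
        assert d.contour_area == pytest.approx(100.0)
        assert d.perimeter == pytest.approx(40.0)

    def test_two_to_one_ellipse_eccentricity(self):
        d = ft.shape_features(_ellipse(0, 0, 20, 10, n=256))
        assert d.eccentricity == pytest.approx(np.sqrt(1 - 1 / 4), abs=2e-3)
        assert d.major_axis == pytest.approx(2 * 20 * 0.5, rel=5e-3)
        assert d.minor_axis == pytest.approx(2 * 10 * 0.5, rel=5e-3)

    def test_orientation_recovers_rotation(self):
        for theta in (0.3, -0.7, 1.2):
            d = ft.shape_features(_ellipse(10, 10, 20, 8, theta=theta, n=128))
            assert d.orientation == pytest.approx(theta, abs=1e-2)

    def test_degenerate_polygon_errors(self):
        with pytest.raises(ValueError, match="zero area"):
            ft.shape_features(((0, 0), (1, 1), (2, 2)))

    def test_winding_order_irrelevant(self):
        poly = _ellipse(5, 5, 8, 4, theta=0.5, n=32)
        fwd = ft.shape_features(poly).as_array()
        rev = ft.shape_features(poly[::-1]).as_array()
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)

    def test_area_matches_monte_carlo(self, rng):
        pts = rng.uniform(0, 40, size=(12, 2))
        hull = Polygon(pts).convex_hull
        contour = tuple(hull.exterior.coords)[:-1]
        d = ft.shape_features(contour)
        samples = rng.uniform(0, 40, size=(200_000, 2))
        inside = np.fromiter(
            (hull.contains(Point(p)) for p in samples), dtype=bool, count=len(samples)
        )
        mc_area_um2 = inside.mean() * 40 * 40 * 0.25
        assert d.contour_area == pytest.approx(mc_area_um2, rel=0.01)

    def test_matches_independent_moment_route(self, rng):
        for _ in range(25):
            cx, cy = rng.uniform(20, 80, 2)
            a = rng.uniform(8, 20)
            b = a / rng.uniform(1.3, 2.5)
            poly = _ellipse(cx, cy, a, b, theta=rng.uniform(-1.4, 1.4), n=32)
            got = ft.shape_features(poly).as_array()
            ref = brute_shape_descriptor(poly)
            want = np.array([ref[k] for k in ft.SHAPE_FEATURE_NAMES])
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


class TestNeighborCounts:
    def test_pair_at_150px(self):
        nuclei = [_nucleus(0, 100, 100), _nucleus(1, 250, 100)]
        counts, cls = ft.neighbor_counts_for_nuclei(nuclei)
        # epi->epi: 0 within 100 px, 1 within 200/300/400 px, for each nucleus
        np.testing.assert_array_equal(counts[:, 0, :], [[0, 1, 1, 1]] * 2)
        assert (counts[:, 1, :] == 0).all()

    def test_single_nucleus_no_self_neighbour(self):
        counts, _ = ft.neighbor_counts_for_nuclei([_nucleus(0, 50, 50)])
        assert (counts == 0).all()

    def test_boundary_distance_inclusive(self):
        nuclei = [_nucleus(0, 0, 0), _nucleus(1, 100, 0)]
        counts, _ = ft.neighbor_counts_for_nuclei(nuclei)
        assert counts[0, 0, 0] == 1  # exactly at radius 100

    def test_monotone_in_radius_and_matches_oracle(self, rng):
        cents = rng.uniform(0, 512, size=(100, 2))
        cls = rng.integers(0, 2, size=100)
        counts = ft.neighbor_counts(cents, cls)
        assert (np.diff(counts, axis=2) >= 0).all()
        np.testing.assert_array_equal(counts, brute_neighbor_counts(cents, cls))


class TestTileVectors:
    def test_empty_tile_zero_vector(self):
        vec = ft.tile_feature_vector([])
        assert vec.shape == (168,)
        assert (vec == 0).all()

    def test_single_epithelial_nucleus(self):
        vec = ft.tile_feature_vector([_nucleus(0, 50, 50)])
        morph = vec[: ft.N_MORPHOLOGICAL].reshape(2, 13, 4)
        # mean = min = max, std = 0 for the epithelial block
        np.testing.assert_allclose(morph[0, :, 0], morph[0, :, 1])
        np.testing.assert_allclose(morph[0, :, 0], morph[0, :, 2])
        np.testing.assert_allclose(morph[0, :, 3], 0, atol=1e-12)
        assert (morph[1] == 0).all()  # no "other" nuclei

    def test_basal_merged_into_epithelial_class(self):
        v_basal = ft.tile_feature_vector([_nucleus(0, 50, 50, NucleusClass.BASAL_EPITHELIAL)])
        v_epi = ft.tile_feature_vector([_nucleus(0, 50, 50, NucleusClass.EPITHELIAL)])
        np.testing.assert_array_equal(v_basal, v_epi)

    def test_epi_other_pair_block(self):
        nuclei = [_nucleus(0, 100, 100), _nucleus(1, 150, 100, NucleusClass.OTHER)]
        vec = ft.tile_feature_vector(nuclei)
        spat = vec[ft.N_MORPHOLOGICAL :].reshape(4, 4, 4)  # (pair, radius, stat)
        # epi->other: one "other" neighbour at 50 px for the single epithelial ref
        np.testing.assert_array_equal(spat[1, :, 0], [1, 1, 1, 1])  # mean per radius
        np.testing.assert_array_equal(spat[1, :, 3], [0, 0, 0, 0])  # std

    def test_permutation_and_translation_invariance(self, rng):
        # elongated nuclei: orientation is well defined (circles have none)
        nuclei = [
            NucleusRecord(
                i, (x, y),
                _ellipse(x, y, 8.0, 4.0, theta=rng.uniform(0, np.pi), n=24),
                NucleusClass(rng.choice(["epithelial", "other"])),
            )
            for i, (x, y) in enumerate(rng.uniform(30, 480, size=(30, 2)))
        ]
        base = ft.tile_feature_vector(nuclei)
        perm = [nuclei[i] for i in rng.permutation(30)]
        # identical descriptor sets; only float summation order may differ
        np.testing.assert_allclose(base, ft.tile_feature_vector(perm),
                                   rtol=1e-9, atol=1e-12)
        shifted = [
            NucleusRecord(n.nucleus_id,
                          (n.centroid[0] + 37, n.centroid[1] + 91),
                          tuple((x + 37, y + 91) for x, y in n.contour),
                          n.model_class)
            for n in nuclei
        ]
        np.testing.assert_allclose(base, ft.tile_feature_vector(shifted), atol=1e-6)

    def test_min_mean_max_ordering(self, rng):
        nuclei = [
            _nucleus(i, x, y, r=rng.uniform(4, 9))
            for i, (x, y) in enumerate(rng.uniform(30, 480, size=(40, 2)))
        ]
        vec = ft.tile_feature_vector(nuclei).reshape(-1, 4)
        assert (vec[:, 1] <= vec[:, 0] + 1e-12).all()  # min <= mean
        assert (vec[:, 0] <= vec[:, 2] + 1e-12).all()  # mean <= max

    def test_matches_brute_force_vector(self, rng):
        for _ in range(10):
            n = int(rng.integers(0, 35))
            nuclei = []
            for i in range(n):
                x, y = rng.uniform(30, 480, 2)
                a = rng.uniform(5, 12)
                cls = NucleusClass(rng.choice(["epithelial", "other", "basal_epithelial"]))
                nuclei.append(NucleusRecord(
                    i, (x, y),
                    _ellipse(x, y, a, a / rng.uniform(1.3, 2.2),
                             theta=rng.uniform(0, np.pi), n=24),
                    cls,
                ))
            got = ft.tile_feature_vector(nuclei)
            want = brute_tile_vector(nuclei)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)
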