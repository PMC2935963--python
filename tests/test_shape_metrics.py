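import numpy as np
import pytest

from pqctshape import (
    AxisMissError,
    CorticalMask,
    ImageGeometry,
    axis_angle,
    centroid,
    directional_thickness,
    max_diameter,
    min_diameter,
    perimeter,
    summarize,
    thickness_profile,
)
from pqctshape.shape_metrics import point_to_segments_distance, polygon_area


def circle_points(R, n=720, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + R * np.cos(t), center[1] + R * np.sin(t)])


class TestCentroid:
    def _mask(self, pixels, v=0.5):
        g = ImageGeometry(width=pixels.shape[1], height=pixels.shape[0], voxel_size=v)
        return CorticalMask(g, pixels, seed=tuple(np.argwhere(pixels)[0]))

    def test_single_pixel_center_formula(self):
        pixels = np.zeros((20, 20), dtype=bool)
        pixels[10, 10] = True
        assert centroid(self._mask(pixels)) == (5.25, 5.25)

    def test_symmetric_annulus_is_centered(self, annulus_analysis):
        analysis, _ = annulus_analysis
        cx, cy = centroid(analysis.mask)
        mid = 283 * 0.5 / 2
        assert cx == pytest.approx(mid, abs=0.26) and cy == pytest.approx(mid, abs=0.26)

    def test_matches_brute_force_mean(self, rng):
        pixels = rng.random((15, 15)) < 0.3
        pixels[7, 7] = True
        cx, cy = centroid(self._mask(pixels))
        rr, cc = np.nonzero(pixels)
        assert cx == pytest.approx(((cc + 0.5) * 0.5).mean())
        assert cy == pytest.approx(((rr + 0.5) * 0.5).mean())

    def test_density_weighted_variant(self):
        pixels = np.zeros((10, 10), dtype=bool)
        pixels[2, 2] = pixels[2, 6] = True
        weights = np.zeros((10, 10))
        weights[2, 2], weights[2, 6] = 3.0, 1.0
        cx, _ = centroid(self._mask(pixels), weights=weights)
        assert cx == pytest.approx((3 * 1.25 + 1 * 3.25) / 4)


class TestDiameters:
    def test_square_diagonal(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        d, ends = max_diameter(pts)
        assert d == pytest.approx(np.sqrt(200), abs=1e-9)

    def test_circle_max_and_min(self):
        pts = circle_points(13.0)
        d, ends = max_diameter(pts)
        assert d == pytest.approx(26.0, abs=0.01)
        assert min_diameter(pts, ends) == pytest.approx(26.0, abs=0.01)

    def test_ellipse_minor_axis(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        pts = np.column_stack([14 * np.cos(t), 9 * np.sin(t)])
        d, ends = max_diameter(pts)
        assert d == pytest.approx(28.0, abs=0.01)
        assert min_diameter(pts, ends) == pytest.approx(18.0, abs=0.01)

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(200, 2)) * rng.uniform(1, 10)
            d, _ = max_diameter(pts)
            brute = 0.0
            diff = pts[:, None, :] - pts[None, :, :]
            brute = np.sqrt((diff**2).sum(-1)).max()
            assert d == brute  # exact equality, both are max over point pairs

    def test_rectangle_projection_width(self, rng):
        pts = np.array([[0, 0], [10, 0], [10, 4], [0, 4]], dtype=float)
        d, ends = max_diameter(pts)
        assert d == pytest.approx(np.hypot(10, 4), abs=1e-12)
        axis = ends[1] - ends[0]
        perp = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
        brute = (pts @ perp).max() - (pts @ perp).min()
        assert min_diameter(pts, ends) == pytest.approx(brute, abs=1e-12)

    def test_tie_break_is_deterministic(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        _, ends = max_diameter(pts)
        # first endpoint has the smallest (y, then x)
        assert (ends[0][1], ends[0][0]) <= (ends[1][1], ends[1][0])


@pytest.mark.parametrize(
    "ends,expected",
    [
        ([[0, 0], [0, 10]], 0.0),  # vertical (same x)
        ([[0, 0], [10, 0]], 90.0),  # horizontal
        ([[0, 0], [10, 10]], 45.0),
        ([[0, 0], [-10, 10]], 135.0),
    ],
)
def test_axis_angle_from_vertical(ends, expected):
    assert axis_angle(np.array(ends, dtype=float)) == pytest.approx(expected)


def test_axis_angle_coincident_endpoints():
    with pytest.raises(Exception, match="coincident"):
        axis_angle(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestPerimeter:
    def test_unit_square(self):
        assert perimeter(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])) == 4.0

    def test_circle_digital_bias_bound(self, annulus_analysis):
        """Traced circumference of a circle >= truth, within +10%."""
        analysis, truth = annulus_analysis
        assert truth.peri_circ <= analysis.result.peri_circ <= 1.10 * truth.peri_circ
        assert truth.endo_circ <= analysis.result.endo_circ <= 1.10 * truth.endo_circ

    def test_perimeter_at_least_twice_max_diameter(self, annulus_analysis):
        analysis, _ = annulus_analysis
        assert analysis.result.peri_circ >= 2 * analysis.result.max_diameter


class TestThickness:
    def test_concentric_circles(self):
        peri = circle_points(13.0, 720)
        endo = circle_points(9.0, 600)
        prof = thickness_profile(peri, endo)
        assert np.allclose(prof, 4.0, atol=0.01)

    def test_concentric_squares_min_face_distance(self):
        def square(half, n_per_side=21):
            s = np.linspace(-half, half, n_per_side)
            top = np.column_stack([s, np.full_like(s, -half)])
            right = np.column_stack([np.full_like(s, half), s])
            bottom = np.column_stack([s[::-1], np.full_like(s, half)])
            left = np.column_stack([np.full_like(s, -half), s[::-1]])
            return np.vstack([top, right, bottom, left])

        prof = thickness_profile(square(10.0), square(5.0))
        assert prof.min() == pytest.approx(5.0)

    def test_matches_brute_force_point_segment(self, rng):
        for _ in range(10):
            peri = circle_points(13.0, 90) + rng.normal(0, 0.3, (90, 2))
            endo = circle_points(8.0, 70) + rng.normal(0, 0.2, (70, 2))
            prof = thickness_profile(peri, endo)
            # O(n*m) brute force over every (vertex, segment) pair
            for i in rng.integers(0, 90, size=8):
                p = peri[i]
                best = np.inf
                for j in range(len(endo)):
                    a, b = endo[j], endo[(j + 1) % len(endo)]
                    ab = b - a
                    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                    best = min(best, np.linalg.norm(p - (a + t * ab)))
            assert prof[i] == pytest.approx(best, abs=1e-12)


class TestDirectionalThickness:
    def test_concentric_isotropy(self):
        peri, endo = circle_points(13.0), circle_points(9.0)
        d = directional_thickness(peri, endo, (0.0, 0.0), np.array([0.0, 1.0]))
        for k in ("anterior", "posterior", "left", "right"):
            assert d[k] == pytest.approx(4.0, abs=0.01)

    def test_eccentric_hole_shifted_toward_top(self):
        """Hole shifted 2 mm toward the image top: anterior 2, posterior 6."""
        peri = circle_points(13.0)
        endo = circle_points(9.0, center=(0.0, -2.0))
        d = directional_thickness(peri, endo, (0.0, 0.0), np.array([0.0, 1.0]))
        assert d["anterior"] == pytest.approx(2.0, abs=0.01)
        assert d["posterior"] == pytest.approx(6.0, abs=0.01)

    def test_180_rotation_swaps_anterior_posterior(self):
        peri = circle_points(13.0)
        endo = circle_points(9.0, center=(0.0, -2.0))
        d1 = directional_thickness(peri, endo, (0.0, 0.0), np.array([0.0, 1.0]))
        d2 = directional_thickness(-peri, -endo, (0.0, 0.0), np.array([0.0, 1.0]))
        assert d1["anterior"] == pytest.approx(d2["posterior"], abs=1e-9)
        assert d1["posterior"] == pytest.approx(d2["anterior"], abs=1e-9)

    def test_axis_missing_cortex_raises(self):
        peri = circle_points(13.0)
        endo = circle_points(9.0)
        with pytest.raises(AxisMissError, match="axis misses cortex"):
            directional_thickness(peri, endo, (20.0, 0.0), np.array([0.0, 1.0]))


class TestSummarize:
    def test_annulus_areas_and_ratios(self, annulus_analysis):
        analysis, truth = annulus_analysis
        r = analysis.result
        assert r.tot_csa == pytest.approx(np.pi * 13**2, rel=0.02)
        assert r.cort_csa == pytest.approx(np.pi * (13**2 - 9**2), rel=0.02)
        assert r.thickness_mean == pytest.approx(4.0, abs=0.5)
        assert r.peri_circ / r.endo_circ == pytest.approx(13 / 9, rel=0.05)

    def test_result_invariants_hold(self, annulus_analysis):
        r = annulus_analysis[0].result
        assert r.max_diameter >= r.min_diameter > 0
        assert r.peri_circ > r.endo_circ > 0
        assert r.thickness_min <= r.thickness_mean <= r.thickness_max
        assert r.tot_csa > r.cort_csa > 0
        assert r.tot_csa_polygon > r.cort_csa_polygon > 0

    def test_translation_invariance(self, rng):
        """All scalar metrics are exactly translation invariant."""
        pts = circle_points(10.0, 200) + rng.normal(0, 0.2, (200, 2))
        shift = np.array([17.0, -4.0])
        d1, e1 = max_diameter(pts)
        d2, e2 = max_diameter(pts + shift)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert perimeter(pts) == pytest.approx(perimeter(pts + shift), abs=1e-9)
        assert polygon_area(pts) == pytest.approx(polygon_area(pts + shift), abs=1e-9)


def recovery_error(voxel_sizes=(1.0, 0.5, 0.25)):
    """Mean relative pipeline-vs-truth error of the convergent quantities.

    Diameters, areas and mean thickness converge as v -> 0; the digital
    circumferences carry a resolution-independent chain-code bias and are
    therefore excluded here (their bound is asserted separately).
    """
    from pqctshape import ImageGeometry, PhantomSpec, analyze_image, rasterize

    errors = []
    for v in voxel_sizes:
        n = int(round(36 / v))
        geom = ImageGeometry(width=n, height=n, voxel_size=v)
        image, truth = rasterize(PhantomSpec(), geom)
        r = analyze_image(image).result
        rel = [
            abs(r.max_diameter - truth.max_diam) / truth.max_diam,
            abs(r.min_diameter - truth.min_diam) / truth.min_diam,
            abs(r.tot_csa - truth.tot_csa) / truth.tot_csa,
            abs(r.cort_csa - truth.cort_csa) / truth.cort_csa,
            abs(r.thickness_mean - truth.thickness["mean"]) / truth.thickness["mean"],
        ]
        errors.append(float(np.mean(rel)))
    return errors


def test_recovery_error_converges_with_resolution():
    """Annulus recovery error shrinks monotonically as v -> 0."""
    errors = recovery_error()
    assert errors[0] >= errors[1] >= errors[2]
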