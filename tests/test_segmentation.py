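from collections import deque

import numpy as np
import pytest
from scipy import ndimage as ndi

from pqctshape import (
    AnalysisConfig,
    CorticalMask,
    CortexErodedError,
    ImageGeometry,
    OpenRingError,
    PhantomSpec,
    ScanImage,
    SeedNotOnBoneError,
    TopologyWarning,
    binarize,
    extract_boundaries,
    flood_select,
    moore_trace,
    morph_clean,
    rasterize,
    segment_cortex,
)
from pqctshape.shape_metrics import polygon_area

from conftest import random_ring_mask


def bfs_flood(binary, seed):
    """Brute-force 8-connected breadth-first flood fill (oracle)."""
    out = np.zeros_like(binary, dtype=bool)
    q = deque([seed])
    out[seed] = True
    H, W = binary.shape
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    q.append((rr, cc))
    return out


class TestBinarize:
    def test_threshold_is_inclusive(self):
        grid = np.array([[100, 500], [450, 449]])
        assert binarize(grid, 450).tolist() == [[False, True], [True, False]]

    def test_all_zero_and_zero_threshold(self):
        zeros = np.zeros((4, 4))
        assert not binarize(zeros, 450).any()
        assert binarize(zeros, 0).all()


class TestFloodSelect:
    def test_keeps_only_seed_blob(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[1:4, 1:4] = True  # blob A
        grid[6:9, 6:9] = True  # blob B
        out = flood_select(grid, (2, 2))
        assert out[1:4, 1:4].all() and not out[6:9, 6:9].any()

    def test_single_blob_identity(self):
        grid = np.zeros((8, 8), dtype=bool)
        grid[2:6, 2:6] = True
        assert (flood_select(grid, (3, 3)) == grid).all()

    def test_diagonal_chain_is_8_connected(self):
        grid = np.eye(9, dtype=bool)
        out = flood_select(grid, (0, 0))
        assert (out == grid).all()

    def test_seed_on_background_raises(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        with pytest.raises(SeedNotOnBoneError, match="seed not on bone"):
            flood_select(grid, (0, 0))

    def test_matches_bfs_oracle_on_random_masks(self, rng):
        for _ in range(30):
            grid = rng.random((20, 20)) < 0.45
            seeds = np.argwhere(grid)
            if len(seeds) == 0:
                continue
            seed = tuple(seeds[rng.integers(len(seeds))])
            assert (flood_select(grid, seed) == bfs_flood(grid, seed)).all()


def opening_oracle(mask, iterations):
    """Direct set-morphology opening with the 3x3 cross (oracle)."""
    cross = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
    cur = {tuple(p) for p in np.argwhere(mask)}
    H, W = mask.shape

    def erode(s):
        return {p for p in s if all((p[0] + d[0], p[1] + d[1]) in s for d in cross)}

    def dilate(s):
        return {
            (p[0] + d[0], p[1] + d[1])
            for p in s
            for d in cross
            if 0 <= p[0] + d[0] < H and 0 <= p[1] + d[1] < W
        }

    for _ in range(iterations):
        cur = erode(cur)
    for _ in range(iterations):
        cur = dilate(cur)
    out = np.zeros_like(mask)
    for r, c in cur:
        out[r, c] = True
    return out


class TestMorphClean:
    def test_identity_at_zero_iterations(self, rng):
        grid = rng.random((12, 12)) < 0.5
        assert (morph_clean(grid, 0) == grid).all()

    def test_solid_square_matches_set_morphology(self):
        grid = np.zeros((14, 14), dtype=bool)
        grid[2:12, 2:12] = True
        assert (morph_clean(grid, 1, seed=(5, 5)) == opening_oracle(grid, 1)).all()

    def test_isolated_pixel_removed(self):
        grid = np.zeros((14, 14), dtype=bool)
        grid[2:10, 2:10] = True
        grid[12, 12] = True
        out = morph_clean(grid, 1, seed=(5, 5))
        assert not out[12, 12] and out[5, 5]

    def test_annihilated_component_raises(self):
        grid = np.zeros((8, 8), dtype=bool)
        grid[3, 3:6] = True  # 1-px-thick line: erosion kills it
        with pytest.raises(CortexErodedError, match="cortex eroded away"):
            morph_clean(grid, 1, seed=(3, 4))


class TestMooreTrace:
    def test_boundary_membership_oracle(self, rng):
        """Trace covers every 4-boundary pixel and nothing interior.

        Moore tracing must visit every foreground pixel with a 4-adjacent
        background (the crack boundary) and may additionally visit pixels
        touching background only diagonally — never a fully interior pixel.
        """
        cross = ndi.generate_binary_structure(2, 1)
        for _ in range(20):
            mask = random_ring_mask(rng, size=26)
            mask = ndi.binary_fill_holes(mask)  # simply-connected blob
            traced = {tuple(p) for p in moore_trace(mask)}
            b4 = {
                tuple(p)
                for p in np.argwhere(
                    mask & ~ndi.binary_erosion(mask, cross, border_value=0)
                )
            }
            b8 = {
                tuple(p)
                for p in np.argwhere(
                    mask & ~ndi.binary_erosion(mask, np.ones((3, 3)), border_value=0)
                )
            }
            assert b4 <= traced <= b8

    def test_chain_perimeter_of_3x3_square(self):
        """The 8-step chain around a 3x3 block has length 8 x v = 4.0 mm."""
        from pqctshape.shape_metrics import perimeter

        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        pts = moore_trace(mask) * 0.5  # scale chain steps by v
        assert len(pts) == 8
        assert perimeter(pts) == pytest.approx(4.0)


class TestExtractBoundaries:
    def _mask(self, pixels, v=0.5):
        g = ImageGeometry(width=pixels.shape[1], height=pixels.shape[0], voxel_size=v)
        return CorticalMask(g, pixels, seed=tuple(np.argwhere(pixels)[0]))

    def test_annulus_topology(self, annulus_analysis):
        analysis, _ = annulus_analysis
        peri, endo = analysis.periosteal, analysis.endosteal
        assert peri.role == "periosteal" and endo.role == "endosteal"
        assert polygon_area(peri) > polygon_area(endo)

    def test_solid_disk_raises_open_ring(self):
        ii, jj = np.mgrid[0:40, 0:40]
        disk = (ii - 20.0) ** 2 + (jj - 20.0) ** 2 <= 14**2
        with pytest.raises(OpenRingError, match="open cortical ring"):
            extract_boundaries(self._mask(disk))

    def test_border_touching_component_rejected(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[0:5, 2:8] = True
        with pytest.raises(Exception, match="border"):
            extract_boundaries(self._mask(grid))

    def test_multiple_large_holes_warn(self):
        grid = np.zeros((30, 30), dtype=bool)
        grid[4:26, 4:26] = True
        grid[8:13, 8:13] = False
        grid[16:21, 16:21] = False
        with pytest.warns(TopologyWarning, match="holes"):
            peri, endo = extract_boundaries(self._mask(grid))

    def test_shoelace_area_vs_pixel_count(self, rng):
        """|polygon area - pixel area| <= perimeter x v for random rings."""
        from pqctshape.shape_metrics import perimeter

        for _ in range(20):
            pixels = random_ring_mask(rng, size=30)
            mask = self._mask(pixels)
            peri, endo = extract_boundaries(mask)
            filled = ndi.binary_fill_holes(pixels)
            pixel_area = filled.sum() * 0.25
            assert abs(polygon_area(peri) - pixel_area) <= perimeter(peri) * 0.5


class TestSegmentCortex:
    def test_recovers_exact_phantom_ring(self, annulus):
        image, _ = annulus
        mask, peri, endo = segment_cortex(image, AnalysisConfig(open_iterations=0))
        expected = image.values >= 450
        assert (mask.pixels == expected).all()

    def test_noise_below_threshold_is_invisible(self):
        from pqctshape import generate

        quiet, _ = rasterize(PhantomSpec())
        noisy, _ = generate(PhantomSpec(noise_sd=(800 - 450) / 6, seed=7))
        cfg = AnalysisConfig()
        m1, *_ = segment_cortex(quiet, cfg)
        m2, *_ = segment_cortex(noisy, cfg)
        assert (m1.pixels == m2.pixels).all()

    def test_idempotence_on_reembedded_mask(self, annulus, config):
        image, _ = annulus
        mask, _, _ = segment_cortex(image, config)
        re = ScanImage(image.geometry, np.where(mask.pixels, 65535, 0))
        mask2, _, _ = segment_cortex(re, config)
        assert (mask.pixels == mask2.pixels).all()

    def test_rotation_equivariance(self, annulus, config):
        """Rotating the input by 90/180/270 degrees permutes the mask exactly."""
        image, _ = annulus
        mask, _, _ = segment_cortex(image, config)
        for k in (1, 2, 3):
            rot = ScanImage(image.geometry, np.rot90(image.values, k).copy())
            mrot, _, _ = segment_cortex(rot, config)
            assert (mrot.pixels == np.rot90(mask.pixels, k)).all()

    def test_stage_name_attached_on_failure(self):
        ii, jj = np.mgrid[0:64, 0:64]
        disk = ((ii - 32.0) ** 2 + (jj - 32.0) ** 2 <= 20**2).astype(np.uint16) * 800
        image = ScanImage(ImageGeometry(width=64, height=64, voxel_size=0.5), disk)
        with pytest.raises(OpenRingError, match=r"\[extract_boundaries\]"):
            segment_cortex(image, AnalysisConfig())
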