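"""Cortical-ring segmentation: threshold, seeded flood, cleanup, tracing.

The pipeline mirrors the classic interactive workflow for mid-shaft pQCT
slices: binarize at an attenuation threshold, keep the 8-connected
above-threshold component under the operator's crosshair (the seed), open
morphologically to strip noise, then trace the periosteal (outer) and
endosteal (inner) boundaries as ordered pixel-center polygons in mm.

Digital-topology pairing: foreground is 8-connected, background holes are
4-connected, the standard combination that prevents both the ring and its
cavity from leaking through diagonal gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    CortexErodedError,
    OpenRingError,
    SeedNotOnBoneError,
    SegmentationError,
    TopologyWarning,
)
from .io import AnalysisConfig, ImageGeometry, ScanImage, pixel_centers_to_mm

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndi.generate_binary_structure(2, 1)  # 3x3 cross

# Moore neighborhood scanned clockwise on screen (row increases downward):
# N, NE, E, SE, S, SW, W, NW as (dr, dc).
_MOORE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass
class Contour:
    """Ordered closed boundary polyline in mm coordinates.

    ``points`` is an (n, 2) array of (x, y) pixel centers; the polygon is
    implicitly closed (last point connects back to the first). Orientation
    is counter-clockwise as seen on screen (x right, y down), i.e. the
    signed shoelace area evaluated in this left-handed frame is negative.
    """

    role: str  # "periosteal" | "endosteal"
    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.role not in ("periosteal", "endosteal"):
            raise ValueError(f"unknown contour role {self.role!r}")
        if len(self.points) < 8:
            raise SegmentationError(
                f"{self.role} contour has only {len(self.points)} points "
                "(degenerate boundary)"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def signed_area(self) -> float:
        """Shoelace signed area in the x-right/y-down frame."""
        x, y = self.x, self.y
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())


@dataclass
class CorticalMask:
    """Binary mask of segmented cortical bone (topologically a ring)."""

    geometry: ImageGeometry
    pixels: np.ndarray
    seed: tuple[int, int]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != (self.geometry.height, self.geometry.width):
            raise SegmentationError("mask shape does not match geometry")

    @property
    def voxel_size(self) -> float:
        return self.geometry.voxel_size

    def pixel_count(self) -> int:
        return int(self.pixels.sum())


def binarize(image: ScanImage | np.ndarray, threshold: float) -> np.ndarray:
    """Foreground iff attenuation >= threshold."""
    values = image.values if isinstance(image, ScanImage) else np.asarray(image)
    return values >= threshold


def flood_select(binary: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Keep only the 8-connected foreground component containing the seed."""
    binary = np.asarray(binary, dtype=bool)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < binary.shape[0] and 0 <= c < binary.shape[1]):
        raise SegmentationError(f"seed ({r}, {c}) outside the image")
    if not binary[r, c]:
        raise SeedNotOnBoneError("seed not on bone")
    labels, _ = ndi.label(binary, structure=_STRUCT_8)
    return labels == labels[r, c]


def morph_clean(
    mask: np.ndarray, iterations: int, seed: tuple[int, int] | None = None
) -> np.ndarray:
    """Morphological opening (3x3 cross) followed by component re-selection.

    ``iterations`` erosions then the same number of dilations; 0 is the
    identity. After opening, the component containing the seed (or, if the
    seed was eroded away, the largest surviving component) is re-selected so
    stray fragments split off by erosion do not rejoin the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    opened = ndi.binary_opening(mask, structure=_STRUCT_4, iterations=iterations)
    if not opened.any():
        raise CortexErodedError("cortex eroded away (threshold too high or cortex too thin)")
    labels, n = ndi.label(opened, structure=_STRUCT_8)
    if seed is not None and opened[int(seed[0]), int(seed[1])]:
        keep = labels[int(seed[0]), int(seed[1])]
    else:
        keep = int(np.argmax(ndi.sum_labels(opened, labels, range(1, n + 1)))) + 1
    return labels == keep


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a binary component by Moore tracing.

    Returns an (n, 2) array of (row, col) boundary pixels in traversal
    order, starting at the raster-first foreground pixel. Termination uses
    Jacob's criterion (re-entering the start pixel from the same backtrack
    direction), which is robust for single-pixel spurs.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("cannot trace an empty mask")
    # pad so neighborhood lookups never leave the array
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    r0 = rows.min()
    c0 = cols[rows == r0].min()
    start = (int(r0), int(c0))
    if padded.sum() == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # west of raster-first pixel: background
    current = start
    first_state = (current, backtrack)
    state = None
    while True:
        i = _MOORE.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        for k in range(1, 9):
            j = (i + k) % 8
            cand = (current[0] + _MOORE[j][0], current[1] + _MOORE[j][1])
            if padded[cand]:
                backtrack = (
                    current[0] + _MOORE[(i + k - 1) % 8][0],
                    current[1] + _MOORE[(i + k - 1) % 8][1],
                )
                current = cand
                break
        else:  # isolated pixel (cannot happen after the sum()==1 guard)
            break
        state = (current, backtrack)
        if state == first_state:
            break
        boundary.append(current)
        if len(boundary) > 4 * padded.size:  # defensive: malformed input
            raise SegmentationError("boundary tracing failed to terminate")
    return np.array(boundary) - 1  # undo padding offset


def _screen_ccw(points: np.ndarray) -> np.ndarray:
    """Orient a closed polygon counter-clockwise in the x-right/y-down frame."""
    x, y = points[:, 0], points[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return points[::-1] if signed > 0 else points


def extract_boundaries(mask: CorticalMask) -> tuple[Contour, Contour]:
    """Trace the periosteal and endosteal contours of a cortical ring mask.

    The periosteal contour is the Moore-traced outer boundary of the
    foreground component; the endosteal contour is the traced boundary of
    the largest enclosed background hole (4-connected). Raises
    :class:`OpenRingError` when no hole exists, and warns when several
    comparably sized holes are present (the largest is used).
    """
    m = mask.pixels
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        raise SegmentationError("cortical component touches the image border")
    filled = ndi.binary_fill_holes(m)
    holes = filled & ~m
    labels, n_holes = ndi.label(holes, structure=_STRUCT_4)
    if n_holes == 0:
        raise OpenRingError("open cortical ring (cortex does not enclose a cavity)")
    areas = ndi.sum_labels(holes, labels, range(1, n_holes + 1))
    total = areas.sum()
    big = int(np.sum(areas > 0.05 * total))
    if big >= 2:
        warnings.warn(
            f"{big} enclosed holes each exceed 5% of the total hole area; "
            "using the largest as the medullary cavity",
            TopologyWarning,
            stacklevel=2,
        )
    largest = labels == (int(np.argmax(areas)) + 1)

    v = mask.voxel_size
    peri_px = moore_trace(filled)
    endo_px = moore_trace(largest)
    peri = Contour("periosteal", _screen_ccw(pixel_centers_to_mm(peri_px, v)))
    endo = Contour("endosteal", _screen_ccw(pixel_centers_to_mm(endo_px, v)))
    return peri, endo


def subpixel_boundaries(mask: CorticalMask, level: float = 0.5) -> tuple[Contour, Contour]:
    """Marching-squares subpixel contours, for sensitivity analysis.

    Uses isoline extraction at the given level on the filled mask and on the
    cavity; point coordinates are interpolated between pixel centers.
    """
    from skimage import measure

    m = mask.pixels
    filled = ndi.binary_fill_holes(m)
    holes = filled & ~m
    labels, n_holes = ndi.label(holes, structure=_STRUCT_4)
    if n_holes == 0:
        raise OpenRingError("open cortical ring (cortex does not enclose a cavity)")
    areas = ndi.sum_labels(holes, labels, range(1, n_holes + 1))
    largest = labels == (int(np.argmax(areas)) + 1)
    v = mask.voxel_size

    def _largest_contour(grid):
        cs = measure.find_contours(grid.astype(float), level)
        rc = max(cs, key=len)
        if np.allclose(rc[0], rc[-1]):
            rc = rc[:-1]
        return pixel_centers_to_mm(rc, v)

    peri = Contour("periosteal", _screen_ccw(_largest_contour(filled)))
    endo = Contour("endosteal", _screen_ccw(_largest_contour(largest)))
    return peri, endo


def auto_seed(image: ScanImage, threshold: float) -> tuple[int, int]:
    """Reproducible stand-in for the interactive crosshair.

    Returns the brightest pixel of the largest above-threshold 8-connected
    component (raster-first among ties).
    """
    binary = binarize(image, threshold)
    if not binary.any():
        raise SeedNotOnBoneError("no pixels above threshold; cannot auto-seed")
    labels, n = ndi.label(binary, structure=_STRUCT_8)
    sizes = ndi.sum_labels(binary, labels, range(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    vals = np.where(comp, image.values, 0)
    idx = int(np.argmax(vals))  # argmax is raster-first among ties
    return np.unravel_index(idx, vals.shape)


def segment_cortex(
    image: ScanImage,
    config: AnalysisConfig,
    seed: tuple[int, int] | None = None,
) -> tuple[CorticalMask, Contour, Contour]:
    """Full segmentation: binarize -> flood -> open -> trace boundaries.

    Deterministic for fixed inputs. ``seed`` overrides the config seed
    policy; with policy "auto" (and no explicit seed) the seed is chosen by
    :func:`auto_seed`. Sub-operation failures are re-raised with the stage
    name attached.
    """
    if seed is None:
        seed = auto_seed(image, config.threshold) if config.seed == "auto" else config.seed

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except SegmentationError as exc:
            if exc.stage is None:
                exc.stage = name
                exc.args = (f"[{name}] {exc.args[0]}",) + exc.args[1:]
            raise

    binary = _stage("binarize", binarize, image, config.threshold)
    flooded = _stage("flood_select", flood_select, binary, seed)
    cleaned = _stage("morph_clean", morph_clean, flooded, config.open_iterations, seed)
    mask = CorticalMask(image.geometry, cleaned, tuple(seed))
    if config.subpixel:
        peri, endo = _stage("extract_boundaries", subpixel_boundaries, mask)
    else:
        peri, endo = _stage("extract_boundaries", extract_boundaries, mask)
    return mask, peri, endo


__all__ = [
    "Contour",
    "CorticalMask",
    "binarize",
    "flood_select",
    "morph_clean",
    "moore_trace",
    "extract_boundaries",
    "subpixel_boundaries",
    "auto_seed",
    "segment_cortex",
]
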