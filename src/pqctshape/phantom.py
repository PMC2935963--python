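"""Synthetic pQCT-like cross-sections with analytically known geometry.

The generator emulates what a mid-shaft tibial slice looks like to the
analysis pipeline: a dense cortical ring (attenuation well above the
segmentation threshold) around a low-value medullary cavity, on a
low-value background, optionally with endosteal trabeculization speckle,
additive Gaussian noise, and a movement-artifact streak. Every phantom
carries its :class:`GroundTruth`: closed-form values where they exist
(circles, ellipse areas and diameters, Ramanujan's ellipse-perimeter
approximation) and dense-boundary numerical values (10,000-point
polylines) where they do not (thickness maps of non-concentric shapes,
every quantity of the tibia-like shape).

Default attenuation values (cortical 800, background 60, scanner units)
bracket the standard analysis threshold of 450 with a wide margin, the
situation of a good-quality scan.

Shapes
------
circular_annulus
    Outer circle radius R, inner circle radius r, optional inner offset.
eccentric_annulus
    Alias for a circular annulus with a nonzero inner offset.
elliptical_annulus
    Outer ellipse (a, b), inner ellipse, common rotation, optional offset.
tibia_like
    Rounded-triangle outer boundary r(t) = R0 (1 + 0.10 cos 3t + 0.02 cos 2t)
    with a radially offset inner boundary — size and cortical thickness in
    the range of real mid-shaft tibiae (max diameter ~26-28 mm, mean
    thickness ~4-5 mm).

Axis convention for directional ground truth: the maximum-diameter axis of
the generating boundary; for circles (where every diameter ties) the image
vertical is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PQCTShapeError
from .io import ImageGeometry, ScanImage
from .shape_metrics import point_to_segments_distance

SHAPES = ("circular_annulus", "eccentric_annulus", "elliptical_annulus", "tibia_like")

_TIBIA_A3 = 0.10  # rounded-triangle harmonic
_TIBIA_A2 = 0.02  # mild ovality
_TRUTH_N = 10000  # dense-boundary resolution for numerical ground truth


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic cortical ring."""

    shape: str = "circular_annulus"
    outer: float | tuple[float, float] = 13.0  # radius or semi-axes, mm
    inner: float | tuple[float, float] = 9.0  # radius/semi-axes (tibia: wall thickness)
    inner_offset: tuple[float, float] = (0.0, 0.0)  # (dx, dy) mm, y down
    rotation_deg: float = 0.0
    cortical_value: int = 800
    background_value: int = 60
    trabeculization_fraction: float = 0.0
    trabeculization_band_mm: float = 1.0
    noise_sd: float = 0.0
    motion_streak: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise PQCTShapeError(f"unknown phantom shape {self.shape!r}")
        if self.cortical_value <= self.background_value:
            raise PQCTShapeError("cortical_value must exceed background_value")
        if self.noise_sd < 0:
            raise PQCTShapeError("noise_sd must be >= 0")
        if not (0.0 <= self.trabeculization_fraction <= 1.0):
            raise PQCTShapeError("trabeculization_fraction must be in [0, 1]")
        ob, ib = self._outer_inner_polar(np.linspace(0, 2 * np.pi, 720, endpoint=False))
        ib = ib + float(np.hypot(*self.inner_offset))
        if not np.all(ob > ib + 1e-9):
            raise PQCTShapeError("outer boundary must strictly contain the inner one")

    # -- canonical-frame geometry -------------------------------------------

    def _outer_inner_polar(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Radial extent of both boundaries about their own centers (checks only)."""
        if self.shape in ("circular_annulus", "eccentric_annulus"):
            return np.full_like(theta, float(self.outer)), np.full_like(
                theta, float(self.inner)
            )
        if self.shape == "elliptical_annulus":
            a, b = self.outer
            a2, b2 = self.inner
            ro = a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))
            ri = a2 * b2 / np.hypot(b2 * np.cos(theta), a2 * np.sin(theta))
            return ro, ri
        ro = self._tibia_radius(theta)
        return ro, ro - float(self.inner)

    def _tibia_radius(self, theta: np.ndarray) -> np.ndarray:
        R0 = float(self.outer) if np.isscalar(self.outer) else float(self.outer[0])
        return R0 * (1.0 + _TIBIA_A3 * np.cos(3 * theta) + _TIBIA_A2 * np.cos(2 * theta))

    def _rot(self) -> np.ndarray:
        t = np.radians(self.rotation_deg)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def boundaries(self, n: int = _TRUTH_N) -> tuple[np.ndarray, np.ndarray]:
        """Dense analytic periosteal/endosteal boundaries, centered at (0,0)."""
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        R = self._rot()
        if self.shape in ("circular_annulus", "eccentric_annulus"):
            outer = float(self.outer) * np.column_stack([np.cos(theta), np.sin(theta)])
            inner = float(self.inner) * np.column_stack(
                [np.cos(theta), np.sin(theta)]
            ) + np.asarray(self.inner_offset)
            return outer, inner
        if self.shape == "elliptical_annulus":
            a, b = self.outer
            a2, b2 = self.inner
            outer = np.column_stack([a * np.cos(theta), b * np.sin(theta)]) @ R.T
            inner = (
                np.column_stack([a2 * np.cos(theta), b2 * np.sin(theta)]) @ R.T
                + np.asarray(self.inner_offset)
            )
            return outer, inner
        ro = self._tibia_radius(theta)
        ri = ro - float(self.inner)
        outer = np.column_stack([ro * np.cos(theta), ro * np.sin(theta)]) @ R.T
        inner = (
            np.column_stack([ri * np.cos(theta), ri * np.sin(theta)]) @ R.T
            + np.asarray(self.inner_offset)
        )
        return outer, inner

    def contains(self, x: np.ndarray, y: np.ndarray, inner_shrink: float = 0.0):
        """Membership of centered points in the outer region and inner cavity."""
        R = self._rot()
        # rotate into the canonical frame
        xc = R[0, 0] * x + R[1, 0] * y
        yc = R[0, 1] * x + R[1, 1] * y
        ox, oy = self.inner_offset
        xi = R[0, 0] * (x - ox) + R[1, 0] * (y - oy)
        yi = R[0, 1] * (x - ox) + R[1, 1] * (y - oy)
        if self.shape in ("circular_annulus", "eccentric_annulus"):
            in_outer = xc * xc + yc * yc <= float(self.outer) ** 2
            ri = max(float(self.inner) - inner_shrink, 0.0)
            in_inner = xi * xi + yi * yi < ri * ri
            return in_outer, in_inner
        if self.shape == "elliptical_annulus":
            a, b = self.outer
            a2 = max(self.inner[0] - inner_shrink, 1e-9)
            b2 = max(self.inner[1] - inner_shrink, 1e-9)
            in_outer = (xc / a) ** 2 + (yc / b) ** 2 <= 1.0
            in_inner = (xi / a2) ** 2 + (yi / b2) ** 2 < 1.0
            return in_outer, in_inner
        theta_o = np.arctan2(yc, xc)
        rho_o = np.hypot(xc, yc)
        in_outer = rho_o <= self._tibia_radius(theta_o)
        theta_i = np.arctan2(yi, xi)
        rho_i = np.hypot(xi, yi)
        ri = self._tibia_radius(theta_i) - float(self.inner) - inner_shrink
        in_inner = rho_i < np.maximum(ri, 0.0)
        return in_outer, in_inner


@dataclass
class GroundTruth:
    """Analytic / dense-boundary reference values for a phantom, mm and mm^2."""

    peri_circ: float
    endo_circ: float
    max_diam: float
    min_diam: float
    thickness: dict = field(default_factory=dict)
    tot_csa: float = 0.0
    cort_csa: float = 0.0
    err_circle: float = 0.0
    err_ellipse: float = 0.0


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _ramanujan(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))


def _max_min_diameter(pts: np.ndarray) -> tuple[float, np.ndarray, float]:
    from scipy.spatial import ConvexHull

    hull = pts[ConvexHull(pts).vertices]
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    axis = hull[j] - hull[i]
    perp = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
    proj = pts @ perp
    return float(np.sqrt(d2[i, j])), axis, float(proj.max() - proj.min())


def _thickness_stats(outer: np.ndarray, inner: np.ndarray, spec: PhantomSpec) -> dict:
    # subsample the periosteal boundary for the O(n*m) distance map
    step = max(1, len(outer) // 2400)
    profile = _chunked_min_distance(outer[::step], inner)
    dmax, axis, _ = _max_min_diameter(outer)
    if spec.shape in ("circular_annulus", "eccentric_annulus"):
        axis = np.array([0.0, 1.0])  # every diameter ties: use the image vertical
    from .shape_metrics import directional_thickness

    u = axis / np.linalg.norm(axis)
    perp = np.array([-u[1], u[0]])
    A_out = _polygon_area(outer)
    A_in = _polygon_area(inner)
    cen_out = outer.mean(axis=0)
    cen_in = inner.mean(axis=0)
    cen = (A_out * cen_out - A_in * cen_in) / (A_out - A_in)  # ring centroid

    class _P:  # lightweight stand-in accepted by directional_thickness
        def __init__(self, points):
            self.points = points

    d = directional_thickness(_P(outer), _P(inner), tuple(cen), u)
    return {
        "anterior": d["anterior"],
        "posterior": d["posterior"],
        "left": d["left"],
        "right": d["right"],
        "min": float(profile.min()),
        "max": float(profile.max()),
        "mean": float(profile.mean()),
    }


def _chunked_min_distance(points: np.ndarray, polygon: np.ndarray, block: int = 400):
    out = np.empty(len(points))
    for i in range(0, len(points), block):
        out[i : i + block] = point_to_segments_distance(points[i : i + block], polygon)
    return out


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Reference geometry of a phantom, independent of any rasterization."""
    outer, inner = spec.boundaries(_TRUTH_N)
    if spec.shape in ("circular_annulus", "eccentric_annulus"):
        R, r = float(spec.outer), float(spec.inner)
        peri_circ, endo_circ = 2 * np.pi * R, 2 * np.pi * r
        max_d = min_d = 2 * R
        tot, cort = np.pi * R * R, np.pi * (R * R - r * r)
        err_circle = 0.0
        err_ellipse = 0.0
    elif spec.shape == "elliptical_annulus":
        a, b = spec.outer
        a2, b2 = spec.inner
        peri_circ, endo_circ = _ramanujan(a, b), _ramanujan(a2, b2)
        max_d, min_d = 2 * max(a, b), 2 * min(a, b)
        tot, cort = np.pi * a * b, np.pi * (a * b - a2 * b2)
        err_circle = _numeric_err_circle(outer)
        err_ellipse = 0.0
    else:
        peri_circ, endo_circ = _polyline_length(outer), _polyline_length(inner)
        max_d, _, min_d = _max_min_diameter(outer)
        tot = _polygon_area(outer)
        cort = tot - _polygon_area(inner)
        err_circle = _numeric_err_circle(outer)
        err_ellipse = _numeric_err_ellipse(outer)
    return GroundTruth(
        peri_circ=float(peri_circ),
        endo_circ=float(endo_circ),
        max_diam=float(max_d),
        min_diam=float(min_d),
        thickness=_thickness_stats(outer, inner, spec),
        tot_csa=float(tot),
        cort_csa=float(cort),
        err_circle=float(err_circle),
        err_ellipse=float(err_ellipse),
    )


def _numeric_err_circle(pts: np.ndarray) -> float:
    from .conic_fit import average_error_circle, fit_circle

    sub = pts[:: max(1, len(pts) // 1000)]
    return average_error_circle(sub, fit_circle(sub))


def _numeric_err_ellipse(pts: np.ndarray) -> float:
    from .conic_fit import average_error_ellipse, fit_ellipse

    sub = pts[:: max(1, len(pts) // 1000)]
    return average_error_ellipse(sub, fit_ellipse(sub))


def rasterize(
    spec: PhantomSpec, geometry: ImageGeometry | None = None
) -> tuple[ScanImage, GroundTruth]:
    """Rasterize a phantom: a pixel is cortical iff its center is in the ring."""
    geometry = geometry or ImageGeometry()
    v = geometry.voxel_size
    cx = geometry.width * v / 2.0
    cy = geometry.height * v / 2.0
    outer, _ = spec.boundaries(720)
    margin = 2.0 * v
    if (
        np.abs(outer[:, 0]).max() + margin > min(cx, geometry.width * v - cx)
        or np.abs(outer[:, 1]).max() + margin > min(cy, geometry.height * v - cy)
    ):
        raise PQCTShapeError(
            "phantom does not fit inside the image with a 2-voxel margin"
        )
    cols = (np.arange(geometry.width) + 0.5) * v - cx
    rows = (np.arange(geometry.height) + 0.5) * v - cy
    X, Y = np.meshgrid(cols, rows)
    in_outer, in_inner = spec.contains(X, Y)
    ring = in_outer & ~in_inner
    values = np.where(ring, spec.cortical_value, spec.background_value).astype(np.uint16)
    return ScanImage(geometry, values), ground_truth(spec)


def add_trabeculization(image: ScanImage, spec: PhantomSpec) -> ScanImage:
    """Seeded speckle of cortical-valued pixels on the endosteal surface.

    Affects the band of cavity pixels within ``trabeculization_band_mm`` of
    the endosteal boundary; ``trabeculization_fraction`` of those pixels are
    set to the cortical value. Deterministic for a fixed spec seed.
    """
    if spec.trabeculization_fraction == 0.0:
        return ScanImage(image.geometry, image.values.copy())
    g = image.geometry
    v = g.voxel_size
    cx, cy = g.width * v / 2.0, g.height * v / 2.0
    cols = (np.arange(g.width) + 0.5) * v - cx
    rows = (np.arange(g.height) + 0.5) * v - cy
    X, Y = np.meshgrid(cols, rows)
    _, in_inner = spec.contains(X, Y)
    _, in_core = spec.contains(X, Y, inner_shrink=spec.trabeculization_band_mm)
    band = in_inner & ~in_core
    rng = np.random.default_rng(spec.seed)
    pick = band & (rng.random(band.shape) < spec.trabeculization_fraction)
    values = image.values.copy()
    values[pick] = spec.cortical_value
    return ScanImage(g, values)


def add_noise_and_artifacts(image: ScanImage, spec: PhantomSpec) -> ScanImage:
    """Seeded Gaussian noise plus an optional movement-artifact streak.

    The streak is a one-pixel-high cortical-valued chord through the
    medullary cavity, crossing both cortical walls and protruding ~3 mm
    beyond the periosteal surface: it splits the enclosed cavity in two,
    which trips the downstream topology rules the way real movement
    artifacts broke the original analysis.
    """
    g = image.geometry
    values = image.values.astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    if spec.motion_streak:
        v = g.voxel_size
        outer, _ = spec.boundaries(720)
        half_extent = np.abs(outer[:, 0]).max() + 3.0  # mm beyond the ring
        row = g.height // 2
        c0 = int(np.floor((g.width * v / 2.0 - half_extent) / v))
        c1 = int(np.ceil((g.width * v / 2.0 + half_extent) / v))
        c0 = max(c0, 1)
        c1 = min(c1, g.width - 1)
        # 3 px thick so a single morphological opening cannot remove it
        values[row - 1 : row + 2, c0:c1] = spec.cortical_value
    out = np.clip(np.rint(values), 0, 65535).astype(np.uint16)
    return ScanImage(g, out)


def generate(
    spec: PhantomSpec, geometry: ImageGeometry | None = None
) -> tuple[ScanImage, GroundTruth]:
    """Rasterize a phantom and apply trabeculization, noise and artifacts."""
    image, truth = rasterize(spec, geometry)
    image = add_trabeculization(image, spec)
    image = add_noise_and_artifacts(image, spec)
    return image, truth


__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SHAPES",
    "rasterize",
    "ground_truth",
    "add_trabeculization",
    "add_noise_and_artifacts",
    "generate",
]
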