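"""Shape quantities of a cortical cross-section.

Given the periosteal and endosteal contours and the cortical mask, this
module computes the full per-scan record: centroid, maximum and minimum
diameter, the angle of the maximum diameter from the image vertical,
digital circumferences, the directional cortical-thickness family, and
cross-sectional areas.

Definitions
-----------
max diameter
    Largest Euclidean distance between any two periosteal contour points
    (the maximum Feret diameter).
min diameter
    Width of the contour's orthogonal projection onto the axis
    perpendicular to the maximum diameter — a projection width, not a
    chord, so it stays well defined for concave tibial sections. The
    centroid-chord variant is available via ``min_diameter(..., chord=True)``.
cortical thickness
    For each periosteal vertex, the shortest distance to the endosteal
    polygon (point-to-segment). Anterior/posterior thicknesses are measured
    where the maximum-diameter line through the centroid crosses the two
    boundaries; anterior is the side toward the image top (standard pQCT
    positioning), left the side toward smaller x. Left/right values are
    computed but excluded from the default report.
areas
    ``tot_csa`` and ``cort_csa`` are pixel-count areas (pixels x v^2) of the
    filled section and of the cortical ring — the convention of standard
    image-moment tools, unbiased for smooth shapes. The shoelace areas of
    the two boundary polygons are also reported (``*_polygon``), slightly
    smaller because pixel-center polygons sit half a pixel inside the
    digital region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from .errors import AxisMissError, PQCTShapeError
from .segmentation import Contour, CorticalMask

#: Column order of the per-scan CSV record.
CSV_COLUMNS = [
    "centroid_x_mm",
    "centroid_y_mm",
    "max_diameter_mm",
    "min_diameter_mm",
    "axis_angle_deg",
    "peri_circ_mm",
    "endo_circ_mm",
    "thickness_anterior_mm",
    "thickness_posterior_mm",
    "thickness_left_mm",
    "thickness_right_mm",
    "thickness_min_mm",
    "thickness_max_mm",
    "thickness_mean_mm",
    "tot_csa_mm2",
    "cort_csa_mm2",
    "tot_csa_polygon_mm2",
    "cort_csa_polygon_mm2",
    "err_circle_mm2",
    "err_ellipse",
]


@dataclass
class ShapeResult:
    """Complete shape record for one cross-section."""

    centroid: tuple[float, float]
    max_diameter: float
    max_axis_endpoints: np.ndarray  # (2, 2) array of (x, y) mm
    min_diameter: float
    axis_angle_deg: float
    peri_circ: float
    endo_circ: float
    thickness_anterior: float
    thickness_posterior: float
    thickness_left: float
    thickness_right: float
    thickness_min: float
    thickness_max: float
    thickness_mean: float
    tot_csa: float
    cort_csa: float
    tot_csa_polygon: float
    cort_csa_polygon: float
    err_circle: float | None = None
    err_ellipse: float | None = None

    def __post_init__(self):
        if not (self.max_diameter >= self.min_diameter > 0):
            raise PQCTShapeError("diameter invariant violated (max >= min > 0)")
        if not (self.peri_circ > self.endo_circ > 0):
            raise PQCTShapeError("circumference invariant violated")
        if not (self.thickness_min <= self.thickness_mean <= self.thickness_max):
            raise PQCTShapeError("thickness ordering invariant violated")
        if self.thickness_min <= 0:
            raise PQCTShapeError("thicknesses must be positive")
        if not (self.tot_csa > self.cort_csa > 0):
            raise PQCTShapeError("area invariant violated (tot > cort > 0)")

    def to_dict(self) -> dict:
        d = {
            "centroid_x_mm": self.centroid[0],
            "centroid_y_mm": self.centroid[1],
            "max_diameter_mm": self.max_diameter,
            "min_diameter_mm": self.min_diameter,
            "axis_angle_deg": self.axis_angle_deg,
            "peri_circ_mm": self.peri_circ,
            "endo_circ_mm": self.endo_circ,
            "thickness_anterior_mm": self.thickness_anterior,
            "thickness_posterior_mm": self.thickness_posterior,
            "thickness_left_mm": self.thickness_left,
            "thickness_right_mm": self.thickness_right,
            "thickness_min_mm": self.thickness_min,
            "thickness_max_mm": self.thickness_max,
            "thickness_mean_mm": self.thickness_mean,
            "tot_csa_mm2": self.tot_csa,
            "cort_csa_mm2": self.cort_csa,
            "tot_csa_polygon_mm2": self.tot_csa_polygon,
            "cort_csa_polygon_mm2": self.cort_csa_polygon,
            "err_circle_mm2": self.err_circle,
            "err_ellipse": self.err_ellipse,
        }
        return d


def centroid(mask: CorticalMask, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Center of mass of the cortical pixels in mm.

    Unweighted (binary) by default; pass an attenuation grid as ``weights``
    for the density-weighted variant.
    """
    m = mask.pixels
    if not m.any():
        raise PQCTShapeError("cannot compute the centroid of an empty mask")
    if weights is None:
        r, c = ndi.center_of_mass(m)
    else:
        w = np.where(m, np.asarray(weights, dtype=float), 0.0)
        r, c = ndi.center_of_mass(w)
    v = mask.voxel_size
    return ((c + 0.5) * v, (r + 0.5) * v)


def _points(contour) -> np.ndarray:
    """Accept a Contour, any object with ``.points``, or a bare array."""
    return np.atleast_2d(
        np.asarray(getattr(contour, "points", contour), dtype=float)
    )


def max_diameter(contour: Contour | np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum Feret diameter and its endpoints.

    Restricts the all-pairs search to convex-hull vertices (the diameter of
    a point set is attained on its hull), which matches the brute-force
    all-pairs scan exactly. Ties are broken by the smallest (y, then x) of
    the first endpoint; endpoints are ordered so the first has the smaller
    (y, x).
    """
    pts = _points(contour)
    if len(pts) < 2:
        raise PQCTShapeError("need at least 2 points for a diameter")
    if len(pts) > 3:
        try:
            hull = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input and similar qhull degeneracies
            hull = pts
    else:
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(np.isclose(d2, best, rtol=0, atol=0))
    # canonical endpoints: order each pair by (y, x); pick lexicographic min
    cands = []
    for i, j in zip(ii, jj):
        if i == j:
            continue
        a, b = hull[i], hull[j]
        if (a[1], a[0]) > (b[1], b[0]):
            a, b = b, a
        cands.append((a[1], a[0], b[1], b[0]))
    key = min(range(len(cands)), key=lambda k: cands[k])
    ay, ax, by, bx = cands[key]
    endpoints = np.array([[ax, ay], [bx, by]])
    return float(np.sqrt(best)), endpoints


def min_diameter(
    contour: Contour | np.ndarray,
    max_axis: np.ndarray,
    chord: bool = False,
    through: tuple[float, float] | None = None,
) -> float:
    """Extent perpendicular to the maximum-diameter axis.

    Default: projection width (max - min projection of all contour points
    onto the perpendicular direction). With ``chord=True``, the length of
    the chord through ``through`` (required) along the perpendicular.
    """
    pts = _points(contour)
    u = np.asarray(max_axis, dtype=float)
    if u.ndim == 2:  # endpoints given
        u = u[1] - u[0]
    n = np.linalg.norm(u)
    if n == 0:
        raise PQCTShapeError("max axis direction is degenerate")
    perp = np.array([-u[1], u[0]]) / n
    if not chord:
        proj = pts @ perp
        return float(proj.max() - proj.min())
    if through is None:
        raise PQCTShapeError("chord variant requires a point to pass through")
    ts = _line_polygon_intersections(pts, np.asarray(through, float), perp)
    if len(ts) < 2:
        raise AxisMissError("perpendicular chord misses the contour")
    return float(max(ts) - min(ts))


def axis_angle(endpoints: np.ndarray) -> float:
    """Unsigned angle (degrees) between a segment and the image vertical.

    0 for a vertical segment (constant x), 90 for horizontal, folded into
    [0, 180).
    """
    endpoints = np.asarray(endpoints, dtype=float)
    dx = endpoints[1, 0] - endpoints[0, 0]
    dy = endpoints[1, 1] - endpoints[0, 1]
    if dx == 0 and dy == 0:
        raise PQCTShapeError("coincident endpoints have no direction")
    ang = np.degrees(np.arctan2(dx, dy)) % 180.0
    return float(ang)


def perimeter(contour: Contour | np.ndarray) -> float:
    """Length of the closed boundary polygon.

    For chain-code contours traced on the pixel grid the segments are v and
    v*sqrt(2) steps. Note the digital perimeter of a smooth shape carries a
    positive bias of up to ~8% (about +5% for a circle) that does NOT
    vanish with resolution; see the methods note.
    """
    pts = _points(contour)
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Unsigned shoelace area of the closed polygon."""
    pts = _points(contour)
    x, y = pts[:, 0], pts[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def point_to_segments_distance(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Min distance from each point to a closed polygon (point-to-segment)."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    A = np.asarray(polygon, dtype=float)
    B = np.roll(A, -1, axis=0)
    AB = B - A  # (m, 2)
    ab2 = np.einsum("ij,ij->i", AB, AB)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    AP = P[:, None, :] - A[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmi,mi->nm", AP, AB) / ab2, 0.0, 1.0)
    D = AP - t[:, :, None] * AB[None, :, :]
    return np.sqrt(np.einsum("nmi,nmi->nm", D, D)).min(axis=1)


def thickness_profile(peri: Contour, endo: Contour) -> np.ndarray:
    """Cortical thickness at every periosteal vertex.

    Shortest distance from each periosteal vertex to the endosteal polygon;
    the direction is periosteal -> endosteal, matching the convention that
    thickness starts on the outer surface.
    """
    return point_to_segments_distance(_points(peri), _points(endo))


def _line_polygon_intersections(
    polygon: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Signed parameters t where origin + t*direction crosses polygon edges."""
    A = polygon
    B = np.roll(polygon, -1, axis=0)
    d = direction / np.linalg.norm(direction)
    e = B - A
    # solve origin + t d = A + s e  for each edge
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = A - origin
        t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
        s = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
    # inclusive bounds with tolerance: a crossing exactly at a shared vertex
    # must not be lost to rounding; duplicates are harmless (extremes used)
    eps = 1e-9
    ok = np.isfinite(t) & np.isfinite(s) & (s >= -eps) & (s <= 1.0 + eps)
    return np.sort(t[ok])


def directional_thickness(
    peri: Contour,
    endo: Contour,
    center: tuple[float, float],
    max_axis: np.ndarray,
) -> dict[str, float]:
    """Anterior/posterior/left/right cortical thickness.

    Casts the maximum-diameter line through the centroid. On each side the
    thickness is the distance between the outermost periosteal crossing and
    the outermost endosteal crossing. Anterior = the side whose periosteal
    crossing has the smaller y (image top); left = smaller x on the
    perpendicular axis.
    """
    u = np.asarray(max_axis, dtype=float)
    if u.ndim == 2:
        u = u[1] - u[0]
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    c = np.asarray(center, dtype=float)

    def _sides(direction):
        tp = _line_polygon_intersections(_points(peri), c, direction)
        te = _line_polygon_intersections(_points(endo), c, direction)
        tp_pos, tp_neg = tp[tp > 0], tp[tp < 0]
        te_pos, te_neg = te[te > 0], te[te < 0]
        if len(tp_pos) == 0 or len(tp_neg) == 0 or len(te_pos) == 0 or len(te_neg) == 0:
            raise AxisMissError("axis misses cortex (a ray failed to cross both boundaries)")
        th_pos = tp_pos.max() - te_pos.max()
        th_neg = te_neg.min() - tp_neg.min()
        p_pos = c + tp_pos.max() * direction
        p_neg = c + tp_neg.min() * direction
        return (float(th_pos), p_pos), (float(th_neg), p_neg)

    (th_a, pa), (th_b, pb) = _sides(u)
    # anterior: periosteal crossing with the smaller image row (y), then col
    if (pa[1], pa[0]) <= (pb[1], pb[0]):
        anterior, posterior = th_a, th_b
    else:
        anterior, posterior = th_b, th_a
    (th_c, pc), (th_d, pd) = _sides(perp)
    if (pc[0], pc[1]) <= (pd[0], pd[1]):  # left: smaller column (x)
        left, right = th_c, th_d
    else:
        left, right = th_d, th_c
    return {
        "anterior": anterior,
        "posterior": posterior,
        "left": left,
        "right": right,
    }


def summarize(
    mask: CorticalMask,
    peri: Contour,
    endo: Contour,
    fit_conics: bool = True,
) -> ShapeResult:
    """Assemble the full shape record for one segmented cross-section."""
    from . import conic_fit  # local import: conic_fit is layered above

    v = mask.voxel_size
    cen = centroid(mask)
    dmax, endpoints = max_diameter(peri)
    # projection width cannot exceed the diameter; clamp float-rounding spill
    dmin = min(min_diameter(peri, endpoints), dmax)
    angle = axis_angle(endpoints)
    profile = thickness_profile(peri, endo)
    directional = directional_thickness(peri, endo, cen, endpoints)

    filled = ndi.binary_fill_holes(mask.pixels)
    tot_csa = float(filled.sum()) * v * v
    cort_csa = float(mask.pixels.sum()) * v * v
    tot_poly = polygon_area(peri)
    cort_poly = tot_poly - polygon_area(endo)

    err_circle = err_ellipse = None
    if fit_conics:
        cfit = conic_fit.fit_circle(peri.points)
        err_circle = conic_fit.average_error_circle(peri.points, cfit)
        efit = conic_fit.fit_ellipse(peri.points)
        err_ellipse = conic_fit.average_error_ellipse(peri.points, efit)

    return ShapeResult(
        centroid=cen,
        max_diameter=dmax,
        max_axis_endpoints=endpoints,
        min_diameter=dmin,
        axis_angle_deg=angle,
        peri_circ=perimeter(peri),
        endo_circ=perimeter(endo),
        thickness_anterior=directional["anterior"],
        thickness_posterior=directional["posterior"],
        thickness_left=directional["left"],
        thickness_right=directional["right"],
        thickness_min=float(profile.min()),
        thickness_max=float(profile.max()),
        thickness_mean=float(profile.mean()),
        tot_csa=tot_csa,
        cort_csa=cort_csa,
        tot_csa_polygon=tot_poly,
        cort_csa_polygon=cort_poly,
        err_circle=err_circle,
        err_ellipse=err_ellipse,
    )


__all__ = [
    "ShapeResult",
    "CSV_COLUMNS",
    "centroid",
    "max_diameter",
    "min_diameter",
    "axis_angle",
    "perimeter",
    "polygon_area",
    "point_to_segments_distance",
    "thickness_profile",
    "directional_thickness",
    "summarize",
]
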