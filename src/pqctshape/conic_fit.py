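"""Ideal-circle and ideal-ellipse fits to a bone boundary.

Quantifies how far a cross-section deviates from an ideal circle or
ellipse: a perfectly circular (elliptical) section has an error of 0.

Circle: algebraic least squares (Kasa), minimizing
``sum (x^2 + y^2 + D x + E y + F)^2`` — a linear problem, exact when the
points lie on a circle.

Ellipse: direct least-squares conic fit with the ellipse-specificity
constraint ``4ac - b^2 = 1`` solved via the generalized eigenproblem, in
the numerically stabilized scatter-matrix-partitioned form (Halir-Flusser)
that avoids the classical formulation's singular-matrix failures. Data are
centered and scaled before fitting and the conic is mapped back, so exact
inputs are recovered to machine precision.

Error conventions (both exposed, see ``kind=``):
* circle error — geometric: mean squared radial deviation, in mm^2;
* ellipse error — algebraic: mean squared conic residual under the
  ``4ac - b^2 = 1`` normalization (dimensionally mm^4-like "residual
  units"); the geometric Sampson approximation of squared orthogonal
  distance is available as ``kind="geometric"``.
The two defaults deliberately differ: they are the only self-consistent
reading of the reported magnitudes of the two deviation indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError


@dataclass
class CircleFit:
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise DegenerateFitError("fitted circle has non-positive radius")


@dataclass
class EllipseFit:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # degrees in [0, 180), major axis from +x, y down
    conic_coeffs: tuple[float, float, float, float, float, float]

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise DegenerateFitError("ellipse axes invariant violated")
        a, b, c, *_ = self.conic_coeffs
        if not (b * b - 4 * a * c) < 0:
            raise DegenerateFitError("conic coefficients are not an ellipse")

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.semi_minor / self.semi_major) ** 2))


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(getattr(points, "points", points), dtype=float))
    return pts[:, 0], pts[:, 1]


def fit_circle(points) -> CircleFit:
    """Algebraic least-squares circle through a point set."""
    x, y = _as_xy(points)
    if len(x) < 3:
        raise DegenerateFitError("need at least 3 points to fit a circle")
    A = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateFitError("points are collinear; circle fit is degenerate")
    b = -(x * x + y * y)
    (D, E, F), *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx * cx + cy * cy - F
    if r2 <= 0:
        raise DegenerateFitError("circle fit produced a non-positive radius")
    return CircleFit(center=(float(cx), float(cy)), radius=float(np.sqrt(r2)))


def _halir_flusser(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stabilized direct ellipse fit; returns conic (a,b,c,d,e,f), unnormalized."""
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"scatter matrix singular: {exc}") from exc
    M = S1 + S2 @ T
    # premultiply by C1^{-1} with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # the ellipse solution satisfies 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    idx = np.nonzero(cond > 0)[0]
    if len(idx) == 0:
        raise DegenerateFitError(
            "no elliptical eigen-solution (degenerate or non-elliptical scatter)"
        )
    a1 = np.real(eigvec[:, idx[0]])
    a2 = T @ a1
    return np.concatenate([a1, a2])


def _conic_denormalize(coef, mx, my, s) -> np.ndarray:
    """Map conic fitted on u=(x-mx)/s, v=(y-my)/s back to (x, y)."""
    A, B, C, D, E, F = coef
    s2 = s * s
    a = A / s2
    b = B / s2
    c = C / s2
    d = -2 * A * mx / s2 - B * my / s2 + D / s
    e = -B * mx / s2 - 2 * C * my / s2 + E / s
    f = (
        A * mx * mx / s2
        + B * mx * my / s2
        + C * my * my / s2
        - D * mx / s
        - E * my / s
        + F
    )
    return np.array([a, b, c, d, e, f])


def _conic_to_geometry(coef) -> tuple[tuple[float, float], float, float, float]:
    a, b, c, d, e, f = coef
    disc = b * b - 4 * a * c
    if disc >= 0:
        raise DegenerateFitError("conic is not an ellipse (discriminant >= 0)")
    cx = (2 * c * d - b * e) / disc
    cy = (2 * a * e - b * d) / disc
    # value of the conic at the center
    fc = a * cx * cx + b * cx * cy + c * cy * cy + d * cx + e * cy + f
    Q = np.array([[a, b / 2.0], [b / 2.0, c]])
    lam, vec = np.linalg.eigh(Q)
    axes2 = -fc / lam
    if np.any(axes2 <= 0):
        raise DegenerateFitError("ellipse axes are not real (numerical failure)")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]  # major first
    major, minor = float(axes[order[0]]), float(axes[order[1]])
    vmaj = vec[:, order[0]]
    angle = float(np.degrees(np.arctan2(vmaj[1], vmaj[0])) % 180.0)
    return (float(cx), float(cy)), major, minor, angle


def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares ellipse fit with the 4ac - b^2 = 1 constraint."""
    x, y = _as_xy(points)
    if len(x) < 6:
        raise DegenerateFitError("need at least 6 points to fit an ellipse")
    mx, my = x.mean(), y.mean()
    s = np.sqrt(((x - mx) ** 2 + (y - my) ** 2).mean())
    if s == 0:
        raise DegenerateFitError("all points coincide")
    coef = _halir_flusser((x - mx) / s, (y - my) / s)
    coef = _conic_denormalize(coef, mx, my, s)
    norm = 4.0 * coef[0] * coef[2] - coef[1] ** 2
    if norm <= 0:
        raise DegenerateFitError("fitted conic is hyperbolic/parabolic (numerical failure)")
    coef = coef / np.sqrt(norm)
    if coef[0] < 0:  # sign convention: a > 0 (both signs satisfy 4ac - b^2 = 1)
        coef = -coef
    center, major, minor, angle = _conic_to_geometry(coef)
    return EllipseFit(
        center=center,
        semi_major=major,
        semi_minor=minor,
        orientation=angle,
        conic_coeffs=tuple(float(v) for v in coef),
    )


def average_error_circle(points, fit: CircleFit) -> float:
    """Mean squared radial deviation from the fitted circle, in mm^2."""
    x, y = _as_xy(points)
    r = np.hypot(x - fit.center[0], y - fit.center[1])
    return float(np.mean((r - fit.radius) ** 2))


def conic_residuals(points, coef) -> np.ndarray:
    """Algebraic conic residual a x^2 + b xy + c y^2 + d x + e y + f."""
    x, y = _as_xy(points)
    a, b, c, d, e, f = coef
    return a * x * x + b * x * y + c * y * y + d * x + e * y + f


def average_error_ellipse(points, fit: EllipseFit, kind: str = "algebraic") -> float:
    """Mean squared deviation from the fitted ellipse.

    ``kind="algebraic"`` (default): squared conic residual under the
    4ac - b^2 = 1 normalization. ``kind="geometric"``: Sampson
    approximation of squared orthogonal distance, in mm^2.
    """
    res = conic_residuals(points, fit.conic_coeffs)
    if kind == "algebraic":
        return float(np.mean(res**2))
    if kind == "geometric":
        x, y = _as_xy(points)
        a, b, c, d, e, _ = fit.conic_coeffs
        gx = 2 * a * x + b * y + d
        gy = b * x + 2 * c * y + e
        g2 = gx * gx + gy * gy
        g2 = np.where(g2 == 0, np.inf, g2)
        return float(np.mean(res**2 / g2))
    raise ValueError(f"unknown error kind {kind!r}")


__all__ = [
    "CircleFit",
    "EllipseFit",
    "fit_circle",
    "fit_ellipse",
    "average_error_circle",
    "average_error_ellipse",
    "conic_residuals",
]
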