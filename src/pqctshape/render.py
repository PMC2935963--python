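"""Quality-control overlay rendering.

Every analysis can emit a visual representation of all outputs — the scan
as a grayscale base with the traced contours, diameter axes, fitted conics
and centroid drawn on top — so an operator can see at a glance whether a
bone was correctly analyzed. Rendering is plain Pillow vector drawing on
an upscaled raster and is byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .conic_fit import CircleFit, EllipseFit
from .errors import PQCTShapeError
from .io import ScanImage
from .segmentation import Contour, CorticalMask
from .shape_metrics import ShapeResult

ALL_LAYERS = (
    "mask",
    "periosteal",
    "endosteal",
    "max_axis",
    "min_axis",
    "fitted_circle",
    "fitted_ellipse",
    "centroid",
)

_COLORS = {
    "mask": (70, 70, 0),
    "periosteal": (0, 220, 0),
    "endosteal": (230, 60, 60),
    "max_axis": (255, 215, 0),
    "min_axis": (0, 200, 220),
    "fitted_circle": (80, 120, 255),
    "fitted_ellipse": (230, 80, 230),
    "centroid": (255, 255, 255),
}


@dataclass
class RenderSpec:
    """What to draw and where."""

    layers: tuple[str, ...] = ALL_LAYERS
    out: str = "overlay.png"
    upscale: int = 4

    def __post_init__(self):
        if not self.layers:
            raise PQCTShapeError("render spec needs at least one layer")
        unknown = set(self.layers) - set(ALL_LAYERS)
        if unknown:
            raise PQCTShapeError(f"unknown render layer(s): {', '.join(sorted(unknown))}")
        if self.upscale < 1:
            raise PQCTShapeError("upscale must be >= 1")


def _mm_to_px(points: np.ndarray, voxel: float, upscale: int) -> list[tuple[float, float]]:
    # pixel center (c+0.5)v maps to upscaled raster coordinate (c+0.5)*upscale
    pts = np.asarray(points, dtype=float) / voxel * upscale
    return [tuple(p) for p in pts]


def _ellipse_points(fit: EllipseFit, n: int = 360) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ang = np.radians(fit.orientation)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pts = np.column_stack([fit.semi_major * np.cos(t), fit.semi_minor * np.sin(t)]) @ R.T
    return pts + np.asarray(fit.center)


def render_overlay(
    image: ScanImage,
    peri: Contour | None = None,
    endo: Contour | None = None,
    mask: CorticalMask | None = None,
    result: ShapeResult | None = None,
    circle: CircleFit | None = None,
    ellipse: EllipseFit | None = None,
    spec: RenderSpec | None = None,
) -> str:
    """Write the QC overlay PNG and return its path."""
    spec = spec or RenderSpec()
    v = image.voxel_size
    up = spec.upscale
    for contour in (peri, endo):
        if contour is not None:
            pts = contour.points
            w_mm = image.geometry.width * v
            h_mm = image.geometry.height * v
            if pts[:, 0].max() > w_mm or pts[:, 1].max() > h_mm or pts.min() < 0:
                raise PQCTShapeError(
                    "contour coordinates fall outside the image geometry"
                )
    vals = image.values.astype(float)
    hi = max(vals.max(), 1.0)
    base = (vals / hi * 255.0).astype(np.uint8)
    img = Image.fromarray(base, mode="L").convert("RGB")
    img = img.resize((image.geometry.width * up, image.geometry.height * up), Image.NEAREST)

    if "mask" in spec.layers and mask is not None:
        tint = np.zeros((*mask.pixels.shape, 3), dtype=np.uint8)
        tint[mask.pixels] = _COLORS["mask"]
        tint_img = Image.fromarray(tint).resize(img.size, Image.NEAREST)
        img = Image.blend(img, Image.composite(tint_img, img, tint_img.convert("L")), 0.5)

    draw = ImageDraw.Draw(img)

    def _poly(points, color):
        px = _mm_to_px(points, v, up)
        draw.line(px + [px[0]], fill=color, width=max(1, up // 2))

    if "periosteal" in spec.layers and peri is not None:
        _poly(peri.points, _COLORS["periosteal"])
    if "endosteal" in spec.layers and endo is not None:
        _poly(endo.points, _COLORS["endosteal"])
    if result is not None and "max_axis" in spec.layers:
        px = _mm_to_px(result.max_axis_endpoints, v, up)
        draw.line(px, fill=_COLORS["max_axis"], width=max(1, up // 2))
    if result is not None and "min_axis" in spec.layers:
        a, b = np.asarray(result.max_axis_endpoints, dtype=float)
        u = b - a
        u /= np.linalg.norm(u)
        perp = np.array([-u[1], u[0]])
        c = np.asarray(result.centroid)
        half = result.min_diameter / 2.0
        px = _mm_to_px(np.array([c - half * perp, c + half * perp]), v, up)
        draw.line(px, fill=_COLORS["min_axis"], width=max(1, up // 2))
    if "fitted_circle" in spec.layers and circle is not None:
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.asarray(circle.center) + circle.radius * np.column_stack(
            [np.cos(t), np.sin(t)]
        )
        _poly(pts, _COLORS["fitted_circle"])
    if "fitted_ellipse" in spec.layers and ellipse is not None:
        _poly(_ellipse_points(ellipse), _COLORS["fitted_ellipse"])
    if "centroid" in spec.layers and result is not None:
        (cx, cy) = _mm_to_px(np.array([result.centroid]), v, up)[0]
        arm = 2 * up
        draw.line([(cx - arm, cy), (cx + arm, cy)], fill=_COLORS["centroid"], width=1)
        draw.line([(cx, cy - arm), (cx, cy + arm)], fill=_COLORS["centroid"], width=1)

    img.save(spec.out, format="PNG")
    return os.fspath(spec.out)


__all__ = ["RenderSpec", "render_overlay", "ALL_LAYERS"]
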