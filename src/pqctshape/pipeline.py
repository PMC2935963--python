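"""End-to-end per-scan analysis: segmentation -> shape record -> ring model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis_models, conic_fit, shape_metrics
from .io import AnalysisConfig, ScanImage
from .segmentation import Contour, CorticalMask, segment_cortex


@dataclass
class ScanAnalysis:
    """Everything produced by one scan analysis."""

    mask: CorticalMask
    periosteal: Contour
    endosteal: Contour
    result: shape_metrics.ShapeResult
    circle: conic_fit.CircleFit
    ellipse: conic_fit.EllipseFit
    ring: analysis_models.RingEstimate

    def to_row(self) -> dict:
        """Flat record: shape metrics, conic fits, ring-model estimates."""
        row = self.result.to_dict()
        row.update(
            circle_center_x_mm=self.circle.center[0],
            circle_center_y_mm=self.circle.center[1],
            circle_radius_mm=self.circle.radius,
            ellipse_center_x_mm=self.ellipse.center[0],
            ellipse_center_y_mm=self.ellipse.center[1],
            ellipse_semi_major_mm=self.ellipse.semi_major,
            ellipse_semi_minor_mm=self.ellipse.semi_minor,
            ellipse_orientation_deg=self.ellipse.orientation,
            err_circle_geom_mm2=conic_fit.average_error_circle(
                self.periosteal.points, self.circle
            ),
            err_circle_alg=float(
                np.mean(
                    conic_fit.conic_residuals(
                        self.periosteal.points, _circle_as_conic(self.circle)
                    )
                    ** 2
                )
            ),
            err_ellipse_alg=conic_fit.average_error_ellipse(
                self.periosteal.points, self.ellipse, kind="algebraic"
            ),
            err_ellipse_geom_mm2=conic_fit.average_error_ellipse(
                self.periosteal.points, self.ellipse, kind="geometric"
            ),
            peri_circ_ring_mm=self.ring.peri_circ_ring,
            endo_circ_ring_mm=self.ring.endo_circ_ring,
            mean_thickness_ring_mm=self.ring.mean_thickness_ring,
        )
        return row


def _circle_as_conic(fit: conic_fit.CircleFit) -> tuple:
    """The circle as a conic normalized to 4ac - b^2 = 1 (a = c = 1/2)."""
    cx, cy = fit.center
    return (0.5, 0.0, 0.5, -cx, -cy, 0.5 * (cx * cx + cy * cy - fit.radius**2))


def analyze_image(
    image: ScanImage,
    config: AnalysisConfig | None = None,
    seed: tuple[int, int] | None = None,
) -> ScanAnalysis:
    """Run the full pipeline on one scan image."""
    if config is None:
        g = image.geometry
        config = AnalysisConfig(
            voxel_size=g.voxel_size, width=g.width, height=g.height
        )
    mask, peri, endo = segment_cortex(image, config, seed=seed)
    result = shape_metrics.summarize(mask, peri, endo, fit_conics=True)
    circle = conic_fit.fit_circle(peri.points)
    ellipse = conic_fit.fit_ellipse(peri.points)
    ring = analysis_models.circular_estimates(result.tot_csa, result.cort_csa)
    return ScanAnalysis(
        mask=mask,
        periosteal=peri,
        endosteal=endo,
        result=result,
        circle=circle,
        ellipse=ellipse,
        ring=ring,
    )


__all__ = ["ScanAnalysis", "analyze_image"]
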