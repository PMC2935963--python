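"""Comparison quantities computed outside the shape pipeline.

Two reference computations frame the shape-software outputs:

* :func:`total_csa` — total cross-sectional area straight from a raw image
  by pixel counting, the way generic image-moment tools compute CSA;
* :func:`circular_estimates` — the manufacturer-style *circular ring
  model*, which assumes the section is a circular annulus and derives
  circumferences and thickness from the two areas alone. It is exact
  exactly when the bone really is circular; for an irregular section it
  understates the periosteal circumference (the circle has the least
  perimeter for a given area), which is the qualitative discrepancy the
  shape-sensitive measurements expose.

The ring-model equations are a reconstruction from the equal-area-radius
definition (the vendor does not publish the formulas):
``R = sqrt(tot/pi)``, ``r = sqrt((tot - cort)/pi)``, circumferences
``2 pi R`` / ``2 pi r``, mean thickness ``R - r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import PQCTShapeError, SeedNotOnBoneError
from .io import ScanImage
from .segmentation import binarize, flood_select

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class TotalArea:
    """Pixel-count areas of one section, mm^2."""

    cortical: float  # above-threshold pixels inside the filled outer boundary
    filled: float  # everything inside the outer boundary, cavity included

    def __post_init__(self):
        if not (self.filled >= self.cortical > 0):
            raise PQCTShapeError("area invariant violated (filled >= cortical > 0)")


@dataclass
class RingEstimate:
    """Circular-ring-model geometry estimates."""

    peri_circ_ring: float
    endo_circ_ring: float
    mean_thickness_ring: float

    def __post_init__(self):
        if not (self.peri_circ_ring > self.endo_circ_ring >= 0):
            raise PQCTShapeError("ring circumference invariant violated")
        if not self.mean_thickness_ring > 0:
            raise PQCTShapeError("ring thickness must be positive")


def total_csa(
    image: ScanImage, threshold: float, seed: tuple[int, int] | None = None
) -> TotalArea:
    """Total CSA of the bone under the seed (largest component if none).

    ``cortical`` counts above-threshold pixels of the selected component;
    ``filled`` additionally includes the enclosed cavity (filled outer
    boundary). Both are pixel counts times v^2.
    """
    binary = binarize(image, threshold)
    if not binary.any():
        raise SeedNotOnBoneError("no pixels above threshold in the image")
    if seed is not None:
        comp = flood_select(binary, seed)
    else:
        labels, n = ndi.label(binary, structure=_STRUCT_8)
        sizes = ndi.sum_labels(binary, labels, range(1, n + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
    filled = ndi.binary_fill_holes(comp)
    v2 = image.voxel_size**2
    return TotalArea(cortical=float(comp.sum()) * v2, filled=float(filled.sum()) * v2)


def circular_estimates(tot_csa_filled: float, cort_csa: float) -> RingEstimate:
    """Circular ring model from total (filled) and cortical areas."""
    if not (tot_csa_filled > cort_csa > 0):
        raise PQCTShapeError(
            f"ring model requires tot_csa_filled > cort_csa > 0, got "
            f"{tot_csa_filled} and {cort_csa}"
        )
    R = np.sqrt(tot_csa_filled / np.pi)
    r = np.sqrt((tot_csa_filled - cort_csa) / np.pi)
    return RingEstimate(
        peri_circ_ring=float(2 * np.pi * R),
        endo_circ_ring=float(2 * np.pi * r),
        mean_thickness_ring=float(R - r),
    )


__all__ = ["TotalArea", "RingEstimate", "total_csa", "circular_estimates"]
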