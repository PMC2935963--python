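# Methods

## Problem and pipeline

A mid-shaft pQCT slice of a long bone shows a dense cortical ring around a
low-attenuation medullary cavity. Manufacturer geometry software commonly
summarizes such a slice with a *circular ring model* — it assumes the
section is a circular annulus — which is blind to the pronounced
triangularity of the tibia. `pqctshape` quantifies the actual
cross-sectional shape from the raw exported image:

1. **Binarize** at an attenuation threshold (default 450 scanner units;
   the supported band is 200–1000, overridable).
2. **Seeded flood fill** keeps the 8-connected above-threshold component
   under the seed (the reproducible stand-in for the operator's crosshair:
   either explicit `(row, col)` or the brightest pixel of the largest
   component).
3. **Morphological opening** (3×3 cross, default 1 iteration each of
   erosion and dilation) strips salt noise; the seed component is then
   re-selected so split-off fragments stay removed.
4. **Boundary tracing** extracts the periosteal contour (Moore-neighbor
   tracing of the filled component, Jacob's stopping criterion) and the
   endosteal contour (trace of the largest enclosed background hole,
   4-connected). Foreground 8- / background 4-connectivity is the standard
   digital-topology pairing that keeps both the ring and its cavity from
   leaking through diagonal gaps.
5. **Shape metrics** and **conic fits** (below) produce the per-scan
   record; the ring model computed from the same areas provides the
   manufacturer-style comparison values.

Contours are polygons through *pixel centers* (pixel `(r, c)` center at
`((c+0.5)v, (r+0.5)v)` mm, y increasing downward). A marching-squares
subpixel contour is available behind `--subpixel` for sensitivity
analysis, but the pixel-center chain is the reference definition because
it makes the perimeter an unambiguous chain-code length.

## Shape metrics

* **Max diameter** — maximum Feret diameter of the periosteal contour
  (largest point-pair distance; computed on the convex hull, which attains
  the same maximum as the all-pairs scan). Ties break to the endpoint with
  the smallest (y, x).
* **Min diameter** — the projection width perpendicular to the
  maximum-diameter axis. A chord through the centroid is offered behind a
  flag, but the projection width is the default because a chord can exit
  and re-enter a concave tibial section.
* **Axis angle** — unsigned angle of the maximum diameter from the image
  vertical, folded into [0, 180)°. Computed, reported on request, excluded
  from the default report.
* **Circumferences** — closed polygon length of each traced contour.
  The chain-code perimeter of a smooth shape carries a *positive,
  resolution-independent* bias (≈ +5 % for a circle, ≤ +8 % generally),
  because axial/diagonal steps overestimate oblique arc length. We report
  the raw digital perimeter and document the bias rather than applying a
  shape-dependent correction.
* **Cortical thickness** — for each periosteal vertex, the shortest
  point-to-segment distance to the endosteal polygon (direction fixed
  periosteal → endosteal); min/max/mean summarize the profile. Anterior
  and posterior thickness are measured where the maximum-diameter line
  through the centroid crosses the two boundaries; anterior is the side
  toward the image top (standard patient positioning; configurable).
  Left/right analogues along the perpendicular axis are computed but left
  out of the default report.
* **Areas** — `tot_csa` (filled section) and `cort_csa` (ring only) are
  pixel counts × v², the convention of standard image-moment tools and
  unbiased for smooth shapes. The shoelace areas of the two pixel-center
  polygons are also emitted (`*_polygon`); they are systematically smaller
  by ≈ perimeter·v/2 because the boundary polygon sits half a pixel inside
  the digital region.
* **Centroid** — unweighted mean of cortical pixel centers; a
  density-weighted variant accepts the attenuation grid as weights.

## Conic fits and deviation indices

The deviation of the section from an ideal circle/ellipse uses two fits:

* **Circle** — algebraic least squares (Kåsa): minimize
  `Σ (x² + y² + Dx + Ey + F)²`, a linear problem, exact on perfect
  circles. The circle error is the mean squared radial deviation
  `mean((‖p − c‖ − R)²)` in mm².
* **Ellipse** — direct least-squares conic fit with the
  ellipse-specificity constraint `4ac − b² = 1`, solved in the stabilized
  scatter-matrix-partitioned form to avoid the classical generalized
  eigenproblem's singular-matrix failures. Data are centered/scaled first
  and the conic mapped back, so noiseless inputs are recovered to
  ≲ 1e-6 mm. The default ellipse error is the mean squared *algebraic*
  residual under the `4ac − b² = 1` normalization; the Sampson
  (geometric, mm²) variant is also emitted.

The mixed convention — geometric for the circle, algebraic for the
ellipse — is deliberate: it is the only reading under which the two
deviation indices of an irregular section can differ by orders of
magnitude in the directions observed in practice (an ellipse fits any
section at least as well as a circle geometrically). Both conventions are
written to the output row for each conic, so either can be reproduced.

Both error metrics are invariant under rigid motion, and fits are
equivariant (tested).

## Circular ring model

`R = √(tot/π)`, `r = √((tot − cort)/π)`, circumferences `2πR`, `2πr`,
mean thickness `R − r`. This is a reconstruction from the equal-area-radius
definition — the vendor does not publish formulas. It is exact for a true
circular annulus; for any non-circular section the isoperimetric
inequality makes the ring periosteal circumference an underestimate of the
traced one, which is the qualitative discrepancy the shape-sensitive
values expose.

## Sympercent cohort statistics

Outcomes are log-transformed and regressed (OLS, statsmodels) on a 0/1
group indicator plus optional covariates (default age, height, weight);
100 × the group coefficient is the sympercent difference, with 100 × its
standard error and the two-sided t-test p value. Sympercents are exact for
constant ratios (`sympercent(A, cA) = 100 ln c`), symmetric, and invariant
to measurement units. Significance stars at 0.05/0.01/0.001; no
multiple-testing correction is applied (matching common practice for
descriptive cohort tables; documented, not configurable). Descriptive
medians/IQRs use the lower-interpolation percentile convention.
Method-agreement summaries are Pearson r plus an OLS y-on-x line with
standard errors.

## Synthetic phantoms and what they do (not) show

The phantom generator produces the study conditions every test runs
under: a 283×283, 0.5 mm-voxel, 16-bit image of a cortical ring at
attenuation 800 on background 60 (threshold 450 sits between with ≥ 6 σ
margin at the default noise levels). Shapes: circular annulus (default
R = 13 mm, r = 9 mm — a young-adult mid-shaft tibia scale), eccentric
annulus (offset cavity), elliptical annulus, and a tibia-like rounded
triangle `r(t) = R0(1 + 0.10 cos 3t + 0.02 cos 2t)` with a constant-depth
wall, sized so max diameter ≈ 26–28 mm and mean thickness ≈ 4–5 mm.
Optional endosteal trabeculization speckle (seeded pixel speckle in a
1 mm band inside the endosteal surface), Gaussian noise, and a
movement-artifact streak (a 3-px cortical-valued chord through the cavity
that splits the enclosed hole and trips the topology rules). All
randomness hangs off one integer seed.

Ground truth is closed-form where possible (circle circumferences/areas,
ellipse axes/areas, Ramanujan's ellipse-perimeter approximation) and
otherwise computed from 10,000-point analytic boundary polylines
(thickness maps of non-concentric shapes, all tibia-like quantities).
Directional truth uses the maximum-diameter axis of the generating
boundary; for circles, where every diameter ties, the image vertical is
the convention.

Phantoms are binary-valued with analytic boundaries; they do not emulate
partial-volume blur, beam hardening, reconstruction kernels, or real
trabecular texture. Passing recovery tests therefore demonstrates
geometric correctness of the measurement chain at scanner resolution, not
robustness to scanner physics.

## Numerical choices and degenerate inputs

* Resolution-convergence checks aggregate the mean relative error of the
  convergent quantities (diameters, areas, mean thickness) over voxel
  sizes 1.0/0.5/0.25 mm on a 36 mm field; the digital circumferences are
  excluded because their chain-code bias does not vanish with resolution
  (they are bounded separately at +10 %/−0 %).
* Line–polygon intersections use inclusive edge-parameter bounds with a
  1e-9 tolerance so an axis passing exactly through a contour vertex is
  not lost to rounding; duplicated crossings are harmless because only
  extreme intersections are used.
* The perpendicular projection width is clamped at the max diameter
  (mathematically it cannot exceed it; float rounding can spill by an
  ulp).
* Failure-loud policy: seed on background, cortex eroded away, open
  cortical ring, border-touching component, axis missing the cortex and
  degenerate conic scatters each raise a named error with the pipeline
  stage attached; several comparably sized enclosed holes raise a
  topology warning, which the CLI escalates to a failing exit code.
* Byte order of raw exports defaults to little-endian (PC-hosted
  scanners) and is configurable. The nominal "2.02 pixels per mm" of some
  export headers is treated as a rounding of the 0.5 mm voxel; the voxel
  size is the single source of physical scale.

## Problem sizes used by the test and acceptance runs

Default phantoms are full 283×283 images; oracle-equivalence suites use
100 random fixtures per operation at small sizes (≤ 30×30 grids, ≤ 200
point contours); statistics recovery uses the study-scale n = 76 with
fixed seeds; convergence uses three voxel sizes on a 36 mm field. These
sizes make every property testable in seconds while keeping the default
geometry identical to real exports.
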