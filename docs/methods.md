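# Methods

`fibrilcyte` quantifies how endothelial-like cells respond to a 1-D adhesive
cue — a parallel array of soft gelatin fibrils on a stiffer base — and how
that response changes under ROCK inhibition, together with the AFM
nanoindentation analysis that characterizes the substrate mechanics. Because
no public imaging or force data accompany this system, the package pairs
every analysis stage with a ground-truthed synthetic generator, so each
estimator can be validated by round trip against known truth.

## Coordinate and angle conventions

Rasters use the image convention: `x` along columns, `y` along rows with
`y` pointing down; pixel centers sit at `(i + 0.5) * pixel_size`.
Orientations of elongated objects are axial (period 180°), measured from
+x toward +y and wrapped into `(-90°, 90°]`; the wrap maps −90° to +90° so
the interval is half-open. All alignment angles are differences of two
axial angles under the same wrap.

## Synthetic fibril-array images

**Substrate.** `FibrilArraySpec` describes stripes of width `fibril_width`
at pitch `spacing` along `axis_angle`. Defaults follow the fabricated
arrays this package models: 40 µm pitch, 5 µm stripes, 0.51 µm/px, 1 mm²
fields. A stripe pattern narrower than one pixel raises a
degenerate-geometry error rather than silently aliasing.

**Cells.** The population model places `Poisson(density × area)` cells
(default 100 cells/mm²). Each cell body is an ellipse of fixed area
π·`base_radius`² (default radius 14 µm, matching the ~615 µm² area of a
28 µm disk) with axis ratio drawn from a clipped normal
(mean 2.0, sd 0.4). The alignment angle of the major axis about the fibril
axis is drawn from a von Mises distribution on the doubled angle with
concentration κ: κ = 0 is the uniform axial law (std 180/√12 ≈ 51.96°),
large κ collapses onto the axis. On a flat substrate the alignment cue is
absent, so orientations are uniform regardless of κ and no centroid
snapping occurs. On the fibril substrate a cell snaps its across-axis
coordinate to the nearest stripe centerline with probability
`on_fibril_fraction` (default 0.8).

**Excluded volume.** Plated cells touch but do not stack. A body whose
placement would leave less than 90% of its pixels visible (the rest hidden
under earlier cells) is re-drawn at a new position, up to 30 attempts,
keeping the best candidate. This yields the touching "cell string"
morphology along fibrils without unphysical pile-ups, and keeps the
generative per-cell orientation a meaningful target for the measurement
round trip. Overlaps that remain are resolved by seniority: later cells
yield their overlapping pixels to earlier labels; label identities are
never merged.

**Protrusions and dose.** Each cell owns two protrusion slots, each filled
with probability 0.7 by a rectangle of width 2 µm extending along the
fibril axis (or the cell's own axis on flat substrate) with an
exponentially distributed length. The mean length follows a saturating
Hill-type map of the inhibitor dose,
`L(dose) = 4 µm + 80 µm · dose / (dose + 2.5 µM)`,
so the steepest growth falls below ~5 µM and single protrusions can reach
beyond 200 µm in the exponential tail at high dose. The distribution
family and the Hill parameters are stand-ins chosen once for plausibility;
no published protrusion-length distribution exists for this system.
Protrusions are painted after all bodies, only over background, so they
run underneath neighboring cells.

**Common random numbers.** All per-cell draws (position, orientation,
elongation, protrusion slots, unit lengths) are independent of dose; the
dose only rescales protrusion lengths. Re-using a seed across a dose sweep
therefore compares the *same* cells at different doses, a deliberate
variance-reduction design: the Solidity dose trend is then essentially
deterministic per field instead of being buried under placement noise.

**Rendering.** The actin channel is the binary cell support, the nucleus
channel one 5 µm disk per cell at its visible centroid, both scaled to
photon counts (200/300 peak, background 10), blurred with a Gaussian PSF
(σ = 0.6 µm), then degraded with Poisson shot noise and Gaussian read
noise (sd 2). All randomness flows through one seeded generator;
fixed seeds give bit-identical rasters. The generator has no 3-D optics,
no uneven illumination, no motility and no intensity texture inside cells;
passing round-trip tests therefore certify the estimators under this noise
model, not performance on real micrographs — flat cell interiors notably
make touching-cell splitting *harder* than textured real data, while the
absence of debris makes thresholding easier.

## Morphometry

Nucleus seeds come from Gaussian smoothing (σ = 1 µm), Otsu thresholding
and connected components, discarding components under 20 µm². Cell bodies
grow from those seeds by a compactness-regularized seeded watershed
(compactness 0.1) on the smoothed inverted actin intensity, restricted to
the Otsu foreground. The compactness term matters: inside a merged blob of
touching cells the rendered intensity is flat, the classical watershed
boundary is then arbitrary, and split fragments acquire spurious
orientations; the regularized flood keeps the partition near-Voronoi with
respect to the seeds (set `compactness=0` for the classical behavior).

Per-region descriptors:

- **Area** A: pixel count × pixel_size².
- **Perimeter** P: marching-squares contour length of the region mask
  (longest contour; interior holes ignored). Contour length behaves better
  than pixel-edge counting, which overestimates smooth boundaries; the
  smoothing-free estimator is deliberately simple and is known to carry a
  small rasterization bias, so the isoperimetric check P² ≥ 4πA is applied
  with 2% slack.
- **Orientation, axes, eccentricity**: from central second moments of
  pixel centers with the 1/12 pixel-variance correction; axis lengths are
  those of the moment-matched ellipse (4√λ). Moment-degenerate regions
  (e.g. single pixels) get orientation 0° and a degeneracy flag.
- **Convex area and Solidity**: hull of pixel centers (Qhull), floored at
  the pixel area so S = A/A_hull stays in (0, 1]. For convex rasterized
  shapes S ≥ 0.98 at ≥ 30 px diameter.

Records with area < 50 µm² carry an artifact flag and border-touching
regions a border flag; both stay in the output table. Scale equivariance
is exact: doubling pixel_size doubles P and quadruples A.

## Cytometry statistics

- **Alignment angle** φ: axial difference between cell orientation and the
  fibril axis, in `(-90°, 90°]`.
- **Orientation Deviation (OD)**: the standard deviation of φ, by default
  about the sample mean (`about_zero=True` switches to the RMS about the
  axis; the two coincide for populations centered on the fibril). The
  random-orientation reference is mean 0° and OD = 180/√12 ≈ 51.96°.
- **Fraction aligned**: share of cells with |φ| ≤ threshold (default 20°).
- **Modal perimeter**: center of the fullest histogram bin (default width
  20 µm, bins anchored at 0, ties to the smaller bin).
- **Solidity indicator**: per-dose mean ± sd of S plus the sign of the
  Spearman correlation of mean S with dose.
- **Perimeter–area envelope**: the P-vs-A scatter of a cell population is
  confined between two through-origin lines; the slopes are
  operationalized as the 2.5% and 97.5% quantiles of the per-cell ratio
  P/A (for disks of radius r, P/A = 2/r, so the upper slope tends to
  2/r_min). Quantiles are configurable; fewer than `min_n` records (10 by
  default) is an error.

Condition summaries exclude border-clipped and artifact-flagged records,
and orientation statistics additionally exclude cells with eccentricity
below 0.6: a near-round cell has no defined major axis, so its measured
orientation is rasterization noise that would inflate OD, and the
exclusion is independent of φ and hence unbiased. All records remain in
the exported tables; the filters act only on the summary statistics.

## AFM force-curve analysis

**Contact model.** A rigid cone of half-angle α on an elastic half-space:
F = (2/π)·tanα·E/(1−ν²)·δ², with δ the sample indentation. The generator
resolves the series compliance exactly — piezo travel past contact splits
into δ plus cantilever deflection F/k_tip by solving the resulting
quadratic — then emits deflection in volts through the photodiode
sensitivity. Defaults: α = 15°, ν = 0.5 (incompressible), k_tip = 2.0 N/m,
sensitivity 28 nm/V. Retraction mirrors approach (purely elastic) unless a
square adhesion well is configured; viscoelasticity and bottom-effect
corrections are out of scope.

**Force conversion.** F = k_tip · (sensitivity · deflection_V), with the
baseline taken as the median force over the first 20% of samples on the
far side and subtracted.

**Contact point.** A breakpoint search fits `F = b` below and
`F = b + a (z − z_c)²` above each candidate breakpoint, solved in closed
form per candidate via suffix power sums (O(n) for the whole scan), taking
the minimum-residual breakpoint with a ≥ 0. Curves whose force excursion
stays within 5 baseline noise standard deviations raise a no-contact
error. Because this onset model under-shoots on stiff samples (their
force–z onset is nearly linear), the full-curve analysis then refines the
contact coordinate continuously by minimizing the residual of the actual
Hertz model, evaluated on a *fixed* sample window chosen once from the
breakpoint — fixing the window prevents the refinement from "improving"
its residual by shedding noisy points. The refinement removes the
half-sample discretization bias; zero-noise round trips recover E to
better than 10⁻³ relative across 10 kPa–10 MPa.

**Modulus fit.** With the contact point known, δ = (z − z_c) − F/k_tip,
and E is the closed-form least-squares solution of F = C·E·δ² over
0 < δ ≤ indent_cap (default 100 nm, the shallow-indentation validity
window of ~10% sample thickness) and F ≥ 0 (adhesion dips excluded).
Retraction segments are fitted by default since only the elastic response
contributes to unloading; approach fitting is available. Fewer than 5
usable samples is an error; a non-positive fitted E clears the validity
flag.

**Sample spring constant.** The deflection-vs-piezo gradient m over the
first 20 nm past contact gives k_s = k_tip·m/(1−m) (series springs). The
forward and inverse maps are exact algebraic inverses; on a Hertzian
(nonlinear) sample the estimate is the effective secant stiffness of the
shallow-contact region, which for a cone vanishes at zero depth — the
linear-contact relation is therefore exercised on linear-spring synthetic
curves.

**Force maps.** Grids of cycles (default 32×32 over 10×10 µm, pitch
≈ 312 nm) spanning a soft fibril stripe (226 kPa) on a stiffer base
(1 MPa). Per-point fits assemble a modulus map; the quantitative fibril
summary uses only the *central* part of the stripe — a binary erosion by 2
grid points (backing off on coarse grids where erosion would empty the
stripe) — discarding edge points where indentation would not be normal to
the surface. The fibril class comes from generator ground truth in
synthetic mode or from Otsu on log E otherwise. More than 20% failed fits
emits a map-quality warning.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's native scales: 1 mm²
fields at 0.51 µm/px (~1961² px, ~100 cells), 10⁶-draw null samples,
400-sample force curves, 32×32 force maps. The orientation-recovery and
dose-trend checks use one field per condition; the pipeline's random-null
statistics pool three flat fields (~280 cells) to tame per-field sampling
error. Ties in the modal-perimeter histogram resolve to the smaller bin;
moment-degenerate orientations resolve to 0°; solidity is clipped into
(0, 1]; envelope quantiles use the linear-interpolation default of
`numpy.quantile`.

## Known limitations

- Segmentation accuracy is validated against this generator's noise
  model; real fluorescence data (texture, uneven illumination, debris,
  out-of-focus light) will degrade it in ways these tests do not measure.
- Perimeter values depend on the contour estimator; exact parity with any
  specific high-content software's perimeter definition is not claimed.
- The Hertz analysis assumes a rigid conical tip, isotropic elastic
  half-space and no adhesion in the fitted window; adhesion hysteresis
  beyond the optional square well, viscoelastic response and
  finite-thickness corrections are not modeled.
- The dose–response morphology map (Hill parameters, exponential
  protrusion lengths) is a plausible stand-in, not a fitted model; only
  qualitative trends (Solidity falls with dose, steepest at low dose)
  should be read from it.
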