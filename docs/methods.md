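# Methods

## The Regenerative Index

A muscle cross-section stained for laminin, embryonic myosin heavy chain
(eMHC) and immunoglobulin G (IgG) yields three per-section counts: total
myofibers (class 1), eMHC⁺ regenerating fibers (class 2) and IgG-infiltrated
necrotic fibers (class 3). The Regenerative Index is

RI = n(eMHC⁺) / n(IgG⁺).

The classes are enumerated independently: a fiber positive for both markers
counts in both class 2 and class 3 (nothing in the class definitions makes
them exclusive; with the default generator settings double-positives do not
occur, but the sensitivity of RI to this convention can be probed via
`frac_double`). Counts may be fractional because replicate sections of the
same biopsy are averaged arithmetically. Three RI regimes are
distinguished explicitly rather than collapsed into numbers:

- `defined` — at least one IgG⁺ fiber; RI is the ratio, reported to one
  decimal with ties rounded away from zero (so 492/48 = 10.25 reports as
  10.3). Unrounded values are always retained alongside.
- `undefined` — no IgG⁺ and no eMHC⁺ fibers (typical of healthy controls):
  the ratio carries no information.
- `infinite` — eMHC⁺ fibers with zero IgG⁺ fibers; flagged, not folded
  into 0 or an arbitrary large value.

### Cohort statistics

Per-sample responses (RI, %eMHC⁺, %IgG⁺) are regressed on age at biopsy by
ordinary least squares; the slope test and R² = 1 − SSE/SST use n−2 degrees
of freedom. Controls are excluded from age regressions — age trends are a
within-disease question and control RI is usually undefined. Group
comparisons (7–8 vs 9–11 years; the boundary puts age 8 in the younger
group) use Welch's unpaired two-tailed t-test with Satterthwaite degrees of
freedom, since between-sample variances differ strongly. When reproducing a
published cohort table the regression is run on the reported one-decimal RI
column (this is what a reader of the table can verify); on fresh data the
unrounded ratios are used (`use_rounded_ri=False`). No multiple-testing
correction is applied. With a single sample, regressions and comparisons
are reported as not-computable rather than raising.

## Segmentation

The laminin channel is thresholded (two-class Otsu by default — the
operator-set thresholds of interactive microscope software are not
publishable, and an automatic default keeps runs reproducible; a fixed
value remains available), morphologically closed with a disk of
`closing_radius` (default 1 µm) to seal staining gaps, and inverted. The
8-connected components of the complement are the fiber interiors
(4-connectivity fragments diagonal necks), so every mask is disjoint from
thresholded laminin pixels — the trace lies strictly within the boundary.

Interiors that the closing step merged are re-split by watershed on the
Euclidean distance transform (EDT). Markers are the connected components
of the EDT's upper dome (pixels deeper than 60% of the region's maximal
depth): a genuine merged pair has two deep lobes separated by a shallow
neck, while a single convex-ish fiber has one connected dome. A split that
produces a fragment shallower than half the region depth is rejected as a
tip artefact. Marking literal EDT maxima instead would be fragile — a
discrete EDT plateau can be disconnected even inside a convex region.

Regions smaller than `min_fiber_area` (default 50 µm²) are removed. Fibers
touching the image border are dropped by default because their area and
Feret diameter are truncated; `border_policy="keep"` retains them.
Coordinates are row-major (y, x), 0-based, pixel centers at integers.

The manual corrections of the semi-automated workflow are modelled as
explicit `merge`/`split` edit actions on the label map, JSON-serialisable
so an edit session is logged and replayable instead of silent.

## Morphometry

- **CSA** = pixel count × pixel_size².
- **Minimal Feret diameter**: the convex hull is built on the *corner*
  points of mask pixels (centers would bias widths half a pixel small); the
  minimal width of a convex polygon is attained with a tangent flush
  against a hull edge, so rotating calipers reduces to minimising, over
  edges, the farthest vertex distance from the edge's line. A dense
  0.05°-grid caliper sweep serves as the independent oracle in tests
  (agreement within 0.5 px on random convex polygons). A single-pixel mask
  has width 1 px by convention.
- **Perimeter**: 4-direction Crofton estimator by default (low
  rasterisation bias on irregular shapes); an exact-polygon mode (convex
  hull perimeter) is provided for closed-form checks on convex shapes —
  no digital estimator reproduces the ideal perimeter of both squares and
  disks simultaneously.
- **Circularity** = 4π·area/perimeter², clamped to ≤ 1 because discretised
  perimeters can push it slightly above 1. It is computed on the mask, not
  its convex hull.

## Marker classification

Each fiber's mask is eroded inward by `interior_erosion` (default 1 µm,
realised through the distance transform) so laminin-adjacent bleed-through
does not contaminate the interior mean; a fiber that erosion would
annihilate falls back to its full mask with a warning. Positivity is
`mean > threshold`. The automatic threshold is a two-class Otsu split of
the per-fiber mean distribution with a separation guard: the upper class
must exceed the lower by at least three pooled standard deviations *and*
half the lower mean, otherwise no positive class is declared. Otsu alone
always produces a split, so without the guard a channel containing no
positive population (controls, secondary-only stains) would generate
spurious calls.

Nuclei are detected in DAPI by Otsu threshold plus watershed seeded at
local maxima of the smoothed distance transform (`peak_min_distance` 3 µm,
minimum area 4 µm²); touching nuclei with distinct depth maxima separate.
Per-nucleus Pax7 means are thresholded the same way. The visual-inspection
step that removes false positives in high-background regions is modelled as
an explicit polygon blacklist applied before counting (auditably, in the
output table, rather than as silent edits). The satellite-cell burden is
reported as Pax7⁺ nuclei per segmented fiber.

## Synthetic sections

The generator emulates a transverse DMD biopsy section:

- **Geometry** — a Laguerre (power-diagram) tessellation of the tissue
  region: seeds with weights from a lognormal target-area distribution
  (default mean exp(µ)=1000 µm², σ_log = 0.45, the wide size variability of
  dystrophic muscle). Power cells are convex, matching real fiber
  cross-sections. Lloyd relaxation (default 3 iterations) is the single
  knob for shape regularity — more iterations give rounder, more uniform
  fibers (verified as a monotone circularity effect in tests). Per-seed
  weights are adapted each iteration toward the target areas; seeds that a
  power diagram would hide are relocated deterministically. A boundary
  band of `boundary_thickness` (default 2 µm) is carved between cells as
  the laminin network; a margin of exterior background surrounds the
  tissue, so no ground-truth fiber touches the image border.
- **States** — per-fiber (eMHC, IgG) status is a categorical draw honouring
  `frac_emhc`, `frac_igg`, `frac_double` (default 0). Nuclei per fiber are
  Poisson (mean 1.5); each is internal with probability
  `frac_internal_nuclei` (default 0.3, the dystrophic hallmark), otherwise
  sub-laminal (within 2 µm of the boundary); Pax7⁺ status (satellite cells,
  default 15%) is assigned only to sub-laminal nuclei, reflecting their
  anatomical position between sarcolemma and basal lamina.
- **Rendering** — uniform tissue background 1.0; signal at `snr` × background
  (laminin on the boundary band, markers on positive interiors, Gaussian
  spots of σ = 2.5 µm for nuclei), light Gaussian blur, additive Gaussian
  noise of `noise_sd`, clipped at 0. Identical parameters give bit-identical
  output.

What the phantom deliberately does **not** model: Poisson shot noise,
autofluorescence structure, fibrosis, inflammatory infiltrate, fat
replacement, staining gradients, or out-of-focus blur. Passing recovery
tests on phantoms therefore demonstrates the correctness of the
algorithms under controlled degradation, not segmentation performance on
real sections, where boundary quality is the dominant difficulty and
operator review remains necessary.

Cohort simulation ties the generator to the ageing model: at age *a*,
`frac_igg` is held at `base_igg_frac` and
`frac_emhc = base_igg_frac · (ri_intercept + ri_slope·a)`, so the expected
truth-level RI is linear in age. Ages where the expected RI would be ≤ 0
are rejected. A truth-level variant (`simulate_truth_cohort`) draws only
the per-fiber states, so replicate studies (e.g. slope-coverage
simulations with 100 replicates) do not pay for image rendering.

## Problem sizes and numerical choices

Recovery tests run at pixel size 1 µm/px (the default for fresh phantoms
is 0.5 µm/px; no acquisition scale is canonical, and both are
configurable): 200-fiber noiseless sections for segmentation recovery,
twenty 500-fiber sections at signal-to-background 5 for classification
recovery, 100 truth-level cohorts of four samples × 2000 fibers for slope
coverage, and one rendered cohort of eight samples × 1500 fibers (about
the per-section fiber count of real biopsies) at signal-to-background 8
for end-to-end slope recovery. Ages 7–10 are used for the simulated
cohorts: with the reference decline RI = 22 − 2·age, age 11 would imply an
expected RI of zero, which the cohort model rejects.

Ties and degeneracies: RI reporting rounds half away from zero; Otsu on
per-fiber means uses up to 256 bins; watershed ties follow scikit-image's
deterministic flooding order; all randomness flows from a single integer
seed through `numpy.random.default_rng`, and cohort children draw child
seeds below 2³¹.

## Known limitations

- Real laminin staining has gaps, folds and intensity gradients that the
  phantom's clean network does not reproduce; the automatic trace on real
  data will need the edit operations and possibly fixed thresholds.
- The marker-positivity model is a hard threshold on the interior mean;
  partial or gradient staining (e.g. fibers at the start of necrosis) is
  not modelled.
- RI comparisons against healthy controls are intrinsically fragile: with
  no damage, the RI is undefined or rests on a handful of fibers. The
  statistics here follow the within-disease design (regression over DMD
  samples; controls only in descriptive tables).
- Morphometrics are 2-D, per-section quantities; oblique sectioning biases
  CSA and circularity (the minimal Feret diameter is used precisely
  because it is the most robust of the three).
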