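# Methods

## Scope and model

`vesselmetrics` quantifies large/medium retinal vessels on en-face OCTA
artery/vein segmentation maps of 3×3 mm macular scans and compares the
resulting metrics across subject groups. The pipeline consumes the *output*
of a vessel segmentation model — a four-class raster (background, artery,
vein, arteriovenous junction) — and deliberately implements no segmentation
itself; any model's output can enter at the manifest boundary. Because the
patient images the design was built around are not publicly available, a
phantom generator with analytically known geometry serves as the data source
for every test and calibration.

## Zones

The field is partitioned around the foveal center (default: geometric image
center, configurable) into:

- **fovea** — disk of radius 0.5 mm (pixel-center distance < 0.5 mm);
- **parafovea** — annulus 0.5–1.5 mm, split into four equal 90° sectors:
  superior, inferior, nasal, temporal;
- **outside** — beyond 1.5 mm.

Coordinate and boundary conventions (the source design leaves these open, so
they are fixed here and used consistently everywhere):

- image row 0 is the superior edge; the mm origin is the field center; x
  grows to the image right, y upward;
- the nasal quadrant faces the optic disc: image-right for OS, image-left
  for OD;
- quadrant boundaries are the diagonals (sectors centered on up/right/down/
  left, matching the common device display); a pixel exactly on a diagonal
  goes to the clockwise sector, deterministically. An axis-split convention
  would be an equally defensible reading of "four equal quadrants"; the
  diagonal split is the default because it is what macular-grid displays use;
- radial bands are half-open (`r_fovea ≤ d < r_outer`), so zones are
  disjoint and cover the field exactly.

## Metrics

Per zone and vessel class (artery, vein, all — junction pixels count only in
"all", to avoid double counting a pixel in two classes):

- **VD** = vessel pixels / zone pixels;
- **VDI** = vessel pixels / skeleton pixels (mean caliber; px and µm, with
  µm = px × pitch × 1000 exactly);
- **VLF** = skeleton pixels / zone pixels. *Naming note:* in some write-ups
  the formula ΣS/N is printed under the label "VDI"; that formula is the
  length fraction and is implemented here as VLF, matching its prose
  description;
- **FD** — box-counting dimension of the skeleton: boxes of side 2, 4, 8, …
  up to min(image)/4, grid anchored at the occupied bounding box, −slope of
  the OLS fit of log N(ε) against log ε over scales with N(ε) ≥ 2. A
  digitized straight line measures 1.0 and a filled square 2.0 (both exact
  on these fixtures). The per-zone FD clips the skeleton to the zone; an
  image-wide FD is also emitted (`zone == "image"`).

Track metrics are computed on ordered centerline paths (see below), in pixel
units, and averaged per zone × class (unweighted by default, length-weighted
optionally):

- **LC** — polyline arc length; **LX** — endpoint chord length;
- **MDAC** — mean angle between the unit chord vectors taken `step` points
  back and forward of each interior point (arccos of the clamped dot
  product). `step = 5` px by default: at ~10 µm/px this spans ~50 µm, small
  enough to stay local and large enough to suppress pixel-chain direction
  noise;
- **TSC** = Σ C(t)² Δs (trapezoid over cumulative arc length — the printed
  definition is an integral in t with no measure stated, and the arc-length
  measure makes TSC invariant to sampling density); **TSC-LX** = TSC/LX
  (undefined for closed tracks, LX = 0); **TSC-LC** = TSC/LC.

Curvature C(t) = (x′y″ − y′x″)/(x′² + y′²)^{3/2} is estimated by smoothing
the coordinate sequences with a Gaussian (σ = 2 samples by default — raw
8-connected pixel chains alias curvature badly) and differentiating with
central differences. The sequences are first extended by quadratic
extrapolation over 3σ samples so the smoother does not flatten the curve at
its ends; without this, squared-curvature integrals are biased low by
several percent on short tracks. On exactly sampled semicircles
(r = 25–101 px) TSC-LC recovers 1/r² within 2% and MDAC recovers the
rotation rate step·Δs/r within 0.1%.

Undefined quantities (empty zone, no skeleton in zone, closed chord)
propagate as NaN — never as zeros — and are dropped pairwise in the
statistics.

## Skeletons and tracks

Masks are thinned with topology-preserving skeletonization (Zhang–Suen via
scikit-image; medial axis selectable). The skeleton is decomposed with
8-connectivity into nodes (pixels with ≠ 2 skeleton neighbors) and edges
(simple paths between nodes); each edge is one track. Pure cycles are cut at
their lexicographically smallest pixel and flagged as loops, for which
chord-normalized tortuosity is undefined. Tracks shorter than
2·mdac_step + 1 points (the minimum for a non-empty MDAC sum) are excluded
from tortuosity aggregation; their pixels still count in skeleton-based
metrics (VLF, FD, VDI), which use the raster. Tortuosity is computed
per-edge; tracks are attributed to a vessel class by majority artery/vein
label under the path (junction pixels neutral, ties to artery) and to a zone
by majority pixel membership (ties to the first point's zone).

## Statistics protocol

Per metric × zone × class cell across groups: each group is tested for
normality with a Kolmogorov–Smirnov test — Lilliefors-corrected by default,
since the null's mean/SD are estimated from the sample; the plain K-S with
plugged-in estimates is available as a config option because statistics
packages differ here. If all groups pass at α = 0.05, a one-way ANOVA is run
and a mean-centered Levene test gates the post hoc: Fisher's LSD (pairwise t
on the pooled MSW, df = N − k, unadjusted) under homogeneous variances,
Tamhane's T2 (pairwise Welch t, Šidák-adjusted) otherwise. If any group
fails normality, Kruskal–Wallis replaces the ANOVA and no LSD/Tamhane post
hoc is emitted (those post hocs presuppose the ANOVA framework). All
p-values are two-tailed; cells are flagged at α = 0.05; no multiple-testing
correction is applied by default (raw p-values are reported, as clinical
OCTA studies typically do), with Benjamini–Hochberg available. Eyes are
treated as independent observations — the fidelity-first choice matching how
such studies count both eyes — and that limitation is stated below.

ANOVA is also available from per-group (n, mean, SD) summaries
(SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)SDᵢ²), which is what lets the package
recompute published baseline-table p-values without raw data. Contingency
tables use Pearson χ² without continuity correction. The demographic worked
examples use person counts for age/sex/duration and eye counts for
laterality — the convention under which the published percentages
reconstruct exactly; the duration comparison is the two-group pooled test
(identical to two-group ANOVA from summaries).

## Phantom generator

Centerlines are parametric curves — lines, circular arcs, sinusoids, cubic
Béziers — with closed-form (or adaptive-quadrature) arc length, chord
length, curvature, TSC family and MDAC, so every raster-derived value has an
exact reference. Curves are rasterized as ribbons: a pixel is painted when
its center lies within width/2 of the centerline polyline (flat end caps,
round joints), with the polyline sampled at ≥ 2 points per pixel. Artery and
vein ribbons overlap into junction pixels, matching the label convention.

Cohorts emulate the three-arm study design: configurable groups of eyes
(alternating OS/OD) at 304×304 px over 3×3 mm (the en-face grid of the
source volumes; the axial dimension is irrelevant here, and the 304 px
en-face assumption is configurable). Default densities: combined
artery+vein VD 0.18 per parafoveal quadrant (split evenly between classes)
and 0.06 in the fovea — large/medium vessels only, with a sparse center
standing in for the avascular zone; per-eye, per-zone, per-class targets are
jittered by a truncated-normal eye effect (8% relative SD), and short
sinusoidal vessels (length 0.12–0.55 mm, caliber 35–65 µm, amplitude
0.02 mm) are painted until the junction-exclusive density reaches target,
with a second top-up pass compensating overlap erosion and inter-zone spill.
Parafoveal curves are rejected if they would enter the fovea, whose small
area makes spill-in dominate its density otherwise. Effect sizes are
injected as additive density offsets per group × zone × class, or as
sinusoid-amplitude offsets (tortuosity). All randomness flows through one
seeded generator; identical seeds give byte-identical cohorts.

What the phantoms do **not** emulate: capillary-plexus texture, OCTA
speckle/decorrelation noise, vascular branching topology, perfusion
weighting. Passing tests therefore demonstrate correctness of the
*measurement and inference machinery* on known geometry, not robustness to
real segmentation artifacts.

## Calibration problem sizes

Power: 10 full-pipeline replicates of 3 groups × 10 eyes at 152×152 px
(half the default resolution; detection of a density effect does not need
caliber-level resolution, and this keeps the Monte Carlo affordable), with a
3-between-eye-SD deficit injected into one cell; detection rate is reported.
Type-I error: 500 replicates of the gated protocol on null cohorts drawn
from the generator's between-eye sampling model at the metric-table level —
the protocol under calibration is identical whether its input table came
from rasters or from the sampling model, and this permits hundreds of
replicates. The observed false-flag rate sits near the nominal α = 0.05.

## Known limitations

- Artery/vein identity is taken from the input labels; crossings are not
  disentangled, and a track crossing a junction keeps its majority class.
- Tortuosity is computed only on tracks the skeletonizer yields; very short
  or heavily branched segments are excluded, so capillary-scale tortuosity
  is out of reach by construction.
- Inter-eye correlation within subjects is ignored by the default protocol
  (eyes as independent observations); no covariate adjustment is provided.
- The raster path overestimates LC by ~5% (8-connected chain lengths) and
  carries curvature aliasing; raster-derived TSC is usable for group
  contrasts but is not a precision estimate of the underlying integral.
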