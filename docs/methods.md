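# Methods

## Problem and model

Lamellar macular holes are partial-thickness foveal defects.  A subset of
eyes progressively loses foveal tissue between OCT visits; the analysis
this package implements compares those progressive (TL) eyes with stable
(ST) eyes on OCT-angiography microvasculature and visual acuity.  The
pipeline has five measurement stages — binarization, sector geometry,
densities/morphometry, tissue-loss quantification, cohort statistics — and
a synthetic-data generator that stands in for the (unreleased) patient
images and tables.

## Binarization

The en-face image is min-max normalized to [0, 1].  Three operators are
fused:

* **global band** — pixel ≥ 0.7 ("white pixels"; lower bound inclusive);
* **Hessian vesselness** — multiscale Frangi filter, bright-ridge
  polarity, scales {1, 2, 3} px, β = 0.5, response rescaled to [0, 1].
  Scales cover the 1-3 px capillary calibres at 5.7 µm/pixel;
* **adaptive threshold** — pixel exceeds its local mean (15 px window,
  reflective padding) by more than an offset of 0.02.  The sign of the
  offset is chosen so a positive offset suppresses flat regions (a
  constant image maps to nothing): thin vessels rise far above their
  neighbourhood mean, plateaus and background do not.

Fusion rule: `vessel = global ∨ (adaptive ∧ vesselness ≥ 0.05)`.  The OR
preserves large bright vessels; the AND admits faint capillaries only
where local contrast and ridge-likeness agree.  Connected components
smaller than 5 px (4-connectivity) are removed as speckle.  All
parameters live in `BinarizationParams`; an alternative reading in which
the 0.7 band gates the fused map instead is available behind
`band_after_fusion`.

Perfusion: with a repeated-frame stack, the decorrelation
`D = 1 − mean_t [2 f_t f_{t+1} / (f_t² + f_{t+1}²)]` (pairs with no signal
contribute 0; values clipped to [0, 1]) marks moving blood; perfused
vessels are vessel pixels with `D ≥ τ_d = 0.05`.  Without a frame stack PD
is refused rather than silently equated to VD.

## Sector geometry

Foveal disk radius 0.5 mm, parafoveal ring outer radius 1.45 mm, quadrant
boundaries at 45/135/225/315° (the ophthalmic four-sector convention; a
rotation offset is exposed).  Radial intervals are inner-inclusive /
outer-exclusive and angular arcs half-open `(a, a+90]`, which makes the
8-sector partition of the r < 1.45 mm disk exact — conservation is
asserted, not approximated.  The ROI quadrant is located from an explicit
`roi_angle_deg` input; how that angle is derived from B-scan geometry is
upstream of this package.  Pixel assignment uses pixel-center coordinates
`((j+0.5)·pitch, (i+0.5)·pitch)`.

## Morphometry

Areas come from the shoelace formula (via shapely, with simplicity
validation that reports the self-intersection location), perimeters from
summed edge lengths.  Circularity `4πA/P²` is reported at 2 decimals in
tables and unclamped internally; values above `1 + 0.02` (isoperimetric
bound plus discretization allowance) raise a warning.  Mask-derived CFZ
extraction — needed only for synthetic tests, since clinical CFZ borders
are manual polygons — flood-fills non-vessel pixels (4-connectivity),
rejects border-touching components, and traces the boundary by marching
squares at level 0.5 on a σ = 1 px Gaussian-smoothed indicator.  The
smoothing matters: contours of raw binary masks overestimate perimeters
by tens of percent (staircase effect), which would corrupt circularity;
the smoothed contour recovers a rasterized disk's perimeter within 2% for
r ≥ 30 px.

## Tissue loss

Per-section loss is follow-up minus baseline gap area, so loss is
positive (the alternative orientation would make every reported loss
negative); shrinkage is kept algebraically and flagged.  A patient's
quantitative loss sums the 3 largest per-section values (ties at third
place broken by ascending section id; with < 3 sections all are summed),
the TL/ST cutoff is 0.02 mm² inclusive, and speed divides by the exact
interval (days/365.25).  Whether a published median speed was computed
per patient or as a ratio of medians is ambiguous; this package computes
per-patient speeds and summarizes those.  Grader agreement uses ICC(2,1)
(two-way random effects, single measure, absolute agreement) with the
per-item grader mean as the downstream consensus.

## Statistics

Shapiro-Wilk (α = 0.05) gates descriptives (mean/SD vs median/IQR,
quantiles by linear interpolation — IQR values depend on this choice) and
test selection (both samples normal → t, else Mann-Whitney).  The t test
defaults to Welch (unequal variances), switchable.  At 14 eyes per group,
asymptotic nulls are not trustworthy, so:

* Mann-Whitney enumerates all `C(n, n_x)` assignments for n ≤ 20 (average
  ranks handle ties); beyond that a tie-corrected, continuity-corrected
  normal approximation is used;
* the signed-rank null is an exact dynamic program over the positive-rank
  sum for up to 25 nonzero pairs (tied average ranks are doubled to keep
  integer support); zero differences are dropped;
* Spearman p-values are permutation-based: full enumeration for n ≤ 8,
  otherwise 10⁵ seeded Monte-Carlo permutations with the add-one
  correction;
* 2×2 prevalences use Fisher's exact test whenever an expected cell is
  below 5, else χ² with continuity correction.  No correction is applied
  across table rows (raw p-values are reported, as is usual for this kind
  of exploratory cohort table).

Two-sided p-values are `min(1, 2·min(P(T ≤ t), P(T ≥ t)))`; fully tied or
zero-variance inputs return degenerate, flagged reports rather than
errors wherever a cohort table must still be produced.

## Synthetic data

The generator's defaults are the study conditions: 512 px rasters at
5.7 µm/pixel (a 2.918 mm field whose central 2.9 mm grid is analyzed —
the printed field size and pixel pitch are not exactly consistent with a
power-of-two raster, and the grid, not the raster edge, defines the
analysis extent), 14 patients per group, ~2.25-year follow-ups (uniform
on 1.7-2.8 years).

**FAZ polygon.** A unit circle perturbed radially by a seeded sinusoid
(4-7 lobes); the amplitude is solved by Brent's method so the polygon's
`4πA/P²` hits the requested circularity, then the polygon is rescaled to
the requested area (circularity is scale-invariant).  Unreachable
circularities raise.

**Vessel network.** Seeded stochastic branching growth from the image
border toward the fovea (angular jitter, 10% branching per step, 1-3 px
widths), terminating at the FAZ; a 2 px terminal capillary ring hugs the
FAZ border from outside, and the FAZ interior is guaranteed avascular.
Growth proceeds in waves until the vessel pixel fraction reaches its
target (default 0.20); the perfused subset is chosen per path, with the
prefix of a shuffled path order bisected so the realized pixel share
matches `perfused_fraction_of_vessels` (default 0.85).  The network is
calibrated only at pixel level (density, width, FAZ exclusion, perfused
share) — it is not a hemodynamic or morphogenetic model, and real
plexuses differ in topology, so segmentation scores on these phantoms
bound algorithmic correctness, not clinical accuracy.

**Rendering.** Vessels at 0.85, background at 0.15, Gaussian read noise
(default sd 0.01), clipping to [0, 1].  Perfused pixels get per-frame
multiplicative speckle with at least one deep fade (×0.25-0.45) per
6-frame cycle at a random frame, independent extra fades at p = 0.1, and
mild bright speckle (×1.0-1.176) otherwise; non-perfused pixels are
identical across frames.  The guaranteed fade emulates the interference
fading of flowing blood and ensures every perfused pixel decorrelates
above τ_d while the mean frame stays bright on vessels; a purely iid
unimodal speckle cannot satisfy both once intensities clip at 1.

**Cohort.** Mean±SD table entries are simulated as normal, median(IQR)
entries as shifted lognormal (shift = median − 2·IQR; the lognormal part
matched by median and IQR via `IQR/m = 2·sinh(0.6745σ)`), preserving the
right skew that motivates the nonparametric tests.  The printed
parafoveal VD/PD cells are scale-inconsistent with the foveal percentages
(fractions vs percents or a typesetting slip), so the generator uses
plausible parafoveal percentage locations (e.g. SCP parafoveal PD ~31.9
TL vs ~34.3 ST) with the printed spreads; those cells are not reproduced
numerically.  TL-group summed loss is 0.02 mm² + lognormal matched to
median 0.09 / IQR 0.055 mm²; ST-group growth stays below 0.015 mm², so
the 0.02 cutoff classifies both groups correctly by construction.
Six per-section gaps per patient are drawn so the top-3 growth sums to
the patient total exactly.  BCVA decline is a linear function of the
speed of loss (slope 4.5 decimals per mm²/year, noise sd 0.004) and SCP
parafoveal PD a decreasing function of the loss amount (slope −50 pp/mm²,
noise sd 0.15): both links recover Spearman |ρ| > 0.95 without claiming
the published correlation coefficients, which depend on unreleased data.
The ROI quadrant is depressed by 3.2 pp in TL eyes.  Inter-variable
correlations beyond these links are not specified by any source and are
simulated as independent.  Grader noise defaults to 0.020 mm², the
closed-form value `sd_true·√((1−ICC)/ICC)` for a target ICC of 0.86 at
the theoretical TL-area sd (~0.051 mm²); single-cohort ICCs remain
volatile because the area distribution is skewed.

## Problem sizes and determinism

Tests and the demo use the full 512 px raster; segmentation recovery is
scored over 10 seeds, cohort power over 200 simulated cohorts, null
calibration over 2000 replicates, ICC calibration over 100 replicates —
sizes chosen so each check is statistically meaningful while the whole
suite stays fast.  Every stochastic stage takes an explicit seed;
`run_demo` derives stage seeds deterministically from one master seed and
repeated runs are bit-identical.

## Known limitations

* The phantom's vessel topology, speckle statistics and noise are
  idealized; passing recovery tests demonstrates the operators are
  implemented correctly, not that they are robust to device artifacts
  (projection artifacts, motion, defocus are all absent).
* Automatic CFZ extraction exists only for the synthetic pathway;
  clinical use expects manually contoured polygons.
* No multivariate modelling: the analysis is a battery of univariate
  contrasts, matching its small-sample setting.
* Layer segmentation (SCP/DCP slab definition) and device Q scores are
  consumed as given, never computed.
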