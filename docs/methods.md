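# Methods

This note documents the measurement models implemented in `cdqa`, the
choices made where the protocol leaves details open, and what the
synthetic phantom does and does not emulate.

## Acquisition model and preprocessing

All estimators consume 8-bit RGB display exports: duplex Color Doppler
video frames and B-mode stills.  Vendor overlays are removed by an
explicit `RegionLayout` (diagnostic box, color box, colorbar strip, scan
surface row) supplied in the acquisition config; automatic overlay
detection is vendor-specific and deliberately out of scope.  Coordinates
are 0-based, row-major, origin top-left, rectangles half-open — chosen so
every pixel-count contract is unambiguous.

Pixel size is calibrated from the displayed depth of field:
`mm/px = 10·FOV_cm / box_height_px`, assumed isotropic (a config override
exists).  For sector probes this is a mid-field approximation: phantom
targets sit mid-image where the display's scan conversion is closest to
isotropic, but no sector rectification is applied, and blind-angle results
for convex probes inherit the same approximation the protocol itself makes.

Color-coded pixels are isolated by HSV hexcone saturation
`S = (max−min)/max > th_sat` (default **0.35**); gray B-mode content has
`S ≈ 0` while Doppler map colors are nearly fully saturated.  The filter is
applied per frame *before* averaging, so grayscale speckle cannot average
into weak false color at flow boundaries (with the per-channel median
filter this otherwise biases gap widths by 1–2 px).  `N` average images
(default **6**) of `M = n_fr/N` consecutive frames each condense the video
(`n_fr` = 30 phased / 24 convex frames from a 3 s clip).  Color noise is
suppressed by a per-channel k×k median filter (default **k = 4**); even
windows take the lower median (rank (k²−1)//2 via `scipy.ndimage.rank_filter`)
and borders replicate edge pixels — both choices made for determinism.

The RGB content is collapsed to one gray level as the channel RMS,
`I = sqrt((R²+G²+B²)/3)`, which keeps white at 255 so `I` is commensurate
with the blind threshold `th_blind` (default **10**, the smallest
gray-level difference distinguishable by eye).  The protocol's phrasing of
this reduction admits other readings (mean-square, unit-normalized); RMS
is isolated behind `intensity_map` so it can be swapped.

## The five estimators

**Blind angle.**  `F` parallel flow axes (default **3**, spaced
**d = 1 mm**) are placed on the least-squares centerline of the color
region (per-column centroids).  Along each axis the blind-zone width `a`
is the longest run of pixels with `I ≤ th_blind` flanked on *both* sides
by flow; runs touching the color-box border are absence of box, not
absence of signal, and are excluded.  Ties break toward the lateral box
center, where insonation is closest to 90°.  With `h` the depth of the
axis midpoint (not the vessel top — the geometry uses the flow-axis
depth), `α = 2·arctan(a/2h)`; per image the F axes give mean ± SD, and
`BA = mean(α_i)`, `σ_BA = (1/N)·sqrt(Σσ_{α,i}²)`.

**Registration error.**  The B-mode lumen is segmented with an adaptive
brightness threshold `th_b = c_b · mean(V)` over the diagnostic box
(`V` = HSV value).  The proportionality constant is not fixed by the
protocol; the default **c_b = 0.5** separates anechoic lumen from tissue
speckle across the synthetic renderer's contrast range and is exposed in
config.  The largest connected dark component is the lumen; its
per-column extreme rows are fitted by least squares into the two wall
lines.  On each average image, `n_box` counts color-box pixels with
`I > th_blind` and `n_out` those above the upper or below the lower line
(pixels exactly on a line count inside — conservative toward the ideal
RE = 0); `RE% = mean_i(100·n_out,i/n_box,i)` with the across-image SD.

**Velocity parameters.**  The on-screen colorbar is sampled along its
vertical midline; the velocity at each row is linear between the
configured endpoint velocities, and each limb is regressed (velocity
against its dominant color channel) to obtain the calibration residual
σ_cal.  A pixel decodes to the velocity of the nearest colorbar color in
RGB distance; colors farther than a tolerance from any bar entry are
invalid (this also rejects residual gray pixels).  Aliased colors are not
unwrapped — acquisitions are assumed scale-adjusted, and the synthetic
generator refuses aliasing outright.  `K` segments (default **16**)
perpendicular to the flow axis, evenly covering **D = 20 mm** centered at
the axis midpoint, yield velocity profiles; peak (AMVS) or mean (VeMeA)
|velocity| per segment is averaged per image, its SD combined with σ_cal
in quadrature, and images aggregate as for the blind angle.  Theoretical
velocities derive from the phantom: `v̄ = Q/(πr²)` with SD from the device
tolerances (±0.4 mL/s on Q, ±0.2 mm on the diameter), and peak
`= profile_factor · v̄` with **profile_factor = 2.0** (fully developed
laminar flow; configurable because the phantom datasheet relation is not
universal).  `AMVS = Δv_color/Δv_th` and `VeMeA = |v̄_color − v̄_th|/v̄_th`
follow with first-order uncertainty propagation.  VeMeA is defined with an
absolute value: all published reference values are non-negative and the
normalization `1 − VeMeA` presumes it.

Note an intrinsic property of line-profile averaging: for a parabolic
profile the mean along a diameter is 2/3 of the peak, i.e. 4/3 of the
cross-sectional mean `Q/A`, so even a perfect scanner measures
`VeMeA ≈ 1/3` on parabolic flow — consistent in magnitude with the
published survey values (0.05–0.64).  The noise-free recovery test
therefore uses a plug-flow scene, where line mean equals area mean.

**Temporal resolution.**  `TR = (FR_duplex/FR_Bmode)·(A_color/A_tot)`
with pixel areas from the layout; the color-box perimeter (a graphic
overlay) is excluded from `A_color`.  Frame rates are explicit inputs
(config or generator) — reading them from the on-screen text would
require vendor-specific OCR.  TR peaks at 0.5 when the color box covers
the diagnostic area and duplex runs at half the B-mode rate.

## Monte-Carlo uncertainty

Method settings are redrawn per iteration from uniform distributions
declared as mean ± SD — read as a *standard deviation*, so the support
half-width is SD·√3 (the alternative half-width reading is a config
switch, `uniform_param`).  Integer settings are drawn continuously and
rounded half away from zero.  Defaults: th_sat 0.35 ± 0.01, k 4 ± 1 px,
d 1.0 ± 0.3 mm, th_blind 10 ± 1 for the blind angle; th_b ± 6 %, th_sat,
th_blind for RE; th_sat, D 20 ± 1 mm and a ±1 mm first-segment offset for
the velocity parameters; ±1 frame/s on both frame rates and ±3 % on both
areas for TR.  `N` and `M` stay fixed while the frames entering each
average image are re-randomized without repetition.  The SD over
iterations (default **10⁴**) is the method uncertainty and combines with
the repeatability SD by root-sum-square — the standard combination for
independent uncertainty contributions.  Iterations that fail are skipped
and counted; more than 5 % failures abort.

## Normalization and the Kiviat index

Scores: `BA* = 1 − BA/BA_lim` (**BA_lim = 45°**, the assumed worst
plausible blind angle), `RE* = 1 − RE/100`, `AMVS* = 1 − |AMVS−1|`,
`VeMeA* = 1 − VeMeA`, `TR* = sqrt(TR/TR_opt)` (**TR_opt = 0.5**; the
square root stretches the small dynamic range of TR).  SDs propagate to
first order (for TR*: `σ_TR* = σ_TR / (2·sqrt(TR·TR_opt))`).  Scores are
clipped to [0, 1] — values beyond the limits would produce negative radii —
and clipping events are reported; the reference data never clip.

The five scores are radii on axes 72° apart in the fixed order
(BA\*, RE\*, AMVS\*, VeMeA\*, TR\*).  The shoelace area divided by the
all-ones pentagon reduces to `S* = (Σ cyclic r_i·r_{i+1})/5`, with
first-order SD `σ_S*² = Σ((r_{i−1}+r_{i+1})/5)²σ_i²`.  The axis order
matters (S* is invariant under rotation/reflection but not arbitrary
permutation); this order uniquely reproduces the published survey areas.
Scoring the published raw means reproduces 57 of the 60 printed normalized
scores and 10 of the 12 printed areas to two decimals; the remainder
differ by up to 0.016 (scores) / 0.03 (areas) because the survey's own
normalization used unrounded parameter values — the bundled dataset can
only carry the printed, rounded ones.

## Synthetic phantom

The generator renders rectilinear (linear-probe-like) scenes: a
multiplicative-speckle background (gamma-distributed, shape 4), an
anechoic lumen band at known depth/angle for a 5.0 mm vessel, and a
constant-flow velocity field — parabolic `2·(Q/A)·(1−(r/R)²)` or uniform
plug — encoded through a two-limb linear colormap (red toward the probe,
blue away; dominant channel `60 + 195·|v|/nyquist`, weak green admixture)
together with the matching colorbar strip.  The rendered velocity is the
signed in-plane flow speed without beam-angle projection: a cosine
projection would scale every displayed velocity by the insonation
geometry, whereas the package's estimators (like the protocol they
implement) compare displayed velocities directly with the phantom's
theoretical ones, so the generator keeps rendered = theoretical by
construction.  Artifacts are explicit and independent: a blind zone
(color suppressed in a band around the color-box center), static bleed
pixels in a ring outside the walls (sampled once per video so the
ground-truth bleed mask is exact), per-frame Gaussian color noise and
per-frame color dropout.  Everything is seeded; identical specs and seed
give bit-identical frames.

What the generator does *not* emulate: physically realistic RF speckle
and its frame-to-frame decorrelation, sector-scan geometry, wall filters,
aliasing, pulsatile flow, and vendor color maps.  Passing recovery tests
therefore demonstrate that the estimators are unbiased on geometrically
exact scenes at display resolution — not that they are robust to every
clinical artifact of a particular scanner.

## Problem sizes and numerical choices

Default study conditions follow the protocol tables (n_fr 30/24, N = 6,
th_sat 0.35, k = 4, F = 3, d = 1 mm, th_blind 10, K = 16, D = 20 mm,
10⁴ MCS iterations).  The test suite renders 240×320 to 480×640 scenes
with 12–30 frames and uses reduced MCS iteration counts in the
orchestration tests, sizes chosen so the whole suite exercises every
pipeline end-to-end at desk scale; the MCS statistical checks still run at
10⁴ iterations where the quantity under test is the Monte-Carlo SD itself.
Ties and degeneracies are fixed deterministically throughout (lower
median, boundary pixels inside, largest-then-most-central blind run), and
SVG radar plots are rendered with a fixed hash salt and no timestamp so
identical inputs yield identical bytes.
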