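# Methods

## The measurement model

A scan is a 16-bit grayscale raster of a rigid square grid of wells at
uniform pitch. With the default device constants — 300 µm wells, 50 µm
spacing, 5 µm/pixel — the pitch is (300 + 50)/5 = 70 px, a well spans
60 px, and a 40 µm post spans 8 px. The grid model is a pure translation:
the anchor (the upper-left pixel of well (0, 0)) plus integer multiples of
the pitch. Two anchor points recorded from the same post sub-position in
two wells of one row determine the pitch (horizontal separation divided by
wells between); their vertical residual is reported as a skew diagnostic
and warned about above 3 px, but never corrected — two points cannot
constrain a rotation, and scanner stages hold slides nearly square.
Coordinates are 0-based (x = column, y = row) with half-open pixel
rectangles, so window areas are exact.

**Spot calling.** A post is measured as the maximum over all 8 × 8-pixel
windows inside a search region of the window's mean intensity (max-average
window). Window sums are accumulated in 64-bit integers for integer
images, which makes the result bit-exact against brute-force enumeration;
ties are broken toward the smallest (y, then x) window origin. The search
region is the post's nominal window expanded by a margin on all sides,
clamped to the well interior. The margin defaults to **half the smallest
inter-post gap** implied by the post layout (2 px for the default 5-post
row): any larger and a dim post's best window could latch onto a bright
neighbouring post in the same well, which would break the identity between
measured and true intensity that the noiseless tests assert. A larger
margin — up to the full well interior — is available for single-post wells
or sparse layouts.

**Post layout.** The probe identity of a post is encoded by its
sub-position inside the well, but the physical arrangement is a
convention of this package: a horizontal row of evenly spaced posts,
vertically centered (for 5 posts: x-offsets 10, 70, 130, 190, 250 µm,
y-offset 130 µm). It is fully configurable per device.

## Quality control and repair

Two failure modes are modelled. *Dust*: a bright particle stuck to a post
saturates the detector, so its max-average window exceeds any biological
signal. *Fallen post*: a post detached during processing, leaving the well
floor at background. QC applies an upper and a lower raw-intensity
threshold; posts outside the band are flagged and their value replaced by
the background estimate (median of well pixels outside the post windows;
array-level background is the median over all wells, with the MAD kept as
a spread estimate). Default thresholds are data-driven — upper: the 99.9th
percentile of post intensities clipped below saturation; lower: background
− 3·1.4826·MAD — and should be overridden whenever the assay's intensity
scale is known, since the right lower threshold for *fallen-post
detection* sits between background and the weakest genuine signal, which
no distribution-free rule can locate.

Fallen posts are repaired by averaging the **same post sub-position**
(same capture probe) in the 8-connected neighbouring wells, excluding
neighbours that are themselves fallen; edge and corner wells use their
truncated neighbourhoods (5 and 3 neighbours). A fallen post with no valid
neighbour is left at background under a distinct `isolated` flag. The
repair reads all neighbour values before writing any, so it is
simultaneous and idempotent, and clean posts are never modified. Post
retention = 1 − (fallen posts)/(all posts) is reported; 16 fallen posts on
the 784-post single-post-per-well device give 768/784 ≈ 98.0%.

## Net signals, masking, statistics

Per well, every target's final intensity is reduced by the well's
negative-control final intensity and clipped at 0 (reported amounts are
non-negative; the clip discards sub-control noise, at the cost of a small
positive bias exactly at the detection floor). Wells missing their
negative-control measurement are excluded and recorded as error records.
Heatmaps hold one 16-bit pixel per well (rounded net signal; masked-out
wells 0).

The tissue mask keeps wells whose tissue fraction is **strictly greater**
than the threshold (default 0.5), so a half-covered well is excluded and
masking is monotone in the threshold. Fractions come either from the
simulator (exact polygon–footprint intersection areas via shapely) or from
a binarized brightfield image (plain intensity threshold + per-well pixel
counting; the binarization threshold is a declared parameter, not a
calibrated constant). Section summaries are mean, sample SD (ddof = 1) and
CV = 100·SD/mean over masked-in wells (≥ 2 required; CV undefined at mean
0). Sections are compared with a two-tailed unpaired t-test — Welch by
default, since equal variances across serial sections is an assumption
nothing here licenses; a pooled option exists. Two zero-variance groups
with equal means give p = 1 by convention. Significance labels: * <0.05,
** <0.01, *** <0.001. No multiple-testing correction is applied across
targets.

## Calibration, LOD, crosstalk

The default calibration form is log(signal) = a + b·log(amount), least
squares on all non-blank points (≥ 3 distinct amounts spanning ≥ 1 decade,
positive signals, fitted slope b > 0 required; violations raise with
diagnostics). A plain linear form is available. The blank SD is the sample
SD of replicate 0-amol **net** signals — the blank mean does not enter the
criterion because signals are already control-subtracted. LOD is the
amount whose fitted signal equals 3·blank SD, obtained by inverting the
fit in closed form; blank SD = 0 gives LOD = 0, and a criterion outside
the fitted signal range still returns a value under an extrapolation
warning. Inversion (`signal_to_amount`) is the same closed form, flagging
out-of-range signals. The fit-based inversion is the default; linear
interpolation between calibration points was considered and rejected as
the primary route because it is not differentiable and handles replicate
scatter poorly, but the points remain stored on the curve for users who
want it.

Crosstalk: with one single-target spike-in run per panel member, row *i*
of the matrix is each probe's control-subtracted signal as a percent of
probe *i*'s matched signal — diagonal 100% by construction, rows invariant
to the spiked amount, negative net signals clipped to 0. The summary is
the mean and max of the off-diagonal entries. The multiplexed-versus-
single-plex equivalence observation is a comparison report, not an
assertion.

## 2⁻ΔΔCt

Replicate Cts are averaged on the Ct scale before differencing; ΔCt =
mean Ct(target) − mean Ct(endogenous control) per sample, ΔΔCt differenced
against the reference sample, fold = 2⁻ΔΔCt. The reference sample's folds
are 1 by construction, and folds are invariant to adding a constant to all
of a sample's Cts (it cancels in ΔCt). An optional per-replicate mode
propagates replicate Ct spread through the exponent for a fold SD. No
amplification-efficiency correction is applied. Renormalization divides
all folds by an anchor target's fold (anchor → 1), and is invariant to
common rescaling.

## What the simulator emulates — and what it does not

The generator renders: flat-top square posts at their exact grid
positions; additive Gaussian noise (default) or Poisson shot noise,
rounded and clipped to [0, 65535]; dust as a saturating disc (radius 6 px)
over the post, large enough to contain a full 8 × 8 window by
construction; fallen posts as bare background; elliptical tissue
footprints with exact per-well coverage fractions; an optional midvein
band in which chosen targets' signal is multiplied by a factor < 1; a
constant negative-control floor in every well. Endogenous post intensity
scales linearly with tissue coverage.

It does **not** emulate: optical point-spread, bleed-through, or
autofluorescence texture; grid rotation or nonuniform pitch; post
morphology defects short of total loss; spatially correlated biological
variability beyond the vein band. Passing tests therefore demonstrate the
*analysis* is correct under the stated image model — exact recovery
without noise, statistically tight recovery under noise — not that the
assay chemistry or optics behave; on real scans the search margin,
thresholds and mask threshold are the knobs that absorb what the simulator
idealizes.

Default simulation conditions: background 100 AFU; negative-control floor
30 AFU above background; internal control 2000 AFU; pixel noise σ = 5 AFU
(a mean over 64 pixels then has SE ≈ 0.6 AFU); leaf ellipse covering
roughly a third of the array; section abundances 2400/400/220 AFU for
miR-167a/miR-159a/miR-396b — ratios of 6× and 0.55× to miR-159a, the
ordering and rough proportions typical of *Arabidopsis* leaf blade — with
a 400 µm-halfwidth vein band depressing miR-167a to 40%. The
serial-section variability scenario applies a unit-mean lognormal
multiplier with CV 0.42 to well signals. All randomness flows from one
explicit seed.

## Problem sizes and numerical notes

The end-to-end checks run the full 28 × 28 device (784 wells; 3920 posts
in the 5-plex configuration, 784 in the single-post configuration), three
section layouts, and 20 seeds for the spatial-recovery study; calibration
and crosstalk recoveries use 100 seeds each. Window sums are exact in
integer arithmetic; means are exact in float64 for 16-bit data (sums <
2⁵³). The t-statistic, percentiles and medians come from scipy/numpy.
Polygon areas are exact for polygons and accurate to the 64-segment
polygonal approximation for ellipses (the dense-rasterization oracle in
the tests agrees within 0.02 per well).

## Known limitations

- No rotation or affine grid correction; badly skewed scans need external
  registration first.
- Fallen-post *detection* by lower threshold requires a threshold chosen
  for the assay's scale; fully automatic detection on an arbitrary scan is
  not attempted (an explicit fallen list can always be supplied).
- The negative-control subtraction clips at zero, biasing near-zero nets
  slightly upward.
- Per-mass normalization is the plain quotient total amount / tissue mass;
  no volumetric or per-well abundance model is implemented.
- The brightfield binarization is a single global threshold; uneven
  illumination is not corrected.
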