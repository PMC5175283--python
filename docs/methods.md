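# Methods

## Problem setting

MALDI mass spectrometry imaging (MSI) rasterizes a thin tissue section
(here: 10 µm sections at a 100 × 100 µm pixel pitch) and records a mass
spectrum per pixel. Plotting the summed intensity in a narrow m/z window
gives an *ion image* of one analyte — e.g. the paclitaxel side-chain
fragment at m/z 284.2, or the deuterated analogue d5-PTX at m/z 289.2
sprayed uniformly over the section as an internal standard. Raw ion
images are not quantitative: *ion suppression* — signal loss caused by
co-located endogenous species — varies between tissues and within a
single tumor section, so identical drug amounts can yield very different
raw intensities.

This package implements the quantitative analysis chain around that
measurement: per-pixel internal-standard normalization, calibration to
absolute amount per area (pmol/mm²), background-thresholded coverage
and particle metrics, three-zone quantification with fold ratios, and
reproducibility statistics — exercised end-to-end on synthetic tissue
phantoms with known ground truth.

## Normalization model

Both channels at a pixel *p* are attenuated by the same local
suppression factor *s(p)*, because the internal standard is chemically
near-identical to the drug and deposited uniformly:

    drug(p) = g · d(p) · s(p) · ε₁(p) + b(p)
    istd(p) = I₀ · s(p) · ε₂(p) + b(p)

with *d(p)* the local drug amount per area, *g* the detector response,
*I₀* the sprayed internal-standard level, multiplicative noise ε and
additive background *b*. The ratio `drug/istd` cancels *s(p)* exactly
(up to noise and background), leaving a quantity proportional to
*d(p)*. Pixels whose internal-standard intensity falls below a floor
(default 5% of the median valid intensity) are masked rather than
clipped — dividing by a near-zero standard yields unbounded ratios that
reflect noise, not drug. The number of pixels masked this way is
reported with every normalization.

Exact consequences used as test invariants: multiplying both channels
by any positive field leaves the ratio unchanged; scaling the drug
channel by *a* scales the ratio by *a*; with zero noise and background
the ratio equals (g/I₀)·d(p) identically.

Normalization trades suppression variability for the internal-standard
channel's own noise. It reduces the relative standard deviation
(RSD% = 100·sd/mean, sample sd with n−1) of a whole-section ROI
precisely when in-section suppression variability exceeds that added
noise — the regime the phantom generator emulates (see below). RSD is
reported on both the raw drug signal and the normalized ratio over the
same ROI, since either convention is defensible. Serial-section series
are compared with a two-sided Welch (unequal-variance) t-test on
whole-section mean ratios and mean internal-standard intensities; Welch
is preferred over the pooled-variance test because section-to-section
variance need not be equal between series.

## Calibration and absolute quantification

Drops of known drug amount (defaults: 0.2, 0.5, 1.5, 5, 10, 15 pmol per
25-pixel spot, i.e. 0.8–60 pmol/mm²) on control tissue define a linear
calibration of mean (normalized) signal *y* against amount per area *x*:

    y = β₁ x + β₀,   R² = corr(x, y)²

fitted by unweighted ordinary least squares and inverted as
*x̂ = (y − β₀)/β₁* to express any ROI's mean signal in pmol/mm².
Choices made where the procedure was genuinely open: the per-spot
summary is the **mean** over valid pixels (robust to spot-size
differences and consistent with an amount-per-surface axis, vs. an
integrated sum); the fit is **not forced through the origin**; no
weighting. Inversion outside the calibrated range (including negative
amounts for signals below the intercept) is flagged as extrapolation,
not forbidden.

Per-spot ion suppression (shared by both channels) corrupts the raw
calibration line but cancels in the normalized one; under the simulated
suppression scenario (per-spot factors uniform on [0.4, 1.0], 1%
multiplicative noise) the normalized R² is ≈ 0.9999 while the raw R²
drops to ≈ 0.94.

## Background threshold, coverage, particle analysis

The positivity threshold is estimated from untreated control sections:
pooled valid control pixels give mean μ_bg and sample sd σ_bg, and

    threshold = μ_bg + k · σ_bg,   k = 3 by default.

*k* is exposed (`--threshold-k`) because "greater than the background
noise" admits several conventions; k = 3 fixes the per-pixel false
positive rate at the Gaussian upper-tail value ≈ 0.135%. Positivity is
a **strict** exceedance; ties at the threshold count as negative.

Percent positive = 100 × positive / valid pixels in the ROI, a
monotone non-increasing function of the threshold.

Particle analysis labels connected components of the positive-pixel
mask (8-connectivity by default, matching common image-analysis
practice; 4 available) and reports count, size, perimeter and
circularity. The perimeter is the count of **exposed pixel edges**
(4-neighbourhood boundary) times the pixel size — a simple, exactly
testable definition; weighted-boundary perimeters used by some tools
are deliberately not reproduced. Circularity = 4π·area/perimeter²,
capped at 1 (a single pixel or a straight run of pixels would otherwise
exceed 1 under the edge-count perimeter). No minimum particle size
filter is applied by default.

## Zonation and fold ratios

A normalized section is partitioned by intensity relative to the
section maximum *M*: **high** ≥ 0.75·M; **mid** in [0.25·M, 0.75·M);
**low** strictly between the background threshold and 0.25·M;
**background** at or below the threshold (background takes precedence
over the bands, since sub-noise pixels should not be quantified as
"low" drug). Both fractions are configurable; zone boundaries are
closed at the lower edge. *M* defaults to a robust maximum — the 99.9th
percentile of valid pixels — so a single hot pixel cannot compress the
bands; the raw maximum is available by flag.

Within each band, circular ROIs (default 25 pixels, the
nearest-n-pixels construction that hits the count exactly) are placed
by seeded rejection sampling: a candidate centred on a random
zone-labelled pixel is accepted if at least a fraction `purity` of its
pixels carry the zone label and it does not overlap a previously
accepted ROI of that zone. This is the reproducible analogue of drawing
ROIs by eye "in representative portions" of each color band. The
pipeline default purity is 0.8; ground-truth recovery experiments use
purity 1.0, i.e. ROIs fully interior to their band, which is what
representative manual placement achieves and what makes the per-zone
means unbiased estimates of the band levels.

Each ROI is reverse-quantified through the calibration curve; per-zone
means give the fold ratios high/low and high/mid. A bulk
"homogenate-equivalent" value — the whole-section mean quantified the
same way — mirrors what a tissue-homogenate assay would report, and the
package demonstrates that sections with equal bulk values can differ by
tens of percentage points in coverage: exactly the spatial information
a homogenate discards.

## Group statistics

Cross-model comparisons (e.g. percent positive across tumor archetypes)
use one-way ANOVA followed by Tukey's HSD (Tukey–Kramer for unequal
group sizes, via statsmodels), with significance at 0.05. The Type-I
error of the ANOVA stage is verified by simulation to sit at the
nominal level.

## Phantom generator

The generator produces the inputs the analysis expects, with ground
truth. One phantom section comprises an elliptical tissue outline with
a mildly irregular boundary, a compartment map drawn per archetype, a
smooth ion-suppression field, and the two observed channels rendered by
the forward model above.

Archetypes emulate qualitative xenograft morphologies: `homogeneous`
(uniform drug), `necrotic_core` (central drug-free blob, default 35% of
tissue), `patchy_vascular` (drug decaying exponentially from ~25 seeded
vessel points, decay length 400 µm, support clipped where penetration
falls below 15% of the perfused level), `fibrotic` (low-drug lamellae
from a warped thresholded sinusoid, default 45%) and `scant` (few
vessels, shorter decay, ≈10% support). Compartment geometry uses seeded
blob/lamella primitives — only the macro-scale distribution drives the
metrics under test, so histological realism is not attempted.

Key defaults, chosen to represent sections from treated animals where
the drug channel is clearly detectable: viable-tissue drug density
8 pmol/mm²; detector gain 50 counts per pmol/mm²; internal standard
I₀ = 100 counts; multiplicative lognormal noise with cv 5% per channel
(1% on calibration sections, where spots are pipetted rather than
perfused); additive Gaussian background (mean 0.5, sd 0.15 counts)
truncated at zero; suppression field = Gaussian-filtered seeded white
noise (correlation length 8 px) rescaled to [0.4, 1.0]. For phantom
sections the rescaling is over **tissue pixels**, so the stated
suppression range is realized within the section itself, as in tissue
where suppression varies strongly inside one tumor; rescaling over the
full grid could leave the section on a flat patch of the field and void
that condition. Serial sections (~300 µm apart) re-draw compartment
boundaries from per-section seeded streams; `section_jitter = 0`
freezes the geometry. All outputs are bit-identical for a fixed seed.

The designed-contrast phantom (`make_zoned_phantom`) carries three
concentric compartments at densities 9.52 / 4.555 / 2.0 pmol/mm²
(high 4.76× the low and 2.09× the mid level — the intra-tumor contrast
scale reported for paclitaxel in poorly perfused tumors), occupying
≈22% / 38% / 40% of the tissue, and is used to verify that the full
chain (normalize → zone → sample ROIs → calibrate → invert) recovers
designed fold ratios.

What the phantoms do **not** emulate: MALDI shot statistics and crystal
effects, mass-axis drift, peak-shape effects (images are generated
directly as ion images; an optional spectral mode emits two-peak
per-pixel spectra for exercising extraction and imzML round-trips),
histology-scale texture, and 3-D tumor structure. Passing recovery
tests therefore shows the analysis chain is correct and well-calibrated
under the stated noise model, not that it is robust to every
instrumental artefact of real acquisitions.

## Numerical and I/O choices

- m/z extraction windows are closed intervals, summing (not max)
  intensities; default half-width 0.25 Da, exposed because instrument
  software rarely documents its window.
- An explicitly supplied acquired m/z range is enforced by containment;
  a range inferred from peak lists (which only bounds the true range
  from inside) is enforced by overlap.
- Grids are 0-based (row, col), row 0 at top; a pixel's value refers to
  its full 100 µm square; ROI area = pixel count × pixel area.
- Circular ROIs are the n nearest pixels to the centre (Euclidean,
  ties broken lexicographically by (row, col)) — deterministic and
  exact in count, unlike a rasterized radius.
- CSV grid dialect: one numeric cell per pixel, `NA` = masked,
  `#key=value` header lines for pixel size, target m/z, window and
  label. imzML 1.1 (+ ibd) I/O goes through pyimzML; pixel size is
  written as the standard scanSettings cvParams, and fully-masked
  border rows/columns are cropped on imzML read since absent pixels are
  simply not written.
- Degenerate inputs raise: empty ROIs, non-positive RSD means,
  all-masked normalizations, zero-variance series comparisons,
  sub-three-point calibrations, zero-signal zonations.

## Problem sizes

Default experiment sizes — 80 × 80 phantom grids (≈ 4,000 tissue
pixels), two pooled control sections for thresholding, six calibration
spots, 100-seed suites for linearity and RSD claims, 20-seed suites for
recovery claims, 320 × 320 controls (≈ 10⁵ pixels) for the
false-positive-rate check — are the package's chosen balance between
Monte-Carlo resolution and quick, deterministic runs; all are
configurable.

## Known limitations

- The internal-standard model assumes the standard experiences the same
  suppression as the analyte at every pixel; matrix effects that
  differentiate the two (e.g. differential extraction) are not modeled.
- The additive background slightly biases ratios upward where the
  internal standard is weak; the istd floor bounds but does not remove
  this.
- Perimeter and circularity follow the exposed-edge convention and will
  differ numerically from tools using weighted boundaries.
- Zone boundaries at exactly 0.75/0.25 of a robust maximum are one
  reasonable reading of "approximately 75%/25% of maximum"; both
  fractions and the maximum convention are configurable rather than
  claimed canonical.
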