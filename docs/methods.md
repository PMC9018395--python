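# Methods

## The measurement model

The assay reads out apoptotic state per cell from three co-registered
16-bit channels. Cells are *identified by their nuclei*: segmentation is
driven entirely by the DAPI channel, and each reporter-channel granule is
attributed to a cell by position. A cell's phenotype is then a pure
function of its granule content and total reporter fluorescence:

| granules (BAX, OMI) | total fluorescence | label |
|---|---|---|
| +, + | any | DOUBLE_POSITIVE |
| +, − | any | BAX_POSITIVE |
| −, + | any | INTACT |
| −, − | both below floor | NONDETERMINED |
| −, − | otherwise | INTACT (diffuse BAX / released OMI) |

Granule-free but fluorescent cells are read as intact because diffuse
cytoplasmic Venus-BAX and degraded OMI are both compatible with the
"BAX puncta negative" state; only cells dark in both reporters are
excluded as nondetermined. Fraction denominators include nondetermined
cells (fractions are over all segmented cells), so the four fractions
always sum to one per well.

## Image analysis

**Nuclear segmentation.** Gaussian smoothing (σ = 2 px), Otsu threshold
with a bimodality guard (the threshold must clear the image median by
4 robust σ, so pure-noise fields yield zero nuclei rather than a
half-image "nucleus"), hole filling, and per-component
distance-transform watershed to split touching nuclei. Objects outside
the 12–4000 px² fragment-area bounds are discarded. Sub-normal objects
(< 230 px²) within a 15 px grouping radius are merged single-linkage
into one nucleus with `fragment_count > 1`; an object (merged or not)
is *fragmented* when its total area stays below the 230 px² normal-
nucleus minimum. Only sub-normal objects are ever grouped, so two
adjacent normal nuclei are never fused. The 230 px² default sits midway
between the measured area of rendered fragment clusters (≤ ~200 px²)
and of the smallest normal nuclei (≥ ~265 px² at the default 9 px
nucleus radius); it must be recalibrated for other magnifications.

**Cell regions.** Each nucleus is expanded by at most 14 px
(`expand_labels`), with collisions resolved by the nearest-nucleus
rule, giving a disjoint partition. This radius covers the simulated
cytoplasm (puncta are placed 6–18 px from the nucleus centroid); real
deployments should set it to the expected cytoplasm extent.

**Granule detection.** White top-hat with a disk footprint of radius
`ceil(max_diameter/2) + 2` removes diffuse fluorescence at the
punctum scale. Local maxima above `peak_height` (on a lightly smoothed
copy, to avoid shot-noise double peaks) seed granules; each is grown to
the connected support above half its peak amplitude, so the measured
equivalent diameter estimates the punctum FWHM independently of
amplitude. A granule is kept iff its diameter lies within the channel's
2–10 px acceptance range (≈1.3–6.5 µm at 0.65 µm/px, the mitochondrial
puncta scale), its integrated top-hat intensity exceeds the channel
threshold, and its centroid falls inside a cell region. Count
monotonicity in both criteria is structural (they are pure filters),
and all intensity thresholds scale linearly with the image
(`DetectionParams.scaled`).

## Screen statistics

Well fractions are computed over cells pooled across a well's sites, so
sparse sites are not over-weighted; wells with fewer than 50 analyzed
cells (configurable) are flagged invalid and skipped, decrementing the
gene's replicate count. Category I/II share one statistic — the
fold-change of the BAX-positive fraction against the same-plate mean of
nontargeting negative-control wells — ranked descending (I) or
ascending (II); category III is the raw double-positive percentage.
Replicates aggregate as mean ± SEM (sd/√n, 0 for n = 1). No further
plate normalization (e.g. B-scoring) is applied beyond the same-plate
control division.

The "10 % cutoff" is implemented as the top/bottom decile *by rank*
(`floor(tail · n)` genes), since the score display is a rank-sorted
curve with a tail; selection by 10 % of the numeric score range is
available as `mode="range"`. Ties at the cutoff break by lexicographic
gene identifier and are flagged `tie_degenerate`. Controls are not part
of the ranked population. Categories are reported independently; a gene
can in principle appear in more than one list.

Secondary confirmation marks each of a gene's four deconvolved siRNAs
hit/miss by the *same* threshold realized at the primary cutoff, and
confirms at ≥ 3 of 4; missing siRNAs count as misses. With per-siRNA
reproducibility p the expected confirmation rate is
4p³(1−p) + p⁴ (≈ 0.95 at p = 0.9), which is what the acceptance
simulation checks binomially. The historical manual-curation step
between primary and secondary screens is out of algorithmic scope: the
pipeline emits the full ranked list and accepts an explicit
include-list.

Z′ uses sample standard deviations and raises on coincident means or
fewer than two wells per arm. Constant control sets are treated as
exactly zero spread so that separated zero-variance controls give
Z′ = 1 without floating-point dust. Plate QC pairs treated
nontargeting-control wells (positive, high %BAX-positive) against
untreated wells (negative).

## Clonogenic arm

The well disk is auto-fitted as the complement of the border-connected
plate background (pixels within `border_tolerance` of the border median
intensity) — a rule insensitive to how much of the well is stained — or
supplied explicitly. Stain is separated by Otsu's threshold on the
in-disk intensities, refined to the midpoint of the two class means so
the blurred colony edge is split symmetrically (raw Otsu drifts toward
the smaller class and biases area by >1 point at mid coverage). Wells
without sufficient stain contrast (blank or fully stained) fall back to
a fixed absolute threshold, the fixed dialect of classic colony-area
macros. Only total covered area is reported, so merged colonies need no
instance separation. Survival is 100 × treated / matched-control area;
values above 100 % are reported with a warning, not clipped.

The ANOVA is an ordinary fixed-effects two-way model with Type II sums
of squares (statsmodels OLS under the hood), with the genotype × dose
interaction included whenever residual degrees of freedom remain and
dropped (with a logged note) otherwise. A response that is constant in
every design cell returns F = 0, p = 1 instead of 0/0. Doses are plain
metadata; the default synthetic design uses the 2.5/5/10 µM grid of the
BH3-mimetics ABT-737/ABT-199.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not microscope optics. Defaults: 1024 × 1024 px fields at 0.65 µm/px
(20× widefield), 384-well plates with a 2-row/column excluded edge
band, 16 sites per well, ~50 cells per field (a configurable guess —
plated density is known but imaged density is not), and a treated
population mixture of 50 % BAX-positive / 40 % intact /
3 % double-positive / 7 % nondetermined, reflecting a treated
population dominated by the two all-or-none states with heterogeneous
cells rare. Untreated wells are 90 % intact; BAX-pool positive-control
wells have puncta formation suppressed and a larger nonfluorescent
fraction.

Nuclei are soft-edged ellipses (apoptotic ones as 2–4 fragments of
2.4–2.8 px radius on a 5.5–9 px ring, spaced to stay within the 15 px
grouping radius yet not fuse after smoothing); cytoplasm is a soft disk
of diffuse fluorescence per phenotype; puncta are 2-D Gaussians with
FWHM equal to the true diameter (3–7 px), amplitude ~3000 counts
(CV 25 %), mutually separated by at least their mean diameter + 3 px,
and — for double-positive cells — cross-channel separated by ≥ 5 px
(non-colocalization). Noise is Poisson shot noise on the expected
signal plus Gaussian read noise (σ = 30) over a constant background
(200); out-of-range intensities clip with a logged warning. Every
stream derives from one seed by `SeedSequence` spawn keys per
(plate, well, site), so any subset regenerates bit-identically.

Imageless generators mirror the screen at scale: per-well multinomial
phenotype counts at n ≈ sites × cells-per-field (so well-to-well spread
is exactly counting noise), per-gene score tables with spiked
multiplicative effects and additive or CV noise, and per-siRNA
secondary scores that reproduce the pooled effect with a configurable
probability. Spiking scales the target class exactly and redistributes
the remaining probability mass proportionally, so a requested k-fold
effect realizes a k-fold change of that class. Colony wells bisect a
global colony-radius scale until the realized covered fraction is
within 1 point (in practice ≪ 0.1) of the request, and record the
realized value.

What the generator does *not* model — and what passing tests therefore
do not establish for real data: optical point-spread functions and
chromatic offsets, illumination gradients and vignetting, debris and
out-of-focus fluorescence, cell crowding/overlap (cells are placed with
a 46 px minimum separation), reporter-expression variability beyond a
single amplitude CV, and any biology linking the phenotype categories
to actual gene function. Detection thresholds shipped as defaults are
calibrated to this renderer and must be re-tuned on real images, as the
original stringency thresholds were.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the sizes the checks
name: 20 default fields (~1000 cells) for detection fidelity, ≥ 500
matched cells for classification accuracy, the full 1318-gene scale for
hit calling (score tables, not images), sort-oracle checks to 10 000
genes, 1000 null simulations for ANOVA calibration, and a reduced
image-mode screen (6 genes, 8 × 12 plate, 256 × 256 px, 2 sites) for
byte-identity of complete runs. Full-scale image rendering of an entire
plate set is supported by the same code path but is not exercised in
the default suite. Comparisons use 1e-12 for closed-form identities
(Z′, mean/SEM), 1e-8 against the balanced-ANOVA closed form, 2
percentage points for colony-area recovery, and binomial bounds for
stochastic rates.

## Known limitations

* Cell extents are nuclear expansions; without a cytoplasm stain, true
  cell boundaries are unknowable, and granules beyond the expansion
  radius of a crowded neighbour can be mis-assigned.
* The fragmented/normal nucleus rule is area-based with a fixed
  threshold; aneuploid or mitotic cells would need a second feature.
* The granularity re-implementation honours the published acceptance
  criteria (diameter range, integrated-intensity threshold) but is not
  a bit-level reproduction of the proprietary module it replaces.
* `simulate_well_summaries` models counting noise only; systematic
  plate effects (edge gradients, transfection drift) are not injected,
  so Z′ values from it are upper bounds for a real plate.
* The ANOVA assumes homoscedastic Gaussian errors; survival percentages
  near 0 or 100 violate this, and a variance-stabilizing transform is
  left to the caller.
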