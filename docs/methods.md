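# Methods

This note documents the models, conventions and numerical choices behind
`lcicquant`, in the order data flows through the pipeline.

## The measurement problem

LCIC layer 2 contains discrete GAD-positive modules inside a surrounding
matrix; several microglial and complement markers shift between these two
compartments across the early postnatal critical period. The pipeline turns
a multi-channel section into (i) per-section compartment ROIs derived from
the GAD reference channel, (ii) a background-subtracted median intensity
ratio per marker channel with a bias class, (iii) a cross-channel phase
score along a thick sampling contour, and (iv) object-level colocalization
and occupancy statistics.

## Synthetic sections and what they stand for

No imaging data is deposited for this system, so validation rests on a
generator with exact ground truth.

**Geometry.** The curved LCIC shell is simplified to a straight horizontal
band (rows 72–184 of a 256×512 px frame by default) holding 4–8
non-overlapping ellipses (row semi-axes 12–18 px, column semi-axes 16–24 px,
bounding-circle gap ≥ 6 px, rejection-sampled with whole-layout restarts).
Nothing downstream depends on curvature — only on the modular/matrix
topology — which is why the simplification is safe. A 32 px tissue-free
margin surrounds the analysis region and provides background. The
ventral→dorsal axis maps to increasing column index; rasters are row-major
with the origin top-left.

**Signal model.** Each channel is an expected-intensity field: a diffuse
term taking `module_mean` / `matrix_mean` / `outside_mean` per compartment,
plus `cell_amplitude` on hard disks (radius 4 px) at cell positions. The
field is blurred with a Gaussian PSF (σ = 1 px), then corrupted by Poisson
shot noise and additive Gaussian read noise (σ = 2), rounded and clipped to
the bit depth (16 by default). This is the standard fluorescence noise
model; no optical realism beyond PSF + shot noise is attempted (no
Z-structure, no vignetting, no autofluorescence texture). Consequences for
interpretation: passing tests show the *pipeline math* is correct under
realistic photon statistics, not that segmentation parameters transfer to
arbitrary real micrographs — on real data the threshold method, `min_area`
and the hand-drawn total outline remain the user's responsibility.

**Cells.** Each cell draws a marker-identity combination from a
`coexpression_table` (probabilities over combinations, summing to 1), then a
compartment: with probability `compartment_preference[primary marker]` a
module pixel, otherwise a matrix pixel; `None` means uniform placement over
the whole region (areal chance level). Somata exclude each other: one
minimum centre separation (9 px) applies across *all* cells, so distinct
populations never overlap spatially — this is what makes "zero
colocalization" exactly realisable and is also the biologically correct
behaviour for cell bodies. Cell disks are kept clear of the tissue border.

**Determinism.** One integer seed drives a single `numpy` PCG64 stream with
a fixed draw order (module geometry → cells → per-channel noise, channels in
sorted name order), so identical configs give bit-identical sections.

**Preset table.** All preset constants are implementation choices that
encode the qualitative developmental patterns; none is a measured value.
Diffuse means are (module, matrix) in arbitrary photon units with
`outside_mean` = 8; the GAD reference channel is (160, 40) at every age.

| marker | P0 | P4 | P8 | P12 |
|---|---|---|---|---|
| C3 diffuse | (110, 110) | (95, 110) | (18, 110) | (10, 10) |
| CD11b diffuse | (70, 70) | (80, 70) | (105, 70) | (48, 70) |
| CD11b cell pref. | uniform | 0.5 | 0.8 | 0.15 |
| CX3CR1 cell pref. | uniform | 0.08 | 0.08 | 0.7 |
| TMEM119 | absent | pref. 0.7 | pref. 0.7 | pref. 0.7 + 3% CX3CR1 overlap |
| Iba1 | subset of CX3CR1 (40% of CX3CR1 cells) at all ages | | | |

CX3CR1's documented "ring around modules" is simplified to plain matrix
placement; the ring topology adds nothing to any statistic computed here.
At P12 the C3 matrix mean (10) sits barely above background (8): the
coverage ratio is then legitimately near-undefined, mirroring the loss of
measurable signal at that age, and the ratio function raises rather than
returning a number.

## Segmentation and ROI algebra

The reference channel is min-max normalised (making the result exactly
invariant under positive affine intensity transforms), thresholded by Otsu
restricted to the analysis region (a fixed-quantile override exists),
morphologically closed (disk radius 2 px), hole-filled, filtered to
components ≥ `min_area` (50 px), and labelled with 8-connectivity in
row-major scan order. A foreground fraction of 0 or > 60% of the region is
treated as implausible: an empty mask plus a structured warning, never a
crash. Otsu was chosen as the parameter-free default where the original
manual procedure says only that "a threshold" was applied; no dilation
margin is added to module outlines (defaulting to 0 where the manual
procedure is silent).

The ROI set then follows by algebra: matrix = total XOR modules (module
components outside the total region are clipped with a warning), and the
partition identity area(modules) + area(matrix) = area(total) holds exactly
by construction. The automatic background box is the largest axis-aligned
rectangle fully outside the total region (histogram-stack algorithm, O(HW)),
required to reach 1024 px; if none qualifies the caller must supply one.

## Coverage ratio

Medians are exact over the pixel multiset of each ROI; the even-count median
is the mean of the central pair (matching the brute-force sort-and-middle
oracle in the tests). Saturated pixels are included, with a warning when
they exceed 1% of a ROI. The ratio requires matrix median strictly above
background median. Bias classes use a tolerance band of ±0.1 around 1:
`modular` above, `matrix` below, `homogeneous` within. Ratios are per
section; pooling pixels across sections is deliberately unsupported, since
the study design treats each section as one replicate.

## Profiles and phase

The sampling contour is a polyline through module centroids sorted by
column, extended by half the mean inter-centroid spacing at each end and
clamped to the modules' bounding box (so the contour never runs into
signal-free margins, which would inject a correlated common-mode drop into
both channels). A single module degenerates to a horizontal segment across
its bounding box. Users can supply their own polyline for real data.

Profiles are sampled at 1 px arclength steps; at each step the mean (not
median) of `thickness` bilinear samples spaced 1 px along the perpendicular
is taken. Thickness defaults to 100 px — the conventional plot-profile
width for this material; since no pixel size is stated for the original
imagery, it is a free parameter. Out-of-bounds samples are clipped to the
border with a warning.

Phase concordance is the Pearson correlation of the two linearly detrended
profiles at zero lag: the simplest statistic whose sign encodes
in-phase/out-of-phase. Identical (or exactly negated) detrended series
short-circuit to ±1.0 so the degenerate cases are exact; constant series
raise. A lag-sweep cross-correlogram (positive lag = second series trails)
is available for diagnostics; no Fourier periodicity estimation is
attempted.

## Colocalization

Detection is scale-space LoG blob detection on the min-max-normalised
channel (radii 2–8 px, 6 scales, response threshold 0.1), returning one
object per local maximum; determinism comes from fixed scan-order sorting.
Matching is distance-sorted greedy one-to-one matching within a match radius
(default: the mean detected radius, ~4 px), which extracts mutual nearest
neighbours first; each unordered marker pair is matched once in sorted
name order so the matched set is independent of listing order, and ties
break by table scan order. Conditional fractions P(B|A) are matched/total.
A permutation control resamples one table's positions uniformly over the
analysis region (default 99 shuffles, add-one p-value) to check observed
overlap against chance. Pixel-correlation coefficients (Manders/Pearson) are
out of scope by design: the biological claims concern double-labelled cells.

## Group statistics

Comparisons use the two-sided Mann–Whitney U test. Without ties and with
both groups ≤ 20, the exact null distribution is used; with ties, an exact
p-value is computed by full enumeration of group assignments (midranks)
while C(n₁+n₂, n₁) ≤ 2·10⁵, beyond which a tie-corrected normal
approximation with continuity correction applies. Groups of 2 are accepted
(the exact distribution is still meaningful, if coarse). All-tied input
returns p = 1 with a warning. Welch's t is available behind a flag. Two
planned comparisons are reported with raw p-values — no multiple-testing
correction — and sections are treated as independent replicates; an
animal-id column can be carried for mixed-model reanalysis elsewhere, but
hierarchical modelling is a documented non-goal.

Quartiles throughout (boxes, the disjoint-box criterion) are Tukey hinges —
medians of the lower/upper halves with the median included in both halves
for odd n. This makes "disjoint boxes" literally equivalent to "3/4 of one
group above 3/4 of the other", which interpolated quartiles do not
guarantee for small n. Whiskers extend to the most extreme values within
1.5·IQR of the hinges; the box figure is drawn from these same precomputed
stats so plot and test cannot disagree.

## Problem sizes

Default sections are 256×512 px with 6 modules. Simulated studies use 15
sections per age (five sections from three animals), matching the original
sampling design; recovery and phase checks use 20 sections; replicate-batch
checks use 20 batches. These sizes give the test suite and the acceptance
script comfortable statistical margins at interactive runtimes.

## Known limitations

* Segmentation defaults (Otsu, closing radius 2, min_area 50) are tuned to
  the generator's geometry; real micrographs need parameter review and a
  hand-drawn total-region mask.
* The generator has no ring topology for CX3CR1, no process morphology for
  microglia, and no inter-section variability beyond noise and geometry
  resampling (no per-animal random effects).
* Per-module (individual patch) ratios are unsupported; all modules of a
  section pool into one modular ROI.
* Whether the original manual workflow excluded saturated or border pixels
  is unknown; this implementation includes both and warns on saturation.
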