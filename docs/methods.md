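# Methods

This note documents the models and procedures focusq implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Image model and preprocessing

Input images are 2D single-channel intensity arrays in arbitrary camera
units; integer types are promoted to float64 on ingest with no rescaling.
Coordinates are 0-based (row, column) and all distances are pixel units.

**Background subtraction.** The background estimate is a grey-level
morphological opening with a disk footprint (`background_radius`, default
50 px, applied with a decomposed footprint for speed).  The radius must
exceed the half-width of every feature to be kept: both the sub-cellular
structures *and the cells themselves* must survive, because the downstream
Pearson and dispersion statistics use cytoplasmic intensities.  The default
therefore sits above the typical cell radius (24–34 px in the synthetic
scenes) and below a cell diameter.  A flat image maps exactly to zero; a
small Gaussian spot on a constant offset is returned with its amplitude
intact.  Output is clipped at 0; non-finite pixels raise.

**Blur-divide equalization.** `equalized = channel / (blur + ε)` with a
Gaussian blur at `equalization_blur_sigma` (default 40 px, at least a cell
radius so only cell-scale intensity is flattened) and
`ε = 10⁻⁶ × max(channel)`.  Pixels whose blurred value falls below ε are
true background and map to 0, which keeps 0/0 regions silent; an all-zero
image returns all zeros.  The output is dimensionless: a spot with fixed
contrast relative to its cell equalizes to the same peak in a dim and a
10×-brighter cell (within a few percent, dominated by blur edge effects).

## Segmentation

**Cells.** Foreground = background-subtracted primary intensity
> `cell_intensity_threshold` (default 30, about half the synthetic
cytoplasmic level and ≈5σ above the noise floor); 8-connected components
below `cell_min_area` (default 400 px) are dropped, an optional maximum-area
filter (off by default) removes large artifacts.  The foreground is split
into single cells by a watershed on the negated Gaussian-blurred image
(`watershed_blur_sigma`, default 4 px).  Watershed seeds come from one of
two sources:

* default — peaks of the Gaussian-smoothed Euclidean distance transform of
  the foreground (`marker_smooth_sigma` 4 px, `marker_min_distance` 20 px;
  smoothing keeps an elongated cell's distance ridge from seeding twice).
  Any foreground component left without a peak is seeded at its distance
  maximum, so no component is silently dropped.
* `use_nuclear_channel_in_watershed` — nuclei segmented from the blurred
  nuclear channel by Otsu's threshold become the markers and the watershed
  runs on the blurred primary+nuclear merge.  This variant separates
  touching cells that have distinct nuclei.

Labels are relabeled consecutively; an empty foreground yields an all-zero
map, not an error.

**Structures (puncta/foci).** A pixel is a candidate when it exceeds the
raw threshold (`raw_bright_threshold`, default 300) in the
background-subtracted image AND the ratio threshold
(`equalized_bright_threshold`, default 1.8) in the equalized image AND lies
inside a cell.  Components are 8-connected (small bright spots should not
fragment on diagonals).  Size exclusion is a pure filter interpreted as a
MINIMUM area — its purpose is noise removal — with mode-specific defaults of
5 px (punctum) and 35 px (focus).  Each surviving component is assigned to
the cell containing the majority of its pixels, ties broken toward the
lower cell id.  All thresholds are manual and held constant across images
and conditions within a run; they are config fields, not constants, because
sensible values depend on camera gain and magnification.

## Metrics

**Per-cell Pearson.** `r` between the background-subtracted primary and
secondary intensities over all pixels of one cell's mask (no pixel
thresholding).  Cells with fewer than 2 pixels or a constant channel are
skipped and logged.  `r` is invariant to affine rescaling of either channel
with positive gain.

**Positivity ratio.** For a structure S, the comparison region is
`dilate(S, disk(dilation_radius)) ∖ (all structure pixels ∪ background)`,
additionally restricted to S's own cell so the region never bleeds into a
neighbour.  *All* structure pixels in the image are excluded, not just S's,
and "background" means pixels outside the cell segmentation.  Ratio = mean
secondary over S / mean secondary over region; positive ⇔ ratio strictly
greater than the threshold (default 1.25, so a ratio of exactly 1.25 is
negative).  Structures with an empty or zero-mean region are flagged
unscorable and excluded from fractions but counted in QC.  Default
`dilation_radius` 5 px: wide enough to sample local cytoplasm, narrow
enough to stay local.

**Dispersion profile.** For each cell whose structure mask holds at least
`min_structure_pixels` (default 5, reusing the punctum minimum) nonzero
pixels: centroid = intensity-weighted mean coordinate of the primary
channel inside the cell mask; each in-cell pixel joins ring
`round(d)` of its Euclidean distance to the centroid, i.e. ring k covers
[k−0.5, k+0.5), which keeps rings non-empty near the centroid; ring value =
mean intensity of its pixels; the profile is divided by the cell's mean
intensity.  Consequently Σ(ring value × ring count) / cell area = 1 exactly,
and a uniform cell profiles flat at 1.0.  Rings with no pixels are absent
from the index rather than zero.  Pixels outside the cell mask never count.
Cells with zero total intensity are skipped with a warning.

**Aggregation.** Cell → site (median) → well (median of site values) →
condition (mean ± sample SD over wells, SD with n−1; undefined and reported
missing with fewer than 2 wells).  An alternative reading pools a well's
cells directly before the median; both are implemented (`pool_sites`),
default is the site-median route.  Cross-cell medians of dispersion
profiles are taken per ring over the cells that possess that ring — padding
short profiles with zeros would bias tails downward.  Peak statistics of a
profile: peak = maximum ring value (ties toward the smallest ring), width =
length of the contiguous ring run around the peak with values ≥ half the
peak.

**Relative expression.** Technical replicate Cts are averaged per
biological sample, then ΔCt = Ct_gene − Ct_reference (ACTB),
ΔΔCt = ΔCt − mean ΔCt of the untreated samples of that gene, fold = 2^−ΔΔCt.
When an `experiment` column is present the untreated baseline is computed
per experiment by default (`pool_experiments` pools them).  Two identities
follow from the definitions and are tested: the geometric mean of untreated
folds is exactly 1, and a plate-wide Ct shift cancels.  Significance
testing (the downstream two-way ANOVA with multiple-comparison correction)
is deliberately out of scope; use a standard statistics package on the
output table.

## Synthetic scenes

The generator emulates one field of view of a plate imaging experiment:
elliptical cells (major semi-axis 24–34 px, axis ratio ≤ 1.5, placed
without overlap by reject-and-resample with bounded retries), a nucleus at
35 % of the minor semi-axis, and a primary channel composed of background
level 80 + a linear illumination ramp (amplitude 20) + cytoplasmic fill 60
+ structures + Gaussian noise (σ 6, clipped at 0).  Structures are
isotropic 2D Gaussian spots with σ = radius/2 — diffraction-limited
appearance rather than hard disks, which stresses the thresholding
realistically.  Two phenotypes:

* **dispersed** — 8 puncta (radius 2.5 px) per cell scattered uniformly in
  an elliptical annulus between the nucleus edge and 85 % of the cell
  boundary, with centres kept a puncta-diameter apart so every planted
  record renders as its own connected structure;
* **clustered** — one focus (radius 8 px) placed just outside the nucleus
  (`cluster_offset` 2 px), emulating the perinuclear focus phenotype.  The
  amplitude balance (structure peak 600 vs cytoplasm 60) makes the focus
  carry a large share of the cell's intensity, as a reporter concentrated
  into one structure does, which is what gives the clustered dispersion
  profile its tall narrow peak.

A fraction `coloc_fraction` of structures (rounded to the nearest whole
structure per scene) is flagged `has_secondary` and mirrored into the
secondary channel (amplitude 400 over a diffuse cytoplasmic level of 60),
giving planted positivity ratios of roughly 3 versus 1.  Identical specs
(including seed) render bit-identical scenes; the noise level does not
perturb the ground truth.  Plate generation derives one seed per
(well, site) from a base seed with a counter-based scheme, so partial
re-runs reproduce individual scenes.

What the generator does **not** emulate: PSF convolution and vignetting,
Poisson (shot) noise, 3D structure, cell-to-cell expression variability,
touching or overlapping cells, debris, and drug-specific phenotype classes.
Passing tests therefore demonstrate the correctness of the measurement
logic under a clean, known-truth regime — not robustness to the full
variability of real micrographs, where the manual thresholds must be chosen
per experiment.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on 256×256
scenes with 6 cells (~48 dispersed structures): 10 seeds for segmentation
recovery, 20 paired 3-well plates for pattern discrimination, and
5 planted colocalization levels × 3 wells for positivity recovery — sizes
chosen so the complete suite finishes in about a minute while every
condition-level statistic still aggregates over 3 wells, mirroring a
triplicate experiment.  All randomness flows through explicit integer
seeds; pipeline outputs are pure functions of (inputs, config), verified by
rerun checksum equality, and result CSVs carry a config-hash metadata
header and round-trip to full float precision.  The pipeline recomputes
every stage on each run rather than caching intermediates: at these problem
sizes a full run takes seconds, and an always-recompute design keeps the
determinism contract trivially auditable.

## Known limitations

* Watershed seeding by smoothed distance peaks can over- or under-split
  unusually elongated or dumbbell-shaped cells; the nuclear-marker variant
  is more robust when a nuclear stain exists.
* Positivity scoring assumes the secondary channel's cytoplasmic level is
  nonzero inside cells; on images where it is truly zero the ratio is
  undefined and structures become unscorable.
* The dispersion profile is 2D; out-of-focus light from a 3D focus is not
  modelled.
* Amplification-efficiency correction (e.g. the Pfaffl method) is not
  implemented; 2^−ΔΔCt assumes near-100 % efficiency for gene and
  reference.
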