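# focusq

Quantification of punctate-reporter clustering and colocalization in
plate-based fluorescence microscopy, for cell biologists measuring
autophagy-related phenotypes: how many LC3B puncta or foci a cell carries,
whether those structures are positive for a co-stained marker (an autophagy
receptor such as p62, NBR1, NDP52, TAX1BP1, OPTN or TNIP1), how strongly two
channels correlate inside single cells, and how tightly the reporter's
intensity is clustered around its centre of mass.  A qPCR helper computes
relative gene expression from Ct tables.

All stages run without microscope data: a synthetic-scene generator renders
multi-cell fields of view with planted ground truth (cell masks, structure
centres, colocalized fraction, pattern class), so every measurement the
package makes can be checked against a known answer.

## What it computes

Given a plate of multi-channel images (primary = punctate reporter,
secondary = immunostained marker, optional nuclear stain), per field of view:

1. **Background subtraction** — a morphological-opening estimate of the slow
   background is subtracted from every channel.
2. **Single-cell segmentation** — foreground by an intensity threshold on the
   primary channel, size-filtered, then split into cells by a watershed on a
   blurred image (primary alone, or a primary + nuclear merge).
3. **Puncta/foci segmentation** — the image is divided by a cell-scale
   Gaussian blur of itself ("blur-divide" equalization) so dim and bright
   cells have comparable contrast; pixels bright in both the raw and
   equalized images, inside cells, form structures; components below the
   minimum area (5 px for puncta, 35 px for foci) are removed.
4. **Per-cell Pearson correlation** `r = cov(P, S) / (σ_P σ_S)` between the
   two channels over each cell's pixels.
5. **Structure positivity** — for each structure, the ratio of the mean
   secondary intensity over the structure to that over a nearby cellular
   region (dilation minus structures minus background); ratio > 1.25
   (strict) means positive.
6. **Radial dispersion profile** — for each cell with enough structure
   pixels, the intensity-weighted centroid of the primary channel is found;
   in-cell pixels are grouped into integer distance rings `round(d)` around
   it; ring means are normalized by the cell's mean intensity.  A sharp tall
   peak indicates a clustered focus; a broad low profile, dispersed puncta.

Statistics aggregate hierarchically: median over cells per site, median over
sites per well, mean ± sample SD over wells per condition.

The qPCR module implements the Livak method: ΔCt = Ct_gene − Ct_ACTB per
sample, ΔΔCt = ΔCt − mean ΔCt of untreated samples, fold = 2^−ΔΔCt.

## Worked example

Simulate a two-condition plate (three wells each) where the treated
condition shows one large perinuclear focus per cell with 80 % of structures
carrying secondary signal, and the control shows eight dispersed puncta with
50 %:

```python
import focusq
from focusq.pipeline import RunConfig, run_pipeline
from focusq.metrics import profile_peak_stats

layout = focusq.PlateLayout.uniform(["dispersed", "clustered"], n_wells=3)
config = RunConfig(
    layout=layout,
    overrides={"clustered": {"pattern": "clustered", "coloc_fraction": 0.8}},
    seed=42,
    output_dir="results/demo",
)
result = run_pipeline(config)

pos = result.tables["positivity_conditions"]
print(pos[pos.statistic == "fraction_structures_positive"][["condition", "mean", "sd"]])

cond = result.tables["dispersion_conditions"]
for name, grp in cond.groupby("condition"):
    peak, ring, width = profile_peak_stats(grp.set_index("distance")["mean"])
    print(f"{name}: peak {peak:.2f} at ring {ring}, half-max width {width}")
```

prints

```
condition     mean  sd
clustered 0.833333 0.0
dispersed 0.500000 0.0
clustered: peak 2.00 at ring 6, half-max width 14
dispersed: peak 1.19 at ring 16, half-max width 35
```

The recovered positive fractions match the planted ones (0.8333 is the
nearest realisable fraction to 0.8 with six structures per scene: five of
six are flagged), and the clustered condition's dispersion profile peaks
higher and is much narrower than the dispersed one — the signature the
profile is designed to detect.  The same pipeline runs from the shell:
`focusq simulate | segment | metrics | qpcr | run` (see `focusq --help`).

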