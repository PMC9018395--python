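# mompscreen

Analysis pipeline for image-based siRNA screens of **heterogeneous
mitochondrial outer membrane permeabilization (MOMP)**, with a
clonogenic-survival arm and a seeded synthetic-data generator.

## The problem

In cell-intrinsic apoptosis, BAX translocates to mitochondria and opens
pores that release intermembrane-space proteins such as OMI. In most
dying cells this is all-or-none, but in some cells only part of the
mitochondrial population permeabilizes ("minority MOMP"), leaving a
survivor with sublethal caspase activation and DNA damage. A
high-content screen for regulators of this heterogeneity images three
channels per field — a nuclear stain (DAPI), Venus-BAX (YFP) and
OMI-mCherry (Texas Red) — and classifies every cell as:

* **BAX_POSITIVE** — suprathreshold BAX puncta, no OMI puncta (full MOMP);
* **INTACT** — OMI puncta retained, diffuse BAX (no MOMP);
* **DOUBLE_POSITIVE** — non-colocalized puncta in *both* channels
  (heterogeneous MOMP, the phenotype of interest);
* **NONDETERMINED** — reporter fluorescence below the analysis floor.

This package re-implements that analysis openly and end to end:

1. **imaging** — nuclear segmentation (Otsu + distance-transform
   watershed, apoptotic-fragment grouping), nearest-nucleus cell
   regions, and granule detection (white top-hat, local-maximum seeding,
   half-maximum support) filtered by the two stringency criteria:
   equivalent diameter within range *and* integrated intensity above
   threshold.
2. **phenotype** — the four-way per-cell classification and pooled
   per-well summaries.
3. **screen** — plate QC via the Z′ factor,
   `Z' = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|`; per-gene triplicate scores
   (categories I/II: fold-change of %BAX-positive vs same-plate
   nontargeting controls; category III: %double-positive); hit calling
   from the top/bottom decile of the rank-sorted score distribution; and
   the secondary-screen filter requiring ≥ 3 of 4 individual siRNAs to
   be concordant.
4. **clonogenic** — crystal-violet colony area as percent of the well
   disk, survival normalized to the untreated 100 %-growth control, and
   a genotype × dose two-way ANOVA (Type II).
5. **synthdata** — deterministic generators for all of the above:
   three-channel 16-bit fields with exact per-cell/per-punctum ground
   truth, 384-well plate maps with edge exclusion, imageless score
   tables with spiked effects, and colony wells with known covered
   fractions.

## Worked example

```python
from mompscreen import RunConfig, run_screen
import pandas as pd

config = RunConfig(
    n_genes=96, replicates=3, mode="scores",
    spiked={"G00007": {"III": 5.0}, "G00042": {"I": 3.0}},
    seed=11, outdir="demo",
)
run_screen(config)
qc = pd.read_csv("demo/qc.csv")
hits = pd.read_csv("demo/primary_hits.csv")
sec = pd.read_csv("demo/secondary_results.csv")
print("per-plate Z':", qc.zprime.round(2).tolist())
print(hits[hits.category == "III"].head(3)[["gene", "score", "rank"]].to_string(index=False))
print(sec[sec.confirmed][["gene", "n_concordant"]].to_string(index=False))
```

prints

```
per-plate Z': [0.87, 0.81, 0.93]
  gene     score  rank
G00007 14.473306     1
G00039  3.677670     2
G00070  3.605070     3
  gene  n_concordant
G00007             4
```

The three replicate plates show a robust assay window (Z′ ≈ 0.8–0.9,
computed from treated nontargeting vs untreated wells at ~800 cells per
well). The gene spiked to a 5× double-positive rate ranks first in
category III with a score of 14.5 % double-positive cells against a 2 %
baseline (the next ranks are counting noise), and it is the only gene
confirmed by the 3-of-4 siRNA concordance filter.

The same pipeline runs from rendered images (`mode="images"`), and every
stage is exposed on the command line:

```sh
momp-screen simulate --seed 1 --outdir sim        # plate map + TIFF fields + truth
momp-screen detect --images sim/images            # nuclei + granules per field
momp-screen phenotype --cells detected/cells_detected.csv
momp-screen score --summaries well_summaries.csv --plate-map sim/plate_map.csv
momp-screen call-hits --scores gene_scores.csv --category III --tail 0.10
momp-screen colonies --design survival_design.csv
momp-screen run-all --config run.yaml --seed 1
```

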