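# pamclone

Spatial clonality analysis of plaque-associated microglia (PAM) from
multicolor fate-mapping centroid tables.

In amyloid-model cortex, microglia carrying a stochastic four-color
Confetti reporter (nGFP, YFP, RFP, mCFP) form same-colored groups around
amyloid plaques. Given only segmented centroid tables — cells with a color
label and plaques with a volume — this package answers three questions:

1. **Which cells are plaque-associated?** A cell is PAM when its body lies
   within a contact radius (30 µm by default) of a plaque, modeled as a
   sphere of equivalent volume, or when an upstream mask-based contact flag
   is set; everything else is non-PAM.
2. **Is the color pattern clonal or random?** For every Confetti⁺ origin
   cell, same-colored neighbors are counted in concentric xy-annuli — a
   10 µm ring, then 20-µm-wide rings out to 290 µm — each spanning the full
   image depth, giving a same-color neighbor density per µm³ per annulus.
   Profiles are averaged image → replicate → group. A Monte Carlo null
   permutes Confetti labels over the positions of all Pu.1⁺ cells
   (10,000 shuffles by default) and a 98% empirical envelope is taken per
   annulus. Where the experimental confidence interval (Student-t across
   replicates) and the null envelope do not overlap, random recombination
   is rejected at P < 0.02 — as clonal excess or deficit.
3. **How big are clones and what do they touch?** Centroids are z-projected
   and tessellated (2D Voronoi, polygons clipped to the image box). Clones
   are connected components of same-colored Confetti⁺ cells under
   tessellation adjacency; the package reports cells per clone, Voronoi
   territory, clone-to-plaque contacts, and least-squares regressions of
   clone size on plaque volume, stratified at 1,000 µm³.

A synthetic-tissue generator (`pamclone.simulate`) emulates the study
design — Poisson background microglia, lognormal plaque volumes, clonal
PAM clusters whose expected size scales linearly with plaque volume, and
sparse clonally-inherited labeling — so every stage is testable without
microscopy data. A `scramble` mode assigns colors independently per cell
and serves as the null generator.

## Worked example

```bash
pamclone run --seed 5 --n-shuffles 1000 --out-dir demo
```

runs simulate → classify → ringtest → clones → regress on a default
synthetic group (8 replicates × 3 images of 600×600×100 µm) and prints

```
pipeline complete: 5 stages in demo
```

`demo/ring_test.json` then holds, per subset (`all`, `PAM`, `nonPAM`), the
observed per-annulus densities, both intervals and the calls. With the
default generator the innermost annuli read, for the pooled subset:

```
bin        observed density   null upper bound   call
(0,10]     5.94e-06           1.12e-06           excess
(10,30]    2.18e-06           6.84e-07           excess
(270,290]  2.38e-07           2.70e-07           none
```

i.e. same-colored cells are several-fold denser than the shuffled baseline
near the origin cells (the planted clones) and indistinguishable from it
at 270–290 µm. `demo/clones.csv` lists each called clone with its color,
cell count, territory (µm²) and contacted plaques;
`demo/regression.json` gives Pearson R, slope and p per volume stratum.

The same analyses run on real exported tables via the stagewise commands
(`pamclone classify --cells cells.csv --plaques plaques.csv --meta
image_meta.csv ...`); see `pamclone --help` for the schemas and flags.

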