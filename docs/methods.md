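# Methods

## Data model

All analyses operate on per-image centroid tables in micrometres, origin
at the image corner, with the hierarchy group → replicate (animal) →
image. Cells carry a Confetti color from the closed vocabulary
`{none, nGFP, YFP, RFP, mCFP}` and a Pu.1 flag (all analyzed cells are
Pu.1⁺); plaques carry a centroid and a volume in µm³. No global
registration is attempted: every statistic is computed per image and then
averaged up the hierarchy, so image-local coordinates suffice.

CSV is canonical. Floats are written as their shortest exact
representation and read back with round-trip parsing, so
`read(write(T)) == T` holds exactly; this is also what makes pipeline
outputs byte-reproducible for a fixed configuration and seed.

## PAM classification

Only centroid and volume survive tabulation, so a plaque is modeled as a
sphere of radius `r_p = (3V/4π)^(1/3)` and the cell–plaque distance is the
Euclidean centroid distance minus `r_p`, floored at zero. A cell is PAM
when this surface distance is ≤ 30 µm (inclusive — "within") for any
plaque of its image, or when an upstream mask-derived `plaque_contact`
flag is present and set (the flag wins, since it encodes geometry the
sphere model cannot). Distance to the centroid instead of the surface is
available behind a flag; surface is the default because large plaques
would otherwise swallow their halo. Images without plaques classify as
100% non-PAM, mirroring plaque-free control tissue.

## Ring-density clonality test

For each Confetti⁺ origin cell, same-colored Confetti⁺ neighbors are
counted in annuli of xy-distance `(0,10], (10,30], …, (270,290]` µm —
a first ring of 10 µm, then 20-µm increments. z is ignored: the counted
volume is the cylindrical shell `π(r₂²−r₁²)·Lz` through the full image
depth, and the per-annulus statistic is the mean over origin cells of
count divided by shell volume (µm⁻³). Annulus membership is half-open on
the right so distances partition without double counting. Neighbors must
match the origin's color; colors are pooled by summation and never
compared across. Per-image profiles are averaged per replicate and then
per group (two-stage mean, never pooled over images), with a Student-t
interval across replicate means at the 98% level as the experimental CI.
A single replicate leaves the CI undefined and flagged.

The null hypothesis is random recombination: colors carry no positional
information. It is simulated by permuting the Confetti labels uniformly
over the positions of the subset's Pu.1⁺ cells, independently per image —
position multiset and per-color counts are invariant, only the pairing is
randomized. For each of `n_shuffles` rounds (10,000 by default; a warning
is emitted below 100) the full two-stage group profile is recomputed, and
the envelope is the pair of empirical 1% and 99% quantiles per annulus
(numpy's linear/type-7 interpolation, recorded in the output metadata).
Shuffle `i` of image `k` uses the dedicated substream `(seed, k, i)`, so
envelopes are reproducible and insensitive to the shuffle count prefix.
Where the experimental interval and the envelope do not overlap the null
is rejected at P < 0.02, as *excess* (experimental lower bound above the
null upper bound — clonality) or *deficit* (the reverse); any undefined
interval yields *none*.

No edge correction is applied to annuli truncated by the image border:
the null is computed in the identical geometry, so border effects cancel
in the comparison. The decision is run separately for the subsets `all`,
`PAM` and `nonPAM`; with a subset, both the origins/neighbors and the
permutation pool are restricted to that compartment (cross-compartment
permutation was considered and rejected as mixing two populations with
different spatial structure; the subset is recorded in every output).
Whether the reported quantity is a density per annulus area or volume is
a free choice; volume (with the image depth Lz) is implemented and all
outputs are labeled µm⁻³.

For repeated shuffling the implementation precomputes, per image, the
pairwise annulus-index matrix and the same-color block mask of the sorted
color multiset; a shuffle then reduces to drawing random positions for
that multiset. This is equivalent in distribution to permuting the label
vector, and the underlying statistic is unit-tested against the public
profile computation.

## Voronoi clone calling

Cell and plaque centroids of one image are z-projected (orthographic; z
discarded) and tessellated. The diagram is computed on the seeds plus
their mirror images across the four box edges, which clips every polygon
exactly to the image rectangle — polygon areas tile the box to numerical
precision (asserted at 1e-6 relative error). Two seeds are adjacent when
they share a ridge longer than ε = 1e-9 µm; degenerate point contacts do
not count. Coincident seeds are separated by deterministic ~1e-6 µm
offsets; seeds are nudged 1e-6 µm inside the box so none coincides with
its own mirror.

Clones are connected components of Confetti⁺ cells under same-color
adjacency. Confetti⁻ cells and plaques are seeds — they shape the mesh
and can break contact between labeled cells — but are never members.
Every Confetti⁺ cell therefore belongs to exactly one clone (singletons
allowed). Clone territory is the summed member polygon area in µm²
(× Lz on request, when a volume is wanted); whether a mask-derived volume
would differ is unknowable from centroid tables, so the Voronoi area is
implemented and labeled as such. A clone contacts a plaque when any
member polygon shares an edge with the plaque polygon; the package emits
contact pairs, plaques-per-clone, clones-per-plaque and the fraction of
plaques contacted by ≥ 2 clones. Plaques enter as single point seeds by
default — volume is carried as an attribute — with an optional `disc`
mode that rings each plaque with perimeter seeds at the equivalent-sphere
radius and merges the resulting polygons. Border polygons are retained
and flagged (`touches_border`).

## Regression

Each (clone, contacted plaque) pair is one data point — a clone touching
k plaques contributes k points — with x the plaque volume and y the clone
cell count (territory behind a flag). Fits are ordinary least squares
with Pearson R and a two-sided t test on n−2 df, for all pairs and
stratified at 1,000 µm³ (ties to the small stratum). Below 3 pairs the
p value is undefined and flagged. Pairs are pooled across images with
the image id retained. An auxiliary summary reports, per image, the
fraction of PAM clones (components among Confetti⁺ PAM cells) adjacent
to a same-colored Confetti⁺ non-PAM cell.

## Synthetic tissue generator

The generator emulates the study design, not the microscopy: it produces
centroid tables directly (no voxel masks or rendered images) for a group
of `n_replicates × n_images` images.

Per image: plaque count ~ Poisson(intensity × volume) with uniform
centroids and lognormal volumes; background microglia ~ homogeneous
Poisson; per plaque, a clonal cluster of Poisson(slope × volume) cells
placed isotropically at the plaque surface, radial spread |N(0, R/2)|
truncated (resampled) at the clone radius R. All positions get Gaussian
jitter and are clipped into the box (a projection, so clone-to-plaque
distances never grow). Labeling is per founder lineage with probability
`label_prob`, one color per labeled lineage from `color_weights`;
`scramble` labels cells independently with the same marginals — the null
generator. Founder ids are retained purely so tests can score clone
recovery; no analysis reads them. Randomness uses per-image substreams
`(seed, stream, image_index)` with separate streams for plaques,
positions and labels, so adding images never reshuffles earlier ones.

Defaults (one image 600 × 600 × 100 µm): 15,000 Pu.1⁺ cells and 800
plaques per mm³ — an aged, heavily plaque-laden amyloid-model frontal
cortex — plaque volumes lognormal with ln-mean 5.8 and ln-sd 0.5 (median
≈ 330 µm³, upper tail past 1,000 µm³), clone slope 0.01 cells/µm³ (mean
clone ≈ 4 cells, matching reported clone-size ranges), clone radius 25 µm
(clones live inside the 30-µm PAM shell), labeling probability 0.1,
color weights (0.15, 0.35, 0.35, 0.15) reflecting the unequal frequency
of the four recombination outcomes, positional jitter 1 µm, and
8 replicates × 3 images per group — replicate counts of the order of the
animal cohorts the design uses. No quantitative clone-growth kinetics
are published for this system, so the slope and radius are stated model
knobs, not fitted values. The ln-sd is deliberately moderate: the clone
model is linear in volume with no saturation, and a heavier volume tail
would make the within-clone pair count so dispersed across replicates
that no replicate-level test could serve as a positive control.

What the generator does *not* emulate: plaque shapes (spheres only),
process-level contact, spatial inhomogeneity of the background,
clone-size saturation at large plaques, and segmentation errors. Passing
tests therefore demonstrate correctness of the statistics under the
stated point-process model, not robustness to real-microscopy artifacts.

## Validation studies

* **Null calibration** (`calibration.scrambled_operating_characteristics`):
  300 scrambled-label groups of 3 replicates × 3 images, 1,000 shuffles,
  98% envelopes. Reported: the per-annulus clonality-call rate (the
  decision requires non-overlap of two intervals, and the t interval at
  2 df is wide, so the realized rate sits far below the nominal 2%) and
  the envelope's empirical coverage of the observed group density
  (≈ 98% by exchangeability of the observed data with the shuffles under
  per-cell random labeling).
* **Planted-clone power** (`calibration.planted_clone_power`): 100
  clonally-labeled groups at full defaults; success means a call in
  (0,10] or (10,30] and silence in (270,290].
* **Slope recovery** (`calibration.slope_recovery`): 200 images; pairs are
  founder-lineage sizes per plaque *including zero-size lineages* — using
  only observed clones would zero-truncate the Poisson sizes and bias the
  slope low by more than 3 SE.
* **Clone recovery**: with sparse labels (2%) and compact clones (10 µm)
  ≥ 90% of labeled founder lineages map 1:1 (Jaccard > 0.8) to called
  clones; the rate degrades monotonically with labeling density as
  same-color collisions merge neighboring lineages. At the default 10%
  labeling collisions alone put the rate below 90%, which is why the
  sparse setting is the stated premise of this check.

Problem sizes above (group counts, shuffle counts, image counts) are the
study sizes at which these properties are asserted in the test suite;
they were chosen to give Monte Carlo standard errors comfortably inside
the asserted tolerances.

## Known limitations

The sphere model understates contact for irregular plaques; Voronoi
territory is a plane-projected proxy for occupied volume; the clonality
test compares two marginal intervals rather than running a joint test,
which is conservative; and clone
calling cannot distinguish two same-colored lineages that are spatially
adjacent — an identifiability limit of the reporter, not of the
implementation.
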