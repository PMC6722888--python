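# Methods

`imcprofiler` reimplements, as a tested library, the image-based analysis
workflow used to profile drug effects on cultured cells by imaging mass
cytometry (IMC): multichannel ion-count images are segmented into single
cells, quantified per channel, normalized, embedded, classified into nuclear
phenotype classes by gentle boosting, and compared across conditions by
multiparametric Pearson similarity. Because real IMC acquisitions of this
kind are not publicly deposited, the package ships a ground-truthed
synthetic generator that plants the reported treatment effects at known
magnitudes; every downstream stage is validated against that truth.

## Synthetic data model

Each region of interest (ROI) is a 500 x 500 um field at 1 um/pixel with 29
isotope channels (two Ir DNA intercalators, viability/IdU, nuclear
cell-cycle and signalling markers, cytokeratins, surface CD/adhesion
markers, and a carrier blank). Cells are non-overlapping ellipses placed by
dart throwing to a target density of 600 cells/mm^2, with area ~
N(180, 40^2) um^2 (floored at 40 um^2), random orientation, axis ratio ~
U(0.6, 0.95), and a concentric nucleus covering 35% of the cell area. Each
cell draws one of six nuclear classes — pHistone3+, pH2A.X+, p53+,
cyclinD3+, Ki-67+, negative — from the condition's mixture.

Signal is deposited per compartment: nuclear channels inside the nucleus
ellipse, membrane channels in a 2-px rim inside the cell boundary,
cytoplasmic channels in cell-minus-nucleus. Pixel values are independent
Poisson draws with rate = background (0.2 counts/px) plus the covering
cell's channel rate. A class-defining marker runs at 30 counts/px against
baselines of 0.5–3; these absolute scales are fabricated (no published
per-marker ion-count scales exist) but chosen so that signal-to-background
matches what segmentable IMC data of cultured monolayers looks like.
Cell-to-cell expression variability is log-normal with CV 0.3. Three
latent factors plant correlation structure: one shared by
pHistone3/Ki-67/p4E-BP1 within mitotic cells, one shared by the surface CD
markers in all cells, and one shared by the two Ir isotopes (per-cell DNA
content; this third factor is what makes the two intercalator channels
cluster together, as they do in real data).

Planted condition effects (defaults; DMSO is identical to nontreated):

| condition  | mixture changes                  | expression changes            |
|------------|----------------------------------|-------------------------------|
| nocodazole | pHistone3+ 0.04 -> 0.12 (3x)     | pHistone3 x2 in mitotic cells |
| etoposide  | Ki-67+ 0.15 -> 0.30, pH2A.X+ 0.20| pH2A.X x5 in every cell       |
| EGF        | none                             | area x1.8, membrane rates x1.5|

The default experiment mirrors the emulated acquisition layout: two
replicate ROIs per compound, one each for the two controls (8 ROIs, ~1200
cells). All randomness derives from one master seed through per-ROI seed
sequences, so the experiment is reproducible bit-for-bit.

What the generator does **not** emulate: channel spillover (deliberately,
since the emulated panel showed no strong contamination), ablation/drift
artefacts, touching or overlapping cells, tissue context, dead-cell
morphology, and 3D structure. Passing tests therefore demonstrate that the
pipeline recovers planted effects from clean monolayer-like count images,
not that it is robust to crowded tissue or acquisition artefacts.

## Segmentation

Two-stage primary/secondary object detection. Nuclei: the DNA channel is
log1p-transformed, Gaussian-smoothed (sigma 1 px), thresholded by global
Otsu (log1p because Poisson counts are heavily skewed), hole-filled, then
declumped by a watershed seeded at Euclidean-distance-transform maxima at
least `min_diameter` apart; objects outside 6–30 px equivalent diameter are
dropped and labels made consecutive. Cells: foreground is the Otsu-
thresholded cytoplasmic channel united with nucleus pixels; a watershed on
the inverted smoothed cytoplasmic intensity, seeded by the nuclei and
masked to the foreground, assigns every foreground pixel to a nucleus. This
seeded-watershed secondary stage replaces the regularized propagation of
CellProfiler's `IdentifySecondaryObjects`; on monolayers with background
gaps between cells the two behave equivalently, and the watershed variant
is simpler to verify. The module contains no randomness. Accuracy is
scored as pixel-level binary precision/recall against truth masks; on
default synthetic ROIs nuclei precision is ~0.97 and cell precision ~0.93.

## Quantification

Per cell: mean intensity of every channel over the whole-cell mask (a
single mean per marker per cell, regardless of compartment), area,
perimeter (the weighted boundary-step estimator of
`skimage.measure.regionprops`), major/minor axis lengths and eccentricity
of the second-moment ellipse, and the unweighted pixel centroid. Lengths
are in um using the stack's pixel size. Axis lengths are measured on cell
objects (the choice between nucleus and cell objects was open; cells match
the "cell size parameter" reading).

## Statistics

Z-scores are computed per channel over the pooled comparison set — not per
ROI — so spatial heat maps of different ROIs share one scale. Values are
first clipped at the 99th percentile (hot-pixel robustness; configurable or
disabled), then standardized with the sample SD; constant columns map to
zeros. Condition comparisons use the two-tailed Mann–Whitney U test (exact
null when the pooled sample is <= 12 and tie-free, otherwise normal
approximation with tie and continuity corrections); an unpaired t-test is
available because the original figure legends cite one while the methods
text names Mann–Whitney. P values are reported raw; no multiplicity
correction is applied, and the output notes this.

## Classification

Fast Gentle Boosting, written from scratch: per class (one-vs-rest,
y in {-1,+1}, uniform initial weights), each of 50 rounds fits every
candidate stump f(x) = a·1[x > theta] + b by weighted least squares
(candidate thresholds are midpoints of sorted distinct feature values; b is
the weighted mean of y on the left, a the right-minus-left difference) and
keeps the stump with the lowest weighted squared error, ties broken toward
the lowest feature index then lowest threshold. Weights update
w <- w·exp(-y f(x)) and renormalize. The comparison at theta is strict, so
a value exactly at the threshold takes the b branch. Scoring sums stump
responses; argmax wins, ties resolving to the earlier class in the
canonical order. Features default to all channel means plus the four size
parameters. Accuracy is assessed by stratified 5-fold cross-validation
with pooled out-of-fold predictions, reported as a row-normalized confusion
matrix. The mitotic index is the per-condition fraction of cells predicted
pHistone3+, pooled over replicate ROIs and computed with exact rational
arithmetic before float conversion.

On synthetic data, training labels come from the generator's truth table;
there is no interactive annotation step.

## Embedding

t-SNE (PCA initialization, perplexity 30, fixed recorded seed) on z-scored
markers plus z-scored size parameters. Feature names are sorted before
fitting, making the embedding invariant to input column order. The
original work specifies none of these hyperparameters; defaults follow
common practice and are recorded in the result object. Embedding is pooled
across all ROIs to reproduce a combined condition map.

## Similarity analysis

Within a classified population (default: predicted-mitotic cells),
pairwise Pearson correlation is computed between raw (non-normalized)
parameter columns; constant columns yield missing values that are never
coerced to zero. Parameters are ordered by complete-linkage agglomeration
on distance 1 - r; the dendrogram is exported as Newick, and correlations
strictly above 0.3 become edges of an undirected parameter graph
(node-link JSON and GraphML).

Cells are unpaired across conditions, so the cross-condition matrix
correlates *matched rank-quantile vectors*: each condition's cells are
reduced, per parameter, to the (i+0.5)/n quantiles at a common n (the
smallest per-condition count), and the full (condition x parameter) block
matrix is correlated and clustered as one. Duplicating a condition
reproduces its within-block exactly. A known limitation follows from
Pearson's affine invariance: pure per-parameter fold-changes (such as the
planted EGF membrane up-regulation) leave quantile vectors perfectly
correlated and are invisible to this comparison, while distribution-shape
changes (class-mixture shifts, variance changes) do register. Quantile
vectors of any parameter are monotone, so cross-parameter blocks sit at
high baseline correlation; the comparison is relative, not calibrated.

## Pipeline

`run_pipeline` executes simulate -> segment -> quantify -> stats -> embed
-> classify -> similarity from a versioned YAML config (unknown keys are
errors). One master seed fans out to per-stage, per-ROI children via seed
sequences keyed by stage name, so stages can be re-run in isolation. The
manifest records the config hash, per-stage object counts (including the
cell-table-vs-mask count conservation check) and SHA-256 checksums of all
numeric artifacts; re-running the same config and seed reproduces them
bit-for-bit. A failing stage writes a FAILED marker naming the stage and
re-raises with context.

## Problem sizes and acceptance checks

The default desk-scale experiment (8 ROIs of 500 x 500 um at 600 cells/mm^2,
~1200 cells) is the package's own choice of a size at which every planted
effect is statistically recoverable: the rarest class (mitotic cells under
control, expected ~6 per control ROI) is the binding constraint. The
mitotic-index ratio check pools the two control conditions (nontreated +
DMSO, same planted mixture) and three seeds before forming the
nocodazole/control ratio, because a single 150-cell control ROI carries
~40% binomial CV on that denominator — the pooled estimator tests the same
threefold effect at a variance the experiment actually supports.
`scripts/acceptance.py` recomputes the cross-validation confusion-matrix
minimum diagonal and the whole-cell segmentation precision from scratch at
any seed.

## Known limitations

* The classifier is near-perfect on synthetic data because classes are
  separated by a single high-rate marker; real phenotype boundaries are
  softer. The performance band check (diagonal in [0.5, 1]) is therefore a
  lower-bound contract, not a difficulty calibration.
* Segmentation is tuned for monolayers with background gaps; dense tissue
  would need declumping and propagation regularization this package does
  not implement.
* The cross-condition similarity procedure is one concrete choice among
  several defensible ones (see above) and is isolated behind a single
  function so it can be swapped.
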