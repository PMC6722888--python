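# imcprofiler

Single-cell phenotype profiling for imaging mass cytometry (IMC) drug
screens, with a bundled ground-truthed synthetic data generator.

IMC images cultured cells at 1 um/pixel across ~30 metal-isotope antibody
channels. This package implements the full image-analysis side of an
in-vitro drug-profiling experiment as a tested Python library:

1. **I/O** — multipage 16/32-bit TIFF stacks, unsigned 16-bit label-mask
   TIFFs, panel and per-cell CSV tables;
2. **segmentation** — nuclei from the Ir-intercalator DNA channel (Otsu on
   log1p counts + distance-transform watershed declumping), whole cells
   grown from nucleus seeds by watershed on the cytoplasmic channel;
3. **quantification** — per-cell mean intensity of every channel plus area,
   perimeter, axis lengths, eccentricity and centroid;
4. **statistics** — pooled Z-scores with 99th-percentile clipping,
   two-tailed Mann–Whitney condition tests, Z-score spatial heat maps;
5. **embedding** — t-SNE maps of marker + size features;
6. **classification** — Fast Gentle Boosting (additive regression stumps,
   one-vs-rest, implemented from scratch) over six nuclear phenotype
   classes, with stratified cross-validation confusion matrices and the
   per-condition mitotic index;
7. **similarity** — pairwise Pearson correlation of parameters within a
   classified population, complete-linkage clustering on 1 − r, and
   correlation graphs (r > 0.3) for edge-bundle rendering.

Because raw acquisitions of this design are not publicly available, the
`synthetic` module simulates drug-treated MCF-7 monolayer ROIs with known
truth: six nuclear classes, compartment-specific Poisson ion counts, and
planted treatment effects (nocodazole triples the mitotic fraction and
doubles mitotic pHistone3 signal; etoposide induces pH2A.X 5x; EGF enlarges
cells and raises membrane markers 1.5x). Every pipeline stage is tested
against this ground truth. See `docs/methods.md` for the model and its
limitations.

## The core statistic, briefly

Gentle boosting fits, per class k, an additive score
F_k(x) = sum_t [ a_t · 1(x_{j_t} > theta_t) + b_t ]
where each round chooses the stump minimizing the weighted squared error
sum_i w_i (y_i − f(x_i))^2, y_i ∈ {−1, +1}, and reweights
w_i ← w_i · exp(−y_i f(x_i)). A cell's predicted class is argmax_k F_k.
The mitotic index of a condition is (# cells predicted pHistone3+)/(# cells),
pooled over its replicate ROIs.

## Worked example

```python
import pandas as pd
from imcprofiler import classify as clf, features as ft
from imcprofiler import segmentation as seg, synthetic as syn

rois = syn.generate_experiment(master_seed=42)      # 8 ROIs, 5 conditions
truth = syn.experiment_table(rois)                  # ground-truth cell table

feats = clf.default_feature_names(truth)
model = clf.train_fast_gentle_boosting(truth, truth["true_class"], feats)

tables = []
for roi in rois:
    nuclei = seg.segment_nuclei(roi.stack)
    cells = seg.segment_cells(roi.stack, nuclei)
    tables.append(ft.extract_features(roi.stack, cells, nuclei))
scored = clf.score_cells(model, pd.concat(tables, ignore_index=True))
print(clf.mitotic_index(scored))
```

prints (seed 42):

```
 condition  n_cells  n_mitotic  mitotic_index
nontreated      150         10       0.066667
      DMSO      149          2       0.013423
       EGF      300         12       0.040000
 etoposide      298          7       0.023490
nocodazole      298         30       0.100671
```

The nocodazole index sits about threefold above the mean of the two
controls (0.101 vs 0.040) — the planted mitotic-arrest phenotype recovered
through segmentation, quantification and classification rather than read
off the truth table. The `examples/` directory contains one short script
per capability (simulation + segmentation scoring, drug-effect statistics,
classification + mitotic index, similarity clustering, t-SNE maps); each
prints the numbers it computes and what they mean. A thin CLI mirrors the
stages (`imcprofiler simulate|segment|quantify|stats|embed|classify|
similarity|run`), with `run` driving the whole pipeline from a YAML config
into a reproducible, checksummed output bundle.

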