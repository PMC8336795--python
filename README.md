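# stiffmorph

Single-cell, image-based morphological profiling of carcinoma cells across
substrate stiffness — as a fully synthetic, ground-truthed, testable
pipeline.

## The problem

Mesenchymal breast-carcinoma cells (MDA-MB-231-like) respond to the
stiffness of their substrate — from soft parenchymal tissue (~0.2–2 kPa) to
bone-like rigidity (~64 kPa) — by remodelling their shape, their biomarker
expression and, on the stiffest substrates, by forming multicellular
clusters. Quantifying this response at single-cell resolution takes a long
chain of image analysis: segmentation of membrane/DNA channels, extraction
of a large morphological + contextual feature catalogue, unsupervised
discovery of morphological cell types ("morphs"), supervised classification
of cluster-member cells, and a statistical layer relating everything to
stiffness. Every link of that chain can fail silently.

`stiffmorph` is for computational biologists and image-analysis developers
who want that chain as reusable, deterministic, *tested* components. Because
the underlying microscopy data of such studies is rarely deposited, the
package ships a synthetic fluorescence-scene generator whose population
statistics emulate the study design — three morph archetypes with
stiffness-dependent mixtures, clumps only at 64 kPa, calibrated marker and
NCR trends — so the whole pipeline is exercised end-to-end against known
ground truth.

## The method

Per cell the pipeline measures exactly **150** morphology + context features
(35 shape descriptors × {cell, nucleus, cytoplasm}, 25 Zernike magnitudes,
5 engineered features including the nuclear–cytoplasmic ratio
NCR = A_nucleus / A_cytoplasm and polarity = ‖c_cell − c_nucleus‖, and 15
context features), plus **69** features per marker channel (intensity, edge,
radial, Haralick texture) — **140** for the two-marker group including the
cytokeratin/vimentin ratio CVR. Morphs are found by Ward clustering of the
z-scored single-cell table, with the cluster count chosen by 30 × 30%
subsampled silhouette / Davies–Bouldin consensus; features are pruned at
pairwise Pearson |r| ≤ 0.8 and a randomised-search random forest (5-fold CV,
class-frequency-weighted F1 on a 10% hold-out) classifies the clump-member
cells that were excluded from clustering. Associations with stiffness use
Spearman's ρ, Kendall's τ and distance correlation; group contrasts use
Welch's t-test. See `docs/methods.md` for the full model description.

## Worked example

```python
from stiffmorph.pipeline import profile_dataset, analyze_dataset

ds = profile_dataset("paper-scale", seed=1)   # generate -> segment -> profile
print(ds.n_retained, ds.n_clumped)            # 826 84

res = analyze_dataset(ds.morphology_table, seed=1, k=3)
print(res.chosen_k)                           # 3
print(round(res.classifier_report.weighted_f1, 3))   # 1.0
print(round(res.clumped_morph3_pct, 1))       # 54.8
print(round(res.ncr_association["spearman"], 3))     # -0.315
```

Those numbers mean: the packaged paper-scale dataset yields 910 profiled
cells of which 84 are clump members (leaving 826 single cells); the
subsampled validity indices select three morphotypes; the tuned forest
classifies held-out single cells essentially perfectly; 54.8% of clumped
cells are classified as the small-round morph 3 (the generator's designed
share is 56%); and NCR is the feature most strongly rank-correlated with
stiffness (|ρ| ≈ 0.31, higher NCR on softer substrates with a maximum at
2 kPa).

The same workflow is available from the shell:

```bash
stiffmorph run-all --profile paper-scale --seed 1 --out run1 --check
stiffmorph generate --profile demo --seed 1 --out scenes/      # stage by stage
stiffmorph segment --in scenes/ --out seg/
stiffmorph profile --masks seg/ --images scenes/ --out features.csv
stiffmorph morphs --features features.csv --k auto --seed 1 --out morphs/
```

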