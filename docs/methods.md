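# Methods

`stiffmorph` implements a single-cell, image-based morphological-profiling
workflow for adherent carcinoma cells cultured on substrates of graded
stiffness, together with a synthetic-scene generator that emulates the
statistical structure of such an experiment so the whole pipeline can be
exercised, tested and calibrated without microscopy data.

## The synthetic experiment

The generator models five substrate stiffness levels (0.2, 2, 16, 32 and
64 kPa, spanning soft parenchymal to bone-like tissue) and two
immunostaining groups imaged in parallel: an E-cadherin group and a
cytokeratin + vimentin group, each alongside a DNA (nuclei) channel and a
membrane channel. Each field of view is a 16-bit multi-channel image with a
physical pixel size.

### Cell shapes

Cells belong to one of three morphological archetypes ("morphs"):

1. **irregular / lamellipodial** — intermediate footprint (900–2200 µm²),
   elongated (eccentricity 0.60–0.90), 2–5 wide lobes plus strong
   high-frequency boundary roughness;
2. **large flattened** — large footprint (1800–3600 µm²), smooth outline,
   mild elongation;
3. **small round** — small footprint (180–450 µm²), near-circular.

Outlines are star-convex radial polygons `r(θ) = r0·(1 + Σ lobes +
roughness)` traced at 256 vertices: this guarantees simple closed contours,
exact analytic area control (radial rescaling), and direct control over
circularity. Morph 1 additionally carries a constructive irregularity
guarantee: extra ripple harmonics are superimposed until the outline's
analytic circularity falls below 0.45, so rasterised morph-1 circularity
stays clearly below the smooth morphs at any seed. Nuclei are ellipses of
nearly stiffness-invariant area (lognormal, median 55 µm², truncated to
35–85 µm²) aligned with the cell's long axis; a per-direction containment
check walks the desired centroid offset (cell polarity) inward until the
ellipse fits fully inside the outline with ~1 µm clearance.

### Mixtures and clumps

Morph proportions vary with stiffness (defaults per level in
`synthetic.DEFAULT_MORPH_MIXTURES`), with the small-round morph peaking at
2 kPa and the spread morphs dominating stiffer substrates. Multicellular
clumps occur only at 64 kPa; clump composition defaults to
(0.40, 0.04, 0.56) for morphs (1, 2, 3). Mixtures are realised by
largest-remainder **quota allocation** rather than multinomial sampling:
the stated composition is treated as a study condition, not a random
variable, which removes ~5-point multinomial noise from composition-recovery
checks at n = 84. Clump members are attached one at a time by sliding along
random directions until just before pixel overlap (gap ≤ 1 px, i.e.
touching under the 8-neighbourhood rule); a deterministic chain layout is
the fallback when random attachment fails.

### Rendering

Per channel: background 1000 counts; nuclei at 30 000; membrane fill at
22 000 (nucleus region ×0.85); marker interior plateau at
8000 × stiffness multiplier × per-cell lognormal (σ_log = 0.25), with a
2-px boundary band at an edge multiplier; additive Gaussian read noise
σ = 600 counts (~2% of the dynamic range); clipped, rounded 16-bit output.
Marker multipliers encode the designed trends: E-cadherin maxima at 2 and
64 kPa (and ×1.3 in small-round cells; clump members ×0.7 total but a much
brighter boundary band), vimentin peak at 2 kPa, cytokeratins rising over
16–64 kPa (so the cytokeratin/vimentin ratio dips at 2 kPa), and elevated
edge-localised E-cadherin in clumped and 2-kPa cells.

### Calibration

Two quantities are calibrated once, at the level of the latent area model,
and then frozen as documented constants:

* a stiffness-dependent cytoplasm scale factor
  (`archetypes.CYTOPLASM_STIFFNESS_SCALE`) tuned so that the absolute
  Spearman correlation between stiffness and the nuclear-cytoplasmic ratio
  (NCR = nucleus area / cytoplasm area) is ≈ 0.31 at the paper-scale
  population size (n = 826 single cells), while keeping the NCR median
  profile's local maximum at 2 kPa and minimum at 32 kPa;
* the morph mixtures above, which set the composition trends and the
  cluster structure.

The Monte-Carlo calibration tests (20 seeds) operate on the latent
distributions directly, which is exact for these quantities and keeps the
test suite fast.

### The paper-scale profile

The packaged `paper-scale` profile contains exactly 910 cells: 826 single
cells split as evenly as possible over the 10 stiffness × staining
conditions, plus 84 clump members at 64 kPa (42 per staining group, groups
of 4–7 cells so every scene supports third-nearest-neighbour distances).
Scenes are 256 × 256 px at 1.0 µm/px with ≤ 7 planned cells each
(placement overflow spills into fresh scenes of the same condition, so the
totals are exact at any seed); `SceneSpec` defaults to 0.25 µm/px and
1024 × 1024 px for single high-resolution scenes. The coarser profile
resolution keeps a full run (generation, segmentation, profiling of 910
cells, clustering, classifier search) around three minutes while leaving
every recovery target intact.

## Segmentation

Gaussian smoothing with σ = 0.25 µm (converted to pixels), global Otsu
thresholding of the membrane and DNA channels, hole filling, removal of
objects < 20 µm², 8-connected labelling. Each nucleus is assigned to the
cell component containing its centroid; components with ≥ 2 nuclei are
split by nucleus-seeded watershed on the distance transform. Retention
rules: border-touching cells and touching *pairs* are excluded from the
single-cell analysis set (kept as context for neighbour statistics, with a
reason code); touching groups of ≥ 3 cells (a configurable threshold — a
pair may be a transient contact) are flagged **clumped**, profiled, and
analysed separately. The reference workflow resolved adjacent cells by
manual editing; this module substitutes the reproducible automatic rule
above, and its fidelity is quantified against ground truth (union-mask IoU
≥ 95%, per-cell areas within 5%, clump-flag agreement) rather than assumed.

## Feature catalogue

Exactly 150 morphology + context features per cell:

* 35 scalar shape descriptors × 3 objects (cell, nucleus, cytoplasm =
  cell minus nucleus) = 105,
* 25 Zernike magnitudes (degree ≤ 8) of the cell silhouette,
* 5 engineered features (NCR, polarity, nucleus/cell area ratio, cytoplasm
  area fraction, perimeter/area ratio),
* 15 context features computed against *all* cells in the scene, including
  excluded ones (touching-neighbour count, shared-boundary fraction and
  length, 1st–3rd nearest-centroid distances and their mean, six
  local-density counts at 25–200 µm, inverse-distance sum, nearest-cell
  area ratio).

Per marker channel, exactly 69 features: 17 intensity statistics, 9 edge
statistics (including the edge fraction = 100 × boundary signal / total
signal), 2 mass-displacement features, 15 radial-distribution features
(5 equal-width rings × fraction / relative mean / CV), and 26 Haralick
texture features (13 GLCM statistics × 2 offsets, direction-averaged,
64 grey levels over the object's range). The two-marker group adds the
cytokeratin/vimentin mean-intensity ratio (CVR) and the per-cell pixel
correlation: 2 × 69 + 2 = 140. The exact member list of such catalogues is
tool-specific; this decomposition reproduces the catalogue *totals* while
keeping the named key features (area, circularity, compactness,
eccentricity, perimeter, NCR, polarity, neighbour counts, edge fraction,
CVR) as explicit members. Catalogue counts are enforced at table assembly
(hard failure on drift) and by a static test.

Numerical conventions, fixed package-wide: boundary pixels are object
pixels with a 4-connected neighbour outside the object; the perimeter is
the 4-direction Crofton estimator `π/8·(c_h + c_v + (c_d1 + c_d2)/√2)`
(transition counts along rows, columns and the two diagonal families) —
chosen because it is nearly unbiased on rasterised disks, so circularity of
a disk is ~1; convex hulls are taken over pixel corners so convex objects
have solidity 1; moments use the pixel-centre point-mass convention; the
annular cytoplasm object is measured against the outer (cell) boundary
only; GLCM statistics of constant-intensity objects define 0/0 cases as 0.
Features never encode absolute image coordinates, and geometric features
are reported in µm/µm² or dimensionless. Orientation and the bounding-box
side lengths are the only frame-dependent descriptors (exempt from the
90°-rotation invariance property).

## Morphotype discovery

Features are z-scored (sample SD; zero-variance columns removed and
logged — in clean synthetic runs the touching-neighbour features of single
cells are constant and drop out here). The number of clusters is estimated
by 30 replicates of 30% subsampling without replacement: each subsample is
Ward-clustered for k = 2..6 and scored by silhouette and Davies–Bouldin;
the consensus k maximises the median silhouette (ties toward larger k,
Davies–Bouldin logged as confirmatory). A deterministic rule is required
for testing; on the packaged dataset both indices agree on k = 3.
"Smallest-variance merging" is implemented as Ward's criterion on Euclidean
distances over all z-scored features. Cluster labels are canonicalised:
for k = 3 the least-circular cluster is morph 1, the larger-footprint of
the remaining two is morph 2, the small round one morph 3 (general k:
descending median cell area). Medoids minimise mean within-cluster
distance (ties to the lowest cell id). Feature importance uses the
k-nearest-neighbour mutual-information estimator (3 neighbours, fixed
seed, clipped at 0). Morph composition per stiffness is computed per scene
first; means and t-based 95% CIs are taken across scenes.

## Classification

Pearson pruning removes, iteratively, one member of the worst-correlated
pair (|r| > 0.8): the member with the higher mean absolute correlation to
all others, ties to the later column. The random-forest classifier is
tuned by randomised search (50 draws over tree count, depth, minimum leaf
size and feature subsampling) with stratified 5-fold cross-validation on a
90% training split, refit on the full training split, and evaluated by the
class-frequency-weighted F1 on the held-out 10% (the classes are unequal in
size). Clumped cells are z-scored with the single-cell statistics and
classified with the trained model; their composition is summarised with the
same scene-grouped CIs.

## Statistics

Stiffness associations report Spearman's ρ and Kendall's τ-b (midranks for
ties) and the distance correlation (biased double-centering estimator, able
to capture non-monotone dependence). Group comparisons use the unpaired
two-tailed Welch t-test (Satterthwaite degrees of freedom) with star codes
* p < 0.05, ** p < 0.01, *** p < 0.001; identical constant groups define
p = 1. CIs are t-based at 95%, for proportions computed on scene-grouped
values. No multiple-testing correction is applied by default (raw stars
are reported); a Benjamini–Hochberg helper is available. The
adhesion-array correlation defaults to Pearson with a Spearman switch (the
two conventions coexist in the source workflow's description). PCA uses
the full SVD on z-scored input; scores are reproducible up to sign.

## What the synthetic data does and does not show

The generator reproduces the *population statistics* the workflow is meant
to recover: three separable morph archetypes, stiffness-dependent
mixtures, clump formation at 64 kPa only, marker mean and edge-fraction
trends, and an NCR–stiffness rank correlation of ≈ 0.31. It does not
emulate optical physics (no point-spread function, photobleaching or
z-structure), cell-shape continua between morphs (real populations show a
morphological spectrum; the archetypes here are well separated by design so
recovery is decidable), confluent growth, or staining artefacts. Passing
the recovery suite therefore demonstrates that the *pipeline* measures,
clusters and classifies correctly under known ground truth — not that the
biological effect sizes would be recovered from arbitrary real microscopy.

## Determinism and problem sizes

A single integer seed drives everything through spawned NumPy
`SeedSequence` children (scene planning, per-scene generation, subsampling,
search and split seeds); identical (profile, seed) pairs give bit-identical
images, tables and results. Default problem sizes: 910-cell paper-scale
dataset on ~136 scenes of 256² px, 30 × 30% validity subsampling, 50-draw
randomised forest search — a complete run takes a few minutes on one core.

## Known limitations

* The automatic segmentation is tuned for well-separated synthetic scenes;
  heavily confluent real images would need watershed seeding or manual
  curation beyond the clump rule.
* Context features of the image-free fast path use a size-aware position
  model rather than true placement, so their fine distribution differs
  slightly from the image path (they are deliberately non-discriminative
  for morphs).
* Welch tests across adjacent stiffness levels are reported without
  multiplicity adjustment, mirroring the raw-star convention.
* Hu moments and Zernike magnitudes are near machine precision for some
  small objects; they are z-scored before use, which can amplify estimator
  noise for nearly constant columns (zero-variance columns are removed,
  near-zero-variance ones are retained).
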