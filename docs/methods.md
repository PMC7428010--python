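# Methods

This note documents the models, algorithms and numerical choices behind
`angiomorph`, what the synthetic generators do and do not emulate, and
the known limitations.

## Image → skeleton graph

Segmentation is Gaussian background subtraction (σ = 25 px), a global
Otsu threshold on the flattened image, removal of objects < 50 px,
filling of holes < 25 px, 1-px skeletonisation, and iterative pruning of
terminal spurs shorter than 5 px (tips are only trimmed on structures
that contain a branch point, so plain lines are never eaten). An empty
or constant image yields an all-false mask — "no network detected" is a
result, not an error. All thresholds live in `RunConfig`.

Pixel adjacency is 8-connected with one correction: a diagonal link is
dropped when the two pixels share an orthogonal skeleton neighbour.
Thin skeletons otherwise contain 1-px triangles (a diagonal shortcut
doubling an orthogonal step) that would read as spurious cycles.

Vertices are connected clusters of skeleton pixels with ≠ 2 neighbours
(branch clusters and tips), with the cluster centroid as the coordinate;
edges are maximal degree-2 pixel paths between vertices, carrying their
ordered path and Euclidean polyline length (floored at 1 px). A
connected component with no such pixels is an isolated ring: one
representative vertex with a self-loop edge. Degree-2 points are thus
contracted away by construction; 2-way junctions can still arise where
pruning removed a spur at a former branch point, which is why the
feature catalog carries an explicit 2-way junction count.

### Element taxonomy

Node degree is the number of incident tubes (a self-loop counts once, so
an isolated ring's vertex is an extremity and the ring itself an
isolated tube). Junction = degree ≥ 2, extremity = degree 1. Master
junctions are transitive-closure groups of junctions within
`fusion_radius_px` (default 5 px; "close proximity" is not quantified in
the assay literature) with the member centroid as coordinate. A tube is
a segment / twig / isolated tube according to whether 2 / 1 / 0 of its
endpoints are junctions; a segment is a *master segment* when each of
its endpoint junctions touches at least one other segment. The
element-conservation identities (tube classes partition tubes; junctions
plus extremities partition vertices) are asserted property-style over
random synthetic networks; master-junction fusion is an additional
aggregation and does not change the base counts.

### Meshes as planar faces

Meshes are bounded faces of the planar embedding, computed from the
rotation system: half-edges at each vertex are ordered by their
departure angle (estimated from the first few path pixels, ties broken
by edge id), and the face successor of a half-edge is the next-clockwise
half-edge after its reversal. Face boundaries concatenate the edge
pixel paths; areas are shoelace sums over pixel centres, perimeters
polyline lengths. Per component the face of largest |signed area| is
the unbounded outer face and is dropped; faces below
`min_mesh_area_px2` (default 25 px²) are discarded *after* counting, so
the pre-filter face count equals the cycle rank Σ(E_c − V_c + 1)
exactly — an identity the test suite checks on 100 random rendered
networks. A face-based rather than hole-based definition was adopted;
the two agree on skeletons, and the face-based one is well defined even
where thick tubes would merge holes.

### Thickness

Tube thickness at a centreline pixel is 2·EDT − 1 of the foreground mask
(the drawn width of a ribbon whose centreline passes through the pixel),
floored at 1 px, averaged along the path. The −1 term makes a rendered
width-w ribbon measure w rather than w + 1, so ratios of widths are
unbiased.

## The 101-feature catalog

The catalog is data, not code: 101 named descriptors in
`data/feature_catalog.json`, version-tagged, split as tube formation 12,
tube morphology 18, node 16, mesh 10, connectivity 8, symmetry 12,
topology 12, complexity 6, texture 7. The symmetry block consists of
sample (n − 1) SDs of element measurements — the spatial-homogeneity
reading of "network symmetry". A feature is NaN only when its defining
element set is empty (mean mesh area with no meshes; SDs with n < 2;
correlation of a constant image). Extraction is deterministic for fixed
input and configuration.

Numerical choices worth stating:

* **Angles** — at 3-way junctions, tube directions are tangents from the
  first `tangent_window_px` (default 5) path pixels; the three gaps
  between sorted directions sum to 360° identically. Junctions whose
  geometry includes a self-loop are skipped.
* **Topology** — distances are tube lengths on a multigraph (parallel
  tubes and self-loops kept). Closeness is (reachable count)/(Σ
  distances) within the component; betweenness is normalised; the MST is
  a spanning forest over components; mean shortest path averages over
  connected pairs only. Everything stays finite on disconnected graphs.
* **Fractal dimension** — box counting over dyadic sizes 2 … min(shape)/4
  (≥ 3 scales required), least-squares slope of log N vs log (1/s), fit
  R² reported alongside.
* **Voronoi** — cells of the junction coordinates clipped exactly to the
  image rectangle by mirroring every seed across the four frame edges;
  the cells then tile the frame, so Σ areas = frame area to machine
  precision (asserted at 1e-6 relative). Seeds on the frame edge are
  nudged 0.25 px inside so no seed coincides with its mirror.
* **GLCM** — intensities quantised to 64 levels between the image min and
  max; symmetric normalised co-occurrence matrices accumulated by numpy
  slicing for the offsets (0,1), (1,0), (1,1), (1,−1) and averaged.
  Energy is the angular second moment Σp²; entropy is Shannon in bits;
  correlation is undefined (NaN) for a constant image.

## Screen profiling

The stage machine raw → z-scored → aggregated → scaled is enforced; each
operation checks and stamps the stage, and every stage is a
deterministic function of its input. Plate-wise z-scoring uses the
sample SD of the DMSO wells (≥ 2 required per plate; a feature with zero
DMSO variance on a plate becomes missing there), which makes the DMSO
wells of each plate mean-0/SD-1 per feature by construction — asserted
to 1e-9. Replicate averaging is missing-aware; min-max scaling imputes
missing values to the feature median first and maps constant features to
0.5 with a warning. Clustering is Ward on Euclidean distances (scipy
linkage; merge heights are monotone), k is a required parameter with an
optional silhouette scan for guidance; the control-like cluster is
auto-detected as the one with the smallest mean |z| profile
(overridable). t-SNE (fixed seed, perplexity < n/3) is strictly a
visualisation; no downstream computation consumes its coordinates.

## Enrichment and structural similarity

Annotation sets are closed transitively over the specific→general term
hierarchy before testing (cycles rejected). Enrichment per (cluster,
term) is the exact hypergeometric upper tail P(X ≥ a) — one-sided,
because the question is over-representation — with terms annotating < 2
compounds excluded, followed by Benjamini–Hochberg across all tested
pairs. The Fisher tail is cross-checked in the tests against direct
binomial-coefficient enumeration on every margin with N ≤ 12 and on the
tail routine up to N = 30. Tanimoto similarity is computed on bit
matrices (empty∩empty defined as 0); z-scores standardise the
off-diagonal pairs; the structure–phenotype graph thresholds z (default
2.0, a config parameter — the threshold and fingerprint type are
consumer choices) and flags edges whose compounds share any expanded
term.

## Expression meta-analysis

Stages filter (mean expression ≥ 1.00, boundary inclusive) → per-gene
[0, 1] scaling → analyses; gene-set members lost to the filter are
logged, never silently dropped. The Braak group change reports *both*
the difference of high/low group means and their ratio: the literature
defines the statistic as a difference but thresholds it as a ratio
("fold change > 1.2"), and only the ratio can carry that name, so both
are emitted and `fold_change` is the ratio. Group bounds default to
high ≥ 5, low ≤ 3 and are config parameters (a narrower low ≤ 2
convention also circulates). Correlation p-values come from the t
distribution on n − 2 df (two-sided); the method behind published
correlation p-values is typically unstated, and this is the standard
choice. Patient clustering reuses the Ward machinery on the scaled
expression of one gene set, jointly across brain regions by default
(regions can be clustered separately via config), k = 3 by default;
high-Braak (stage 5–6) enrichment per cluster and region reuses the
exact Fisher tail.

## Synthetic generators

All generators are pure functions of (design, seed).

**Networks.** Seeds are sampled with a minimum separation (45 px) inside
a margin; edges are the Gabriel graph of the seeds (a Delaunay subset,
hence planar and non-crossing, with mesh-friendly short edges); a
spanning forest is always kept and a `mesh_fraction` of the
cycle-closing edges survives, so the planted cycle count — and by the
Euler identity the planted mesh count — is exact. Degree-2 pass-through
points with bends sharper than 100° drop their shorter edge: endothelial
tubes do not hairpin, and a rasterised hairpin is a blob the
skeletonizer cannot resolve. Tubes are straight strokes of
`tube_width` px (default 5) at fixed intensity with optional Gaussian
noise. Ground-truth counts are taken on the degree-2-contracted planted
graph, because extraction contracts degree-2 points. Presets: `tree`,
`honeycomb` (an exact hexagonal lattice; m×n cells give m·n meshes),
`dense_mesh`. Round-trip recovery (extract the rendered image, compare
fusion-aware counts via `recovered_counts`) holds components exactly and
tubes/junctions/meshes to within ±5 % (floor of one count) across 100
random designs. What the generator does **not** emulate: curved and
tapering tubes, intensity inhomogeneity across the well, touching or
overlapping tubes, debris and imaging artefacts. Passing round-trip
tests therefore validates the graph/taxonomy machinery, not robustness
to real microscope images.

**Screens.** Wells carry a per-plate baseline vector (shift SD 2) plus
i.i.d. Gaussian noise (SD 1); planted phenotype clusters add effect
vectors expressed in z units (scaled by the noise SD), on disjoint
feature blocks in the default design (4 clusters × 10 features ×
effect 5). With zero effects the post-normalisation z-scores of treated
wells are ~ N(0, 1) *up to* the shared finite-control correction: all
wells of a plate share the estimated DMSO mean/SD, so the approximation
is exact only as the number of control wells grows, and the null test
checks it in that regime. Real screens' spatial plate effects (edge
wells, gradients) are not modelled.

**Expression.** A latent angiogenic axis per patient: pro-angiogenic
genes (TIE1, ITGB5, ESAM, S1PR1, CDH5, VWF, KDR) load +0.6, the
anti-angiogenic glutamate-receptor set (GRM1, GRM5, GRIA1, GRIA2,
GRIN3A, GRIK2, GRM3, GRIK5) −0.6, a second receptor set (GRIN1, GRINA)
+0.36; expression = baseline + loading·axis + N(0, 0.5), truncated at
0, one sample per patient per region (301 patients × 4 regions), with a
small per-region offset (SD 0.1). High Braak stage is drawn with
probability expit(2·axis), then a stage uniform in {5, 6} or {1–4}.
Patients fall into three planted groups at axis centres (−2, 0, 2) with
SD 0.25: the separation is chosen so that, given the stated loadings and
noise, adjacent planted states overlap by well under 1 % — the planted
labels are then a meaningful ground truth rather than a soft gradient,
which is what "recovering the planted subgroup" requires. A handful of
genes sit below the expression cutoff to exercise the filter. Not
emulated: count-like noise, patient covariates, region-specific disease
gradients, or correlated gene modules beyond the single axis.

## Problem sizes

Defaults used by the test suite and the acceptance script: 384×384 px
images with 18–25 seeds (100 networks for the identity suites), screens
of 60 compounds × 2 replicates × 4 plates with 16 DMSO wells per plate
(20 seeds), expression studies of 301 patients × 4 regions × ~42 genes
(50 seeds for correlation, 5 for clustering). These sizes were chosen so
each property is measured on enough independent replicates to be
meaningful while the whole suite stays fast enough to run habitually.

## Known limitations

* Segmentation is a reproducible default, not a tuned match to any
  specific acquisition system; on real images the thresholds in
  `RunConfig` will need adjustment.
* Mesh areas of a component nested inside another component's face are
  attributed to both (the outer face of the inner component is dropped,
  but the enclosing mesh keeps its full area).
* The rotation-system face walk relies on distinct departure angles;
  exactly coincident multi-edge geometries fall back to an id-based tie
  break.
* Fingerprint generation from structures (SMILES) is out of scope; the
  pharmacology module consumes precomputed bitstrings.
* The expression module analyses a given matrix; acquisition, QC and
  normalisation of real cohort data are upstream of this package.
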