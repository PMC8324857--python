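# Methods

`icnsmap` analyzes whole-heart maps of the intrinsic cardiac nervous system
(ICNS): point clouds of neuron somata annotated on serial sections, together
with contour traces of the cardiac chambers and great vessels. This note
documents the models, parameter choices, and numerical conventions, and what
the synthetic validation data do and do not establish.

## Neuron records and the inclusion rule

A neuron marker is a 3D position (µm), a section index (sections are 5 µm
apart by default; `z = section × thickness` at the mid-plane), and optional
soma short/long axes. The size criterion for accepting a soma is
**at least 13 µm × 23 µm**, boundary-inclusive, applied to (short, long)
axes. Markers without axis measurements pass with a `size_unverified` flag,
because deposited files typically record only already-accepted neurons.
Somata span several 5 µm sections; annotating in four-section intervals
prevents double counting. The synthetic module can emulate this (duplicating
each soma over 3–5 consecutive sections) and `dedup_section_intervals`
collapses lateral-position groups whose sections are closer than the
four-section window back to one marker per soma.

## PAM clustering and cluster-number selection

Clustering is classic Kaufman–Rousseeuw k-medoids (PAM) on Euclidean
distances in 3D µm coordinates, implemented from scratch:

- **BUILD** greedily seeds medoids: the first minimizes total distance, each
  subsequent one maximizes the cost reduction.
- **SWAP** evaluates every (medoid, non-medoid) exchange and applies the
  best strictly improving one until none exists. The swap deltas are
  computed vectorized from nearest/second-nearest medoid distances; this is
  algebraically identical to the exhaustive evaluation. The run is
  deterministic given input order; assignment ties go to the lower medoid
  index.

PAM converges to a single-swap local optimum. On small unstructured
instances this occasionally differs from the exhaustive optimum — the R
`cluster::pam` reference shows the same behaviour — while on clusterable
data the two agree almost always; the test suite checks both facts.

Silhouette widths follow the standard definition
`s(i) = (b(i) − a(i)) / max(a, b)` with `a` the mean within-cluster distance
(excluding self) and `b` the best other-cluster mean distance; singleton
clusters get `s = 0`. Our implementation is cross-checked against
scikit-learn in the tests.

**Cluster number** is chosen by comparison with randomized data: 10 null
datasets are drawn by independently permuting each coordinate axis across
points — preserving every marginal distribution (and hence the organ's
spatial footprint) while destroying 3D association; a uniform-in-bounding-
box null is also available. Each null dataset is clustered at every k of the
grid (so its distance matrix is reused). Candidates are all k whose real
mean silhouette is within ε = 0.01 of the maximum; among candidates the k
with the widest real-minus-mean-null gap wins, ties to the smaller k. The ε
rule is a fixed, documented replacement for the visual inspection a human
analyst would apply. The default grid is k = 2..20 (2..16 in the pipeline);
for hearts with thousands of neurons the pipeline selects k on a random
subsample (default 800 somata) and then labels all neurons with a full PAM
run at the chosen k — selection is a property of the density field and is
stable under subsampling, while full-size selection would cost
O(k n²) per swap pass across the whole grid.

## Flatmaps and packing density

The neuron cloud lies on a gently curved atrial sheet, so the two leading
principal axes give a faithful 2D flatmap. PCA is computed by SVD of the
centered cloud; the reflection ambiguity is fixed by making each axis's
largest-magnitude loading positive, so orientation is reproducible across
subjects. Rank-deficient (collinear) clouds are flagged degenerate.

Packing density is a Gaussian kernel **sum** over neurons (units
neurons/µm², integrates to n; the raster integral is verified to 2%),
with Scott's rule per axis (`h_j = sd_j · n^(−1/6)`) as the default
bandwidth, reported in all outputs. Both the per-point KDE and a raster
(counts-per-bin analogue) are produced.

## Regions of interest

Five ROIs are defined from contoured structures: the pulmonary-vein hilum
(PVs + left atrium), the SVC–right-atrium root, the left atrioventricular
sulcus (marked by the coronary sinus), the anterior interatrial sulcus, and
the posterior left atrium. A neuron is *proximal* when its minimum 3D
point-to-segment distance to the ROI's contours is within the radius;
sulci are junctions rather than structures, so the interatrial sulcus
requires joint proximity to **both** atria. The default radius is 500 µm —
roughly one atrial wall thickness at this scale; the original proximal/
distal calls were visual, so the radius is configurable, reported in
outputs, and monotonicity in it is guaranteed (and tested). Because ROIs
overlap anatomically, a neuron may belong to several; per-ROI fractions
need not sum to 1 and the union count is reported separately. A cluster is
*associated* with an ROI when more than half its members are proximal.
Distances use a KD-tree over contour vertices to propose the 16 nearest
vertices and evaluate exact point-to-segment distances on their adjacent
segments; this is exact whenever vertex spacing is far below the radius
(always here) and is cross-checked against the brute-force definition.

## Scaffold registration and material coordinates

The scaffold is a structured (nu+1)×(nv+1) node grid of bilinear quad
elements (default 16×16) sampled from the template surface; a point on it is
addressed by a material coordinate (element id, ξ ∈ [0,1]²) that is
invariant under node deformation. Bicubic patches would track curvature with
fewer elements, but bilinear elements keep the per-round node update exactly
linear; the default grid keeps the geometric discretization error of the
template family in the low tens of µm.

Registration of a subject proceeds in three steps:

1. **Alignment.** A similarity transform (Umeyama closed form) is estimated
   from matched per-structure centroids — the subject's contour centroid per
   structure against the template's, computed from contours sliced the same
   way so the sampling bias matches. This step is essential, not cosmetic:
   closest-point fitting cannot observe tangential (in-plane) motion, so
   without anatomical landmarks the material frame slides by hundreds of µm
   even when the fitted surface matches the data to a few µm.
2. **Fitting.** Alternating least squares: project every contour point onto
   the current surface — restricted to the scaffold elements of its own
   structure's region, a second anatomical anchor — then solve the linear
   system minimizing Σ wᵢ‖xᵢ − Σ φⱼ(ξᵢ) pⱼ‖² + λ Σ_edges ‖(pⱼ−gⱼ) −
   (pⱼ′−gⱼ′)‖². The penalty is a membrane on node *displacements* from the
   aligned configuration: penalizing raw node differences would shrink the
   mesh toward a point as λ grows, whereas the displacement form is neutral
   to the aligned geometry and exactly accommodates rigid translation.
   Defaults: λ = 1.0, unit weights, at most 10 rounds, stop when the RMS
   changes < 0.5 µm; contour data are subsampled to ≤ 2000 points. With λ=0
   and data that do not constrain every node the normal equations are
   singular and the error says to raise λ. Given fixed correspondences each
   solve minimizes the objective exactly, so the RMS is non-increasing
   within a round. Known material addresses can be passed directly
   (`correspondences=`), which turns the fit into one consistent linear
   solve (used for calibration, e.g. exact translation recovery).
3. **Embedding and transfer.** Each neuron is projected onto the fitted
   surface and stored as (element, ξ); evaluating the same address on the
   generic scaffold places all subjects in one frame. Projection of a point
   onto an element minimizes ‖S(ξ) − x‖ by alternating exact 1D
   minimizations (the surface is linear in each ξ coordinate separately, so
   each sub-problem is a clamped quadratic — robust exactly where a
   projected 2×2 Newton step stalls on element edges). The API-level
   `project_point` multi-starts on every element; the fitting loop seeds
   from a coarse per-element ξ-grid and refines the 4 nearest candidate
   elements, which reproduces the global result to machine precision on
   this geometry and is checked against a dense ξ-grid search in the tests.

**Overlap** between two registered subjects bins their material coordinates
into ξ-subcells (default 2×2 per element), normalizes each subject's bin
counts to sum to 1, and reports the histogram intersection
Σ min(dₐ, d_b) ∈ [0,1] (computed in integer arithmetic so identical sets
give exactly 1), the per-bin min/max ratio, and the Jaccard index of
occupied bins. All overlap statistics are symmetric.

## Synthetic study conditions

The generator emulates the features of the real data that the analyses
consume, on a single-sheet surface:

- **Geometry**: a height field over (u,v) ∈ [0,1]² at 8000 µm extent — a
  tilted plane (slope 0.18, so 5 µm iso-z sections land ~25–30 µm apart and
  sectioning is informative everywhere) carrying a broad dome (amplitude
  1800 µm, σ 2000 µm; the atrial base) and a gentler ridge (500 µm, the
  hilum). Anatomical structures are twelve (u,v) patches; five ROI anchors
  sit on or beside the corresponding patches.
- **Sex profiles**: totals Gaussian around 2845 (male, CV 5%, matching the
  reported 2676–2973 range) and 1581 (female, CV 7%); 8–12 clusters for
  males, 4–8 for females; each of the four vessel/sulcus ROIs always
  receives at least one cluster, extra clusters go to random anchors.
  Cluster positions are tangent-plane Gaussians (sd 300 µm) plus a 25 µm
  off-surface jitter; 5% of neurons are uniform background. Packing density
  is controlled by `density_scale` (effective spread = spread/√scale;
  female 0.7 → wider, sparser clusters). Cluster centers are rejection-
  placed to keep pairwise separation ≥ 4× the effective spread, so the
  planted cluster number is recoverable by construction. Soma axes are
  lognormal with medians (16, 28) µm and shape parameters (0.09, 0.04 for
  the long/short ratio), chosen so ~97% of somata pass the 13×23 µm rule —
  the filter is exercised but not dominant. No per-cluster size data exist
  to calibrate against, so cluster sizes are symmetric multinomial.
- **Individual variability**: an affine (scale 0.9–1.1, rotation ≤ ±0.08
  rad, both proportional to `warp_amplitude`/300 so amplitude 0 is exactly
  the identity) plus a low-frequency sinusoidal displacement field with
  per-axis amplitude `warp_amplitude`/√3 (default total 300 µm). Surface
  and markers are warped identically and contours are sliced from the
  warped surface at 5 µm.
- **Validation profile**: a deliberately small 4-cluster heart (~240
  neurons, one cluster per vessel/sulcus ROI) used where simulations are
  repeated dozens of times (cluster-number recovery, registration
  accuracy); the full-size profiles are used for count/density statistics.

What passing tests show — and what they do not: the synthetic sheet has no
multi-chamber topology, no annotation noise or missing sections, no
staining variability (beyond an optional dropout fraction), and its
deformations are smooth and global. Recovery of planted structure here
validates the algorithms' correctness and their behaviour under smooth
inter-individual variability; it does not certify performance on real
histology, where annotation and tissue-preparation artifacts dominate.

## Determinism and seeds

All stochastic steps take explicit integer seeds; pipeline stages derive
child seeds by hashing the master seed with the stage name (SHA-256, folded
below 2³¹), so any stage can be reproduced in isolation and no two stages
share a stream. Fixed seeds give bit-identical outputs.

## Known limitations

- PAM is exact only up to single-swap local optima (see above).
- Tangential registration accuracy rests entirely on the anatomical
  landmarks (structure centroids and per-structure element restriction);
  with few or degenerate structures the material frame is underdetermined.
- The interatrial-sulcus ROI is a joint-proximity band narrower than a
  typical cluster spread, so by construction only a majority — not all — of
  a sulcus cluster is proximal to it.
- Flatmaps are linear projections; strongly folded sheets would need
  geodesic flattening, which is out of scope.
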