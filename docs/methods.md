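# Methods

## The network model of external morphology

A body plan is encoded as a simple, undirected, connected graph: nodes are
discrete, delimitable morphological units (axial segments, limb articles,
endites, exites, epipods, flagellae, cephalic shields, eyes) and edges are
physical articulations or junctions between them. Networks enter the
pipeline as labeled 0/1 adjacency matrices (CSV, first row and column
carrying identical unit labels) or from the synthetic generator. Validation
is strict: asymmetric cells, nonzero diagonals, non-binary entries,
duplicate labels and disconnected graphs are all hard errors — a single
organism's morphology is one connected body, so disconnection signals a
data problem rather than a modeling choice. Node order is the file's label
order and is preserved in every downstream vector and matrix.

All-pairs shortest-path structure (distance matrix, distance degrees
σ_i = Σ_j d_ij, eccentricities, Wiener sum W, pair counts g_k per distance,
per-node layer counts n_k^i) is computed once per network by BFS
(`scipy.sparse.csgraph`) and reused by every distance-based quantity.

## The 40-measure battery

Eight network parameters (N, M, diameter, radius, average path length,
average degree, average local clustering with k<2 nodes contributing 0,
density) and ~28 topological descriptors from chemical graph theory are
computed per network, plus four normalized complexity scores (below). All
information-theoretic descriptors use base-2 logarithms with 0·log 0 := 0.

Several descriptor names in the morphometric literature are ambiguous; the
variants chosen here (recorded in `descriptors.VARIANTS`) are:

- **Eccentricity** (as a scalar): mean vertex eccentricity.
- **Centralization**: distance-based, Σ_i (σ_i − σ_min) — it clusters with
  the other distance sums, which is the behavior expected of it.
- **Compactness**: Wiener index normalized between the path
  (W = N(N²−1)/6, least compact, 0) and the star (W = (N−1)², most
  compact, 1); degenerate at N=2 where it is defined as 0.
- **Konstantinova index**: entropy of the distance-degree distribution
  σ_i/2W.
- **Bonchev index 1**: entropy of the distance distribution g_k/P with
  P = N(N−1)/2; **Bonchev index 2**: magnitude form
  W·log₂W − Σ_k g_k·k·log₂k.
- **Balaban-like information indices**: the Balaban J kernel
  (M/(μ_c+1))·Σ_edges (w_i·w_j)^(−1/2) with the distance degree replaced by
  local distance information, u_i = σ_i log₂σ_i − Σ_j d_ij log₂ d_ij
  (index 1) or by the layer-entropy-weighted distance degree v_i = H_i·σ_i
  (index 2). Non-positive weights (only possible at N=2) are skipped; an
  empty sum yields 0.
- **Edge equality**: Σ_c (m_c/M)² over edge classes defined by the
  unordered endpoint-degree pair.
- **Normalized edge complexity**: Σ_i k_i over the complete graph's edge
  count N(N−1)/2, taken literally.

Spectra (adjacency eigenvalues λ, Laplacian eigenvalues μ) come from dense
symmetric eigendecomposition; the study's largest network has 929 nodes, so
dense N×N solves are cheap and exact. Tiny negative Laplacian eigenvalues
are clipped to zero.

## Normalized complexity measures

Four scores in [0,1], peaking at intermediate edge density:

- **MAg** (medium articulation): over the uniform directed-edge ensemble,
  mutual information I = Σ (1/2M)·log₂(2M/k_i k_j) and redundancy
  R = Σ (1/2M)·log₂(k_i k_j) satisfy I + R = log₂(2M) identically, so the
  unique scale-free product normalization is MAg = 4IR/(I+R)².
- **Ce** (efficiency complexity): efficiency E = mean inverse shortest-path
  length, rescaled to e ∈ [0,1] between the N-path anchor and the complete
  graph, folded with 4e(1−e). e is clipped to [0,1] to guard floating-point
  excursions at the anchors.
- **Cr** (graph index complexity): the spectral radius located between the
  path bound 2cos(π/(N+1)) and the complete bound N−1, folded with 4c(1−c).
- **OdC** (offdiagonal complexity): entropy (natural log, matching the
  source convention) of the degree-offset abundances a_m = Σ_k c_{k,k+m}
  from the node–node link correlation matrix, normalized by ln(k_max);
  defined as 0 when k_max ≤ 1 or only one offset occurs. The alternative
  normalizer ln(N−1) is not the default.

## Centrality suite

Twelve indices per node: betweenness (Brandes, unnormalized pair counts),
closeness ((N−1)/σ_i), eigenvector (Perron vector, max-normalized), Katz
((I−αA)⁻¹1, α = 0.85/λ_max by default), Bonacich power
((I−βA)⁻¹A1 rescaled so Σc² = N; β = 0.2 by default — a low β probes the
local radius of influence), PageRank (damping 0.85, unit-sum), decay
(Σ_j δ^d_ij, δ = 0.5), Stephenson–Zelen information centrality in two
variants (the harmonic N/(N·C_ii + tr C − 2·rowsum_i C) form with
C = (L+J)⁻¹, and the simplified 1/C_ii trace form — they correspond to the
two variants common network toolkits report), subgraph centrality
((e^A)_ii), total communicability (row sums of e^A) and Valente–Foreman
integration ((1/(N−1))·Σ_j (d_max+1−d_ij)). Only β is fixed by the study
design; δ, α and the damping are conventional defaults, overridable and
recorded on the result objects. β = 0.2 can exceed 1/λ_max on dense graphs;
the solver then computes the analytic continuation of the walk series and
emits a warning rather than failing, since that regime is meaningful for
the scaled Bonacich score.

## PCA, clustering and the tree

PCA is an SVD of the centered table; the default is correlation PCA
(z-scored columns, sample sd) because the 40 measures span roughly six
orders of magnitude and covariance PCA would be dominated by the
Wiener-type sums. `scale=False` gives the covariance convention. Constant
columns are dropped with a warning.

HCA uses Ward.D2 semantics — squared-Euclidean objective with square-rooted
merge heights — via scipy's `ward` linkage on the Euclidean distances of
the scaled table; ties break deterministically at the lowest index. The
dendrogram is exportable as Newick with height differences as branch
lengths, the k-cut (k = 4 for networks, k = 6 for measures by convention)
and the cophenetic correlation are returned, and hierarchical k-means
(k-means seeded from the tree-cut centroids) is available as a robustness
comparison, reported rather than forced to agree.

## Branch ordering and bifurcation patterns

The root split of the network dendrogram defines two evolutionary branches;
the branch with the larger mean node count is labeled "left/large". Within
a branch, leaves are ordered center-out by recursively letting the child
subtree with more leaves continue the spine toward the root (ties: lower
merge height, then lexicographic). On caterpillar-shaped subtrees this
reproduces the natural reading order: taxa that join the branch's
agglomeration at lower heights sit closer to the hypothetical origin.

The published pattern calls are visual; the classifier here is an explicit
operationalization: Spearman ρ of the measure value against center-out rank
within each branch, with *ascending* iff both ρ ≥ τ, *descending* iff both
ρ ≤ −τ, otherwise *mixed*, τ = 0.3 by default and exposed on the CLI. Being
rank-based, calls are invariant under strictly monotone transforms.
Borderline profiles (irregular measures) are sensitive to τ by design and
are not treated as fixed ground truth.

The evolutionary developmental potential (EDP) of a region is summarized
from an influence-type centrality (eigenvector by default): per-region
means over the annotation classes (axis, head_shield, appendage, eye,
other), an axis-concentration ratio (axis mean / whole-network mean) and a
cephalization ratio (head-shield mean / axis mean). These ratios are
reporting devices for the qualitative color-map observation that influence
migrates from the whole body axis to the cephalic region; they are not
published quantities.

## Synthetic body-plan generator

The generator emulates segmented bilaterian anatomy: a chain of S axial
segments; per segment, bilateral appendage pairs as article chains of
length A attached at the segment; per article, lateral lobes; an optional
carapace hub joined to the head segments (5 by default); up to two eyes on
the first segment. Regions are annotated at generation time. Randomness is
restricted to bounded per-segment jitter of lateral counts, so node counts
obey a closed form and a resolved spec is fully deterministic; the preset
solver accumulates segments toward a target size and closes the residual
gap with single padding lobes, hitting targets in [50, 2000] exactly.

Two presets encode the designed morphotype contrast:

- **plexus** — phyllopodous: short limbs (A = 3) with 3–4 lobes per
  article, so segments act as irradiation centers and eigenvector
  centrality spreads along the body axis;
- **linear** — stenopodous: long thin limbs (A = 6) with at most an
  occasional single lobe, where eigenvector centrality localizes at the
  carapace/head instead.

These parameter choices were made to realize, at matched size, the
documented contrast that the plexus axis-concentration ratio exceeds the
linear one while the linear cephalization ratio exceeds the plexus one; the
contrast is verified statistically (paired draws over ≥20 seeds, one-sided
sign test) rather than assumed per draw.

What the generator does *not* emulate: real per-organism unit inventories
(which endites/exites a given taxon has), tagmosis beyond the head/trunk
distinction, appendage specialization along the axis, or any attempt to
rebuild actual taxa node-for-node. Passing synthetic-cohort tests therefore
demonstrates that the pipeline is correct and discriminates the two
morphotype regimes — not that it reproduces the published multivariate
coordinates, which depend on the deposited matrices.

## Problem sizes and numerical choices

The default test and acceptance runs use: 500 random connected graphs with
N ≤ 8 against brute-force oracles; centrality oracles at N ≤ 20 at 1e−8;
a 12-network cohort spanning 250–929 nodes for the end-to-end pipeline; and
20 paired generator draws at N ≈ 400 for the morphotype contrast. Dense
eigendecompositions are used throughout (largest N ≈ 930). Degenerate
cases: N = 2 defines compactness, Ce and Cr as 0 (the anchors coincide);
Balaban-like sums skip non-positive weights; tied branches yield an
undefined trend reported as 0 with a warning.

## Known limitations

- The exact descriptor variants and PCA scaling used for the published
  variance fractions (60.6%/12.2%/90.6%) and cophenetic correlation (0.685)
  cannot be pinned down without the original analysis scripts; the
  reproduction harness reports both scaling modes and the variant registry
  makes the reconstruction choices explicit.
- The study's deposited adjacency matrices are required for any
  study-reproduction check; without them only the synthetic pipeline runs.
- The bifurcation classifier's τ is a free parameter; calls for measures
  with irregular published profiles (e.g. OdC, Cr) should not be
  over-interpreted.
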