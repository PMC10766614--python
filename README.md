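# morphonet

Anatomical-network analysis of segmented body plans.

`morphonet` is for researchers who study morphological evolution by
abstracting an organism's external anatomy into a network: every discrete
morphological unit (axial segment, limb article, endite, exite, epipod,
flagellum, cephalic shield, eye) is a node, and every physical articulation
between units is an edge. Given a collection of such networks — for
example, the body plans of early arthropods — the package:

1. reads and validates labeled 0/1 adjacency matrices (CSV) and exchanges
   graphs as GraphML;
2. computes a 40-measure battery per network: 8 network parameters
   (N, M, diameter, radius, average path length ⟨d⟩ = 2W/N(N−1), average
   degree, clustering, density), distance descriptors (Wiener index
   W = Σ_{i<j} d_ij, Harary, Balaban J = (M/(μ+1))·Σ_{(i,j)∈E}(σ_i σ_j)^(−1/2),
   …), degree descriptors (Zagreb M₁ = Σk_i², M₂, Randić
   Σ(k_i k_j)^(−1/2), …), information indices (Bonchev, Bertz
   2M·log₂2M − Σk_i log₂k_i, layer entropies, Balaban-like variants),
   spectral indices (Estrada Σe^{λ_i}, energy Σ|λ_i|, Laplacian
   counterparts) and four normalized complexity measures in [0,1]
   (medium articulation MAg = 4IR/(I+R)², efficiency complexity Ce, graph
   index complexity Cr, offdiagonal complexity OdC);
3. runs correlation PCA and Ward.D2 hierarchical clustering on the
   networks × measures table, with cophenetic correlation, hierarchical
   k-means cross-check, Newick tree export and heatmap ordering;
4. orders the tree's two root branches center-out and classifies each
   measure's profile as an *ascending* or *descending bifurcation*
   (per-branch Spearman trend against center-out position);
5. summarizes the *evolutionary developmental potential* (EDP) of
   anatomical regions by concentrating influence-type centralities
   (eigenvector, Katz, Bonacich power with β = 0.2, PageRank, plus
   betweenness, closeness, decay, information, subgraph, communicability
   and integration) into per-region means and concentration ratios;
6. generates synthetic body plans — a parametric segment/appendage/lobe
   grammar with *plexus* (phyllopodous, lobe-rich) and *linear*
   (stenopodous, chain-limbed) morphotype presets spanning 250–929 nodes —
   so the entire pipeline is testable without any deposited data.

See `docs/methods.md` for the exact definitions, variant choices and
limitations.

## Worked example

```python
from morphonet import measure_table, pca, hca, branch_ordering, classify_table
from morphonet.synthetic import generate_cohort, generate_body_plan, preset
from morphonet.centrality import eigenvector
from morphonet.evolution import edp_summary

nets, manifest = generate_cohort(12, (250, 929), seed=42)
table = measure_table(nets)               # 12 x 40, complete
res = pca(table)                          # correlation PCA
tree = hca(table, k=4)                    # Ward.D2 on the scaled table
order = branch_ordering(tree, sizes=table["nodes"].to_dict())

plexus = generate_body_plan(preset("plexus", 400, seed=0))
linear = generate_body_plan(preset("linear", 400, seed=0))
for net in (plexus, linear):
    s = edp_summary(net, eigenvector(net))
    print(net.name, round(s.concentration_ratio, 2), round(s.cephalization_ratio, 2))
```

With these seeds this prints:

```
PC1 66.2%  PC2 28.5%  PC3 3.0%          # res.variance_explained[:3]
cophenetic correlation: 0.595           # tree.cophenetic_correlation
plexus_400n_seed0 8.52 3.07
linear_400n_seed0 7.22 6.12
```

The first principal component of the synthetic cohort is dominated by the
size-driven extensive measures, and the Ward tree's first split separates
the cohort into its two branches. The last two lines are the EDP summary:
the plexus body plan holds more of its eigenvector centrality along the
body axis (axis-concentration 8.52 > 7.22), while the linear body plan with
its cephalic shield concentrates influence in the head (cephalization
6.12 > 3.07) — the generator's designed primitive-vs-derived contrast.

A command-line interface wraps the same functions:

```sh
morphonet synth --preset plexus --target-n 600 --seed 42 --out adj.csv
morphonet validate adj.csv
morphonet measures adj.csv --out measures.csv
morphonet hca measures.csv --k 4 --tree-out tree.nwk
morphonet bifurcation measures.csv --tau 0.3 --out calls.csv
```

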