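# metnet

Seed-based reconstruction and expression-integrated analysis of the yeast
methionine biosynthesis interaction network.

## The problem

Methionine restriction alters growth signalling in *Saccharomyces
cerevisiae*, and the cellular machinery it touches is best read off a
network: which proteins around the methionine biosynthesis enzymes respond,
and through which complexes and pathways.  `metnet` implements that analysis
chain as a tested, reusable pipeline for systems biologists:

1. **Gated network expansion.**  Starting from the eight proteins annotated
   to the *methionine biosynthetic process* (HOM2, HOM3, MET6, MET13, STR3,
   HOM6, MET2, MET22), pool their component / function / process GO terms
   into an *Annotation Table* (7 / 31 / 29 terms).  A candidate protein joins
   the network iff it physically interacts with a current member and its own
   GO terms are compatible with the table, one namespace at a time; expansion
   runs to a fixpoint.
2. **Topology.**  Diameter and characteristic path length `L = mean d(u,v)`,
   degree `k` and normalized betweenness centrality per node, a least-squares
   fit of `P(k) ~ k^-γ` on log-log axes with its `R²`, and the union of the
   top-10 hubs (degree) and top-10 bottlenecks (betweenness).
3. **Differential expression.**  Per-gene two-sample Student *t*-test on a
   normalized log2 matrix (two conditions × replicates), Benjamini–Hochberg
   FDR < 0.05, absolute fold change > 1.5 on the ratio scale.
4. **Active modules.**  Node scores `z_i = Φ⁻¹(1 − p_i)`; a connected
   subnetwork *A* with *k* members scores `z(A) = Σ z_i / √k`, calibrated to
   `s(A) = (z(A) − μ_k) / σ_k` against Monte-Carlo random *k*-node groups;
   greedy (or simulated-annealing) search for high-`s(A)` modules.
5. **Dense modules.**  Core-clustering vertex weighting and seed-and-expand
   complex prediction (score = density × size, reported above 3), merged into
   one dense responsive network.
6. **Enrichment.**  Hypergeometric over-representation of gene lists against
   GMT/TSV term collections, BH-adjusted.

A synthetic-study generator (`metnet.synthetic`) produces all inputs with
recorded ground truth — a scale-free PPI with a GO-coherent planted
subnetwork, a planted clique, planted differential genes — so the whole
pipeline is testable offline.

## Worked example

The numbered drivers under `analysis/` run the full chain on the seeded
synthetic study and write their tables under `results/`:

```sh
python analysis/01_annotation_table.py
python analysis/02_simulate_study.py
python analysis/03_reconstruct_and_topology.py
python analysis/04_differential_expression.py
python analysis/05_active_modules.py
python analysis/06_dense_modules_enrichment.py
```

Output of the run at seed 7:

```
seed proteins (8): HOM2 (YDR158W), HOM3 (YER052C), MET6 (YER091C), ...
  component terms pooled: 7
  function  terms pooled: 31
  process   terms pooled: 29
expanded in 2 rounds: 108 nodes, 272 edges
diameter 5, mean path length 2.53 (small-world for a 108-node graph)
degree distribution: gamma = 0.910, R^2 = 0.56
1 modules reported; top: k = 15, z(A) = 14.51, s(A) = 8.59
overlap with planted responsive module: Jaccard = 1.00
1 dense modules with score > 3
dense network: 6 nodes, 15 edges; planted clique recovered: True
top enriched term: T_PLANTED_DENSE (adjusted p = 6.4e-10)
```

Reading this: the gated expansion admitted exactly the planted GO-coherent
subnetwork (100 nodes) around the 8 seeds; the reconstructed graph is
small-world (diameter 5, mean path 2.5) with a power-law-like degree
distribution; differential expression recovered all 60 planted genes
(31 up / 31 down called, observed FDR 0.03); the greedy search found the
planted 15-node responsive module exactly (`s(A) = 8.6`); inside it the
planted 6-clique came out as the single dense module (score 6.0 = density 1
× 6 nodes); and the dense network is over-represented for the term planted
over those genes.

The same stages are available as a CLI (`metnet simulate | reconstruct |
topology | dge | activemod | mcode | enrich | run-all`) for use on real
inputs: GAF or 3-column TSV annotations, BioGRID TAB3 / TSV / SIF physical
interactions, a log2 expression TSV with a condition map, and GMT term
collections.  `metnet run-all --config config.yaml` writes every stage
output plus a `summary.json`; reruns are byte-identical under a fixed seed.

## Layout

```
src/metnet/        library: io_formats, annotation, reference, spa, topology,
                   dge, active_modules, mcode, enrichment, synthetic,
                   pipeline, cli
analysis/          numbered narrative drivers (write to results/, scratch/)
tests/             pytest suite incl. brute-force oracles and acceptance tests
scripts/           acceptance.py
docs/methods.md    models, parameters, calibration, known limitations
```
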