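# Methods

This note documents the models and procedures implemented in `metnet`, the
parameters that matter, the numerical choices, and the limits of what the
synthetic benchmarks demonstrate.

## Gated seed expansion

The network is grown from a seed protein set over an undirected physical
interaction graph.  Admission of a candidate gene requires (i) adjacency to
a current member and (ii) GO compatibility with the *annotation table*, the
pooled component / function / process term sets of the seeds.  Admission is
monotone, so the result is the least fixpoint; breadth-first layering and
full rescans provably coincide, and the unit tests verify equality with a
full-rescan oracle on hundreds of random instances.  Choices:

- **Gate semantics.**  The phrase "its GO terms are present in the table"
  admits two readings.  The default, `any_per_namespace`, requires at least
  one table term in *each* namespace; genes annotated in only one or two
  namespaces always fail.  The strict `all_terms` mode (every annotated term
  of the gene in the table) is implemented but excludes nearly everything on
  real annotation densities — genes typically carry many terms per
  namespace, of which the table holds only the seeds' — and the large
  networks this analysis style produces are only reachable under the
  permissive reading.
- **Seeds are members unconditionally** and are not gate-checked; seeds
  absent from the interaction file stay as isolated generation-0 nodes with
  a warning.
- **Edges.**  The final edge set is the full induced subgraph on admitted
  nodes, not the discovery tree.  Self-loops are dropped at read time and
  `(a,b)/(b,a)` duplicates collapse under unordered-pair equality.
- **Roots.**  The GO namespace roots (GO:0005575, GO:0003674, GO:0008150)
  stay in the table because the curated seed table contains them; they make
  the gate nearly vacuous for their namespace, and a flag excludes them.
- **Evidence codes** are not filtered by default; the readers expose an
  exclusion list for users who want to drop, e.g., IEA-like annotations.
- **Determinism.**  Iteration is over sorted gene keys; permuting edge or
  seed order changes nothing, including the per-round admission trace.

## Topology

Diameter and characteristic path length (mean shortest-path distance over
unordered reachable pairs) are computed on the largest connected component,
whose size is reported alongside.  Betweenness is standard shortest-path
betweenness with even splitting across equal-length paths, normalized by
`(n−1)(n−2)/2`; both raw and normalized values can be emitted.  The degree
distribution fit is ordinary least squares of `log10 P(k)` on `log10 k` over
observed degrees `k ≥ 1` with no logarithmic binning, `γ = −slope`, and the
`R²` of that line; a single-valued degree distribution is an error.  This is
deliberately the simple descriptive fit used by interactive network tools,
not a maximum-likelihood tail estimator: it answers "how power-law-like is
the whole distribution", and its `γ` is not comparable to Clauset-style
estimates.  Hubs are top-*n* by degree, bottlenecks top-*n* by betweenness,
ties broken by gene key; their union is the "key gene" list.

## Differential expression

The pipeline starts from an already-normalized log2 matrix (array
preprocessing such as RMA is out of scope).  Per gene, a two-sided
equal-variance Student *t*-test compares the two conditions (each needs ≥ 2
replicates); the pooled variance is floored at `ε = 1e-8` so
replicate-identical genes stay defined, and genes identical in both groups
with equal means are assigned `t = 0, p = 1`.  Fold change is the ratio
`2^(mean_restricted − mean_control)`; "absolute fold change > 1.5" means
ratio > 1.5 or < 1/1.5, with strict inequalities.  BH adjustment is the
step-up procedure (delegated to statsmodels; the tests pin it to the
definitional sort/step-up/cummin oracle).  Significance is `p_adj < 0.05`
and the fold-change cut, both configurable.

Calibration demonstrated by the tests: raw-p type-I error 0.05 ± 0.01 on a
2000-gene Gaussian null; on the planted benchmark (60 true genes at |log2
fold change| 2, σ = 0.25, triplicates) mean recall ≥ 0.9 at observed FDR
≤ 0.1 over 20 replicates.

## Active (expression-responsive) modules

Node scores are `z_i = Φ⁻¹(1 − p_i)` from the per-gene differential
expression p-values; p is clamped into `[1e-16, 1 − 1e-16]` before the
transform, and genes without a p-value are neutral (`z = 0`).  A connected
module *A* of size *k* aggregates to `z(A) = Σ_{i∈A} z_i / √k` (default;
a `1/k` variant is selectable — the √k form keeps `z(A)` distributed
independently of *k* for iid scores, which is what cross-size comparison
presupposes).  The calibrated score is `s(A) = (z(A) − μ_k)/σ_k`, with
`μ_k, σ_k` estimated by Monte Carlo over uniformly random *k*-node groups
(10 000 samples by default, one cumulative sum per random permutation so all
*k* are sampled at once; a connected-subset null is available).  Two exact
facts the tests rely on: sampling *k* of *n* fixed scores without
replacement gives `μ_k = √k·z̄` and `σ_k = σ_z·√((n−k)/(n−1))`, so the
N(0,1) idealization holds only up to the realized population mean and the
finite-population correction.

Search is greedy: from each of `n_restarts = 10` start nodes (highest *z*
first), repeatedly add the neighboring node that maximizes `s(A)` — at fixed
*k* that is the boundary node with the largest *z* — until no addition
improves the score or `k = max_k = 250`.  A seeded simulated-annealing
refinement (geometric cooling, add/remove moves that preserve connectivity)
is available behind the same score contract.  Returned modules are sorted by
`s(A)` and trimmed to non-overlapping node sets.

**Selection bias (known limitation).**  `s(A)` calibrates against *random*
same-size groups, but the search reports the *maximum* of `s(A)` over a
selected trajectory of connected subsets seeded at the highest-z nodes.
That maximum is strongly upward-biased under the null: with 300
exchangeable standard-normal scores the best start node alone is ~2.9, and
measured null searches on scale-free graphs return top scores of roughly
3–12.  Consequently `s(A) > 3` must not be read as "significant at 3σ"; the
score ranks candidate modules but its absolute value overstates surprise.
A planted low-p module (p ~ U(1e-6, 1e-4) inside vs U(0.2, 1) outside)
separates clearly anyway — recovered with Jaccard ≥ 0.8 in ≥ 90% of seeded
replicates at scores ≈ 13–15 — but a principled significance statement
would need a max-calibrated null (random-permutation re-runs of the search
itself), which is out of scope here.

## Dense modules

Classic core-clustering complex detection: each vertex of degree ≥ 2 is
weighted by (highest core number of its closed neighborhood) × (density of
that core subgraph); complexes are seeded from the highest-weight unassigned
vertex and grown through unassigned neighbors with weight ≥ (1 − VWP) ×
seed weight (VWP = 0.2), each vertex joining at most one module.  "Haircut"
(on by default) reduces a module to its 2-core; "fluff" is available but
off.  The score of a module is its induced density × size, computed once on
the final node set; modules need ≥ 2 nodes and score > 3 to be reported.
Defaults follow the published algorithm; the score > 3 reporting cut is the
downstream convention for calling a module dense.  Merging reported modules
takes the induced subgraph of the parent network on their union and reports
its connected-component count.

## Over-representation analysis

One-sided hypergeometric upper-tail test per term, `P(X ≥ x)` with
population `N` = background, `K` = term size, `n` = query size; BH across
tested terms (same code path as the expression FDR).  The background
defaults to all genes of the term map and can be set to the measured-gene
universe; only enrichment (not depletion) is tested, and term–gene maps come
from files so analyses are hermetic.

## Synthetic studies

`metnet.synthetic` generates every input with recorded truth, composed by
`make_study(seed)`:

- **Interaction graph:** preferential attachment, 300 nodes, m = 3 — a
  small scale-free backbone whose degree distribution is power-law-like at
  this size (mean least-squares `R²` ≈ 0.7 over seeds).
- **Planted GO structure:** a connected module (default 100 nodes) grown
  breadth-first from 8 seed nodes; module members receive gate-compatible
  terms in all three namespaces, decoys get 1–3 namespaces with only
  off-table terms, so gated expansion recovers exactly seeds ∪ module.
- **Expression:** 1000 genes, triplicates per condition, baselines
  ~ N(8, 1) log2 units, replicate noise σ = 0.25, planted shifts ± log2FC.
  The study default is log2FC = 3 (8-fold), the magnitude of a strongly
  induced regulon, placed on the planted responsive module (15 network
  nodes, up) plus 15 further up and 30 down genes outside the network; the
  statistics benchmarks use the harder log2FC = 2 setting.
- **Nesting:** planted clique (K6, edges added) ⊂ planted active module ⊂
  GO module ∪ seeds, so expansion → integration → dense-module detection
  each has a recoverable target; one gene-set term covers the active module
  for the enrichment stage.

Every generator is a pure function of (parameters, seed); written studies
are byte-identical across runs.  What the benchmarks do *not* emulate:
probe-level microarray noise and normalization artifacts, annotation
incompleteness and evidence-code heterogeneity, degree-correlated study
bias in interaction data, and database-version drift — so passing recovery
tests shows the algorithms are correct and calibrated on their assumptions,
not that real snapshots will reproduce any particular published network.

## Problem sizes and determinism

Default test and acceptance sizes (300-node graphs, 1000-gene matrices,
10 000 calibration samples, 200-instance oracle sweeps) keep the full suite
and the acceptance script fast on a single CPU while leaving every
statistical check well-powered.  All randomness flows through
`numpy.random.default_rng` seeds carried in configs and recorded in outputs;
pipeline reruns under a fixed config are byte-identical (no timestamps are
written).
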