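# Methods

## Model and assumptions

The pipeline treats co-expression as a surrogate for interaction: genes
whose expression profiles are strongly linearly correlated across samples
are assumed to interact, so the gene set of a condition induces an
undirected *derived interaction network* with an edge wherever
|Pearson r| strictly exceeds a threshold τ. The approach assumes the
expression matrix is already normalised and log-scaled; no background
correction or re-normalisation is applied. Correlations are computed
between genes (rows) across samples, since genes are the network's
vertices. The signed correlation is stored as edge weight for reporting,
but every topological computation treats the graph as unweighted — a hard
threshold, not a weighted analysis, defines the model.

## Preprocessing policy

Microarray probes map many-to-many to genes. The collapse policy is
deterministic and logged so its effect is measurable:

1. rows containing any missing value are dropped and counted;
2. probes mapping to more than one gene are dropped;
3. among a gene's remaining probes, the one with maximal row variance is
   kept (ties to the smallest probe id).

Max-variance selection is the standard probe-collapse choice when no
platform-specific rule is given; it is idempotent and keeps retained rows
bit-identical to the source file. Exact replication of any particular
published row count is not guaranteed by this policy, since published
preprocessing pipelines are rarely fully specified.

## Network statistics conventions

The topology panel follows the conventional network-analyzer definitions,
fixed here because published panels rarely state them:

* clustering coefficient = mean of local clustering coefficients, with
  degree < 2 vertices contributing 0;
* diameter = max over connected components of the component diameter;
  radius = min over components of the component radius (so a graph with a
  2-vertex component has radius 1 — this convention reproduces the
  "radius 1" values typical of sparse thresholded networks with many small
  components, and is the main place where conventions can differ between
  tools);
* characteristic path length = mean shortest-path distance over connected
  ordered pairs only; "shortest paths" = fraction of ordered vertex pairs
  that are connected (reported as a fraction in [0, 1]);
* centralization = Freeman degree centralization
  (n/(n−2))·(k_max/(n−1) − density);
* heterogeneity = coefficient of variation of the degree distribution.

Degenerate inputs: a single-vertex graph has density and clustering 0;
an empty graph raises.

## Community detection

The divisive loop is the exact O(m²n) recompute algorithm: edge
betweenness (Brandes, unnormalised, fractional counting over unordered
pairs — multiple shortest paths between a pair split one unit of weight
equally) is recomputed after every removal. Ties on the maximal
betweenness are detected with a 1e-9 relative tolerance (betweenness
values are accumulated floats) and broken uniformly at random under the
caller's seed, which fully determines the removal order.

Partitions are defined by connected components, which change only when an
edge removal disconnects something, so modularity is evaluated only at
splits. Q is always computed against the *original* edge set, because
e_ij is defined as a fraction of all edges of the network being
partitioned. Disconnected input is legal: its initial components form the
first recorded partition before any removal, so a network that is already
split into k modules can report that partition (and its Q) as the optimal
cut. The cut with maximal Q wins; exact ties go to the earliest recorded
split (fewest communities). No fast-greedy, spectral, or approximate
variant is offered: the exact loop is the contract, and it bounds
practical problem sizes to a few thousand edges.

A note on a worked example: for the 4-cycle, fractional counting gives
betweenness 2.0 per edge (each edge carries one adjacent pair plus two
half-shares from the opposite pairs), consistent with the identity
Σ_edges betweenness = Σ_pairs d(u,v) = 8.

## Pathway projection

The reduction heuristic is applied in a single simultaneous pass: support
counts (how many annotated sub-network genes carry each candidate
pathway) are computed once from the raw candidate sets, and every gene
independently picks its maximum-support candidate, ties to the smallest
pathway id. "Other genes that can also be assigned p" is read as other
annotated genes whose *candidate* set contains p, regardless of their
eventual assignment — no iterative re-assignment, which keeps the result
order-invariant and deterministic. Unannotated genes are excluded from the
PPN and counted in a sidecar field. Intra-pathway gene edges become node
self-weights and are excluded from the degree attribute, which measures
connectivity *between* pathways. PPN edge weights are gene-edge counts; a
`binarized()` view collapses them to presence/absence. Annotations come
from a flat (gene, pathway id, name) TSV so the pipeline has no live
annotation-service dependency.

## Synthetic generator

`SyntheticSpec` plants gene blocks with a block-structured target
correlation: rho_in within blocks, rho_out between, sampled as
X = C^{1/2} Z with Z standard normal (symmetric eigen square root, so the
rows have correlation C in expectation with no per-gene loop). Optional
independent jitter of standard deviation s shrinks off-diagonal
correlations by 1/(1+s²). The target matrix must be numerically positive
semidefinite (eigenvalues ≥ −1e-8, clipped at zero) — PSD rather than
strictly PD so that the degenerate perfectly-correlated block
(rho_in = 1, noise 0) is admissible; genuinely indefinite targets raise
before sampling.

Defaults are the benchmark condition exercised throughout the tests:
4 blocks × 10 genes, rho_in = 0.95, rho_out = 0, 50 samples per
condition, no jitter. At these settings, thresholding at τ = 0.8 recovers
essentially every within-block pair (Fisher-z: P(r̂ < 0.8 | ρ = 0.95,
n = 50) ≈ 3·10⁻⁷ per pair) and essentially no between-block pair, so the
planted partition is recoverable exactly and Q_max sits at ≈ 0.75, the
modularity of four equal disconnected cliques. The disease-like condition
decorrelates the last half of the blocks (rho 0.2 by default), emulating
the sparser network a pathology produces and giving the
condition-specific subtraction stage real work. Each block carries a
planted candidate pathway set (singleton by default; arbitrary
many-to-many schemes can be supplied).

What the generator does **not** emulate: microarray noise physics (probe
affinity effects, saturation, background), heavy-tailed expression
distributions, sample-level batch effects, or correlation structure
beyond block-plus-background. Passing the planted-recovery tests
therefore shows the pipeline machinery is correct under its own model
assumptions, not that τ = 0.8 or the community algorithm is optimal for
any real dataset.

## Pipeline

One YAML config drives the run; a single seed feeds the generator and
every tie-break. Community detection runs on the full thresholded network
by default (`largest_component_only` restricts it to the largest
component, the choice appropriate when one giant component dominates);
pathway projection subtracts the disease network from each reference
community, filters at `min_cardinality` (default 100), and writes
GraphML/SIF PPNs plus top-|r| cross-pathway gene-pair tables for the two
largest pathway nodes. Each stage writes its artifacts before the next
starts, so a failure aborts with the stage name while partial outputs
remain. Test and acceptance runs use the 40-gene default benchmark, which
keeps the exact O(m²n) loop at a fraction of a second per run.

## Known limitations

* The exact divisive loop does not scale to the ~10⁵-edge networks real
  thresholded microarray data can produce; runs at that scale need
  cluster time by design.
* Pearson-only correlation; no partial correlation, mutual information,
  or multiple-testing control — the hard threshold is the model.
* The pathway reduction heuristic is greedy-by-support and single-pass;
  its ties (broken lexicographically) are arbitrary when supports are
  equal.
* PPN "enhancement" is descriptive (cardinality/degree); no statistical
  enrichment test is performed.
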