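# Methods

## Model overview

`netgenes` treats essential-gene prediction as binary node classification
on an organism's protein functional-association network. The working
assumptions are:

1. **Topology carries the signal.** Essential genes sit in structurally
   distinctive network positions (hubs, bottlenecks, dense egonets), so a
   feature vector computed from the graph alone is informative.
2. **Structure generalizes across species where identities do not.** A
   feature like "mean neighbour degree" means the same thing in any
   organism's network, which is what makes training on one set of species
   and predicting on another defensible. Leave-one-species-out (LOSO)
   validation tests exactly this assumption.
3. **Labels are complete within the universe.** Every gene of an organism
   not listed as essential is treated as non-essential; missed essentials
   therefore appear as label noise in the negative class.

## Feature extraction

### Recursive (ReFeX-style) block

Base features per node (6): degree; weighted degree (sum of incident edge
weights, weights = confidence score / 1000, dimensionless in (0, 1]);
egonet internal edge count; egonet boundary edge count; and the weighted
variants of the two egonet counts. The egonet of *v* is {v} ∪ N(v).

Each recursion appends, for every column present at its start, the
neighbour sum and neighbour mean of that column, giving a cumulative width
of 6·3^g after g iterations. The mean over an empty neighbourhood is
defined as 0 so isolated nodes never introduce missing values. Column
names embed the recursion depth (`sum2(degree)` ≠ `sum1(degree)`): the
depth-2 re-aggregate of a base feature is a distinct column even when its
values coincide with a depth-1 column. Schema mode accepts that
redundancy deliberately — a Random Forest is insensitive to duplicated
columns, and the payoff is a fixed, input-independent 267-column schema
(recursion depth 4, truncation to the first 267 columns in enumeration
order), without which cross-organism training would be ill-defined.

Research mode instead interleaves each recursion with:

- **vertical logarithmic binning** (default fraction p = 0.5): the
  ⌈p·remaining⌉ smallest unassigned values take the current bin, ties
  always share a bin (the bin extends past the nominal cut), then the rule
  recurses on the remainder. Output depends only on value ranks, so any
  strictly increasing transform of a column leaves its bins unchanged.
- **correlation pruning** (default similarity threshold s = 0): features
  whose bin vectors differ by ≤ s everywhere are connected; within each
  connected component the earliest feature under the enumeration order
  (then lexicographic name) survives. Because no two survivors are
  directly similar, a second prune pass is a no-op (idempotence).

Recursion stops when an iteration contributes no surviving feature or
after `max_iterations` (default 4).

### Explicit block

Twelve centralities in fixed order — degree, betweenness, closeness,
harmonic closeness, eigenvector, PageRank (damping 0.85), Katz
(attenuation 0.005), load, subgraph, current-flow closeness (information),
current-flow betweenness, Laplacian — plus clique number (size of the
largest maximal clique containing the node), local clustering coefficient,
biconnected-component membership count (articulation points > 1, isolated
nodes 0), and strength (weighted degree).

Numerical conventions chosen for the finiteness guarantee on arbitrary
graphs: centralities are computed on the unweighted topology; path-based
measures use within-component normalization; eigenvector centrality is the
per-component Perron vector (unit Euclidean norm, value 1.0 for
singletons); current-flow measures are computed per component and set to 0
on components too small to define them (< 2 nodes for closeness, < 3 for
betweenness); Katz on < 2 nodes is 1.0. The Laplacian centrality slot is a
deliberate design choice for the spectral/perturbation family:
communicability betweenness, the other natural candidate, requires one
dense matrix exponential per node and is computationally prohibitive at
the package's target network sizes (10³–10⁵ nodes), whereas Laplacian
centrality has a closed form in local degrees. The centrality list is
configurable for users who want a different twelfth measure and can pay
its cost. Clique enumeration is exponential in the worst case and guarded
by a configurable node limit (default 50,000).

The assembled matrix is recursive block (267) then explicit block (16):
283 columns. Training refuses any other width unless explicitly overridden
(research mode), so a schema drift cannot silently produce an
incompatible model.

## Training and scoring

- **Undersampled-fold ensemble.** Negatives are shuffled (seeded) and
  partitioned into `n_folds` = 10 disjoint chunks differing in size by at
  most one; one forest is trained per chunk on all positives + that chunk.
  This is the strictest reading of "undersample, but every negative seen
  at least once": coverage is exact and testable. At the ~8.5:1 imbalance
  the package targets, chunks are automatically near-balanced with the
  positive set; an optional cap at |positives| per chunk exists for more
  extreme imbalances.
- **Forest hyperparameters.** 150 trees, entropy criterion, √p features
  per split — the optimum found by 10-fold grid search in the setting the
  package reproduces; the `grid_search` helper re-runs such a search
  scored by cross-validated AUROC with deterministic (enumeration-order)
  tie-breaking.
- **Probability and score.** Ensemble probability is the arithmetic mean
  of member-forest probabilities. Genes with probability ≥ 0.70
  (inclusive — the published score floor of exactly 70.0 implies the
  boundary is kept) receive essentiality score = 100·p rounded to one
  decimal; all others are omitted from prediction tables.
- **AUROC** is computed from midranks (Mann–Whitney form), i.e. ties
  between a positive and a negative count one half. Single-class label
  vectors are an error, and LOSO skips such organisms with a warning
  rather than imputing a value.
- **Label-version comparison** reports per-organism AUROC differences,
  their mean (and the mean rounded to integer percent), and both a paired
  and a Welch t-test — the two standard choices — flagging the paired test
  as degenerate when the differences have zero variance instead of
  emitting a meaningless p-value.
- **Determinism.** Every stochastic step (negative shuffling, per-fold
  forest seeds, synthetic generation) derives from one integer seed;
  identical inputs + seed reproduce byte-identical outputs.

## Input handling

STRING-dialect edge lists are parsed with: optional header (detected by a
non-numeric third field), optional gzip, symmetric duplicate rows
collapsed keeping the **maximum** score (conservative and deterministic),
self-loops dropped with a warning, and integer scores validated in
[1, 1000]. Nodes remain in the network even when all their rows are
filtered out (a gene does not vanish because its only association was a
self-loop or low-confidence edge). No confidence cutoff is applied by
default (`min_score = 0`), keeping effectively all proteins of the
organism; sparsification is opt-in. Label files are intersected with the
interactome's gene universe; identifiers that do not map are counted and
reported, not fatal. Annotation lookups for unknown genes return the gene
id itself and "NA" rather than failing.

A training-suitability check warns when an interactome has fewer than
50,000 edges — small networks yield features too sparse for a
generalizable model — but does not refuse them.

## Synthetic cohorts

The generator emulates the *shape* of real bacterial interactome cohorts:

- **Topology:** preferential attachment seeded with a path on m nodes
  (heavy-tailed degree distribution; edge count exactly (m−1) + (n−m)·m,
  a tree at m = 1). Defaults: 6 organisms × 800 nodes, m = 2 — large
  enough for stable centrality estimates and ~84 positives per organism,
  small enough for a full-cohort LOSO run in minutes on one core.
- **Edge confidence:** integer uniform on [150, 999], mirroring the range
  observed in functional-association networks after the provider's
  low-confidence floor.
- **Labels:** per node, essential ~ Bernoulli(logistic(α + β_deg·z₁ +
  β_btw·z₂)) where z₁, z₂ are the standardized log-degree (log1p, so the
  transform is defined for isolated nodes) and standardized betweenness;
  α is solved by bisection so the mean planted probability equals the
  target prevalence (default 0.105, the essential fraction of real
  training cohorts) to within 10⁻⁶. Defaults β_deg = 2, β_btw = 1 give a
  strong but not deterministic centrality signal; β = 0 is the null.
- **Truth probabilities are persisted** alongside labels so calibration
  diagnostics remain possible without regeneration.

What the generator does **not** emulate: evidence-channel structure of
real confidence scores, modularity/community structure, phylogenetic
correlation between organisms, and annotation-biased labelling. Passing
the recovery tests therefore shows the pipeline can extract planted
structural signal end to end — it does not certify real-data AUROC.

## Problem sizes and runtime choices

The shipped validation uses 6 organisms × 800 nodes for parameter
recovery (signal and null cohorts share topology, so features are computed
once), 120–200-node graphs for schema checks, and ≤ 12-sample / ≤ 8-node
exhaustive oracles for the AUROC and betweenness property suites. These
sizes put every stable structural property well above noise while keeping
a full run on a single core in the minutes range. Feature extraction
dominates wall-time (the flow-based centralities are cubic-ish per
component); the CLI therefore caches per-network feature matrices keyed by
a content hash of the links file plus the feature configuration.

## Known limitations

- Schema mode's truncation at 267 columns keeps redundant re-aggregates
  by design; models pay a small efficiency cost for schema stability.
- The identities of the 12 centralities and the exact retained recursive
  features are package conventions (documented above and configurable),
  not a canonical standard; models are only comparable across runs that
  share the configuration, which is why the schema and config are stored
  with every trained ensemble.
- Centralities are unweighted; confidence scores influence only the
  weighted base features and strength.
- LOSO AUROC on synthetic cohorts is optimistic relative to real
  cross-species transfer (no phylogenetic structure, no label noise).
- The paired/Welch t-tests in the label-version comparison assume
  per-organism AUROCs are exchangeable draws; with 27–34 organisms this
  is a rough but conventional approximation.
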