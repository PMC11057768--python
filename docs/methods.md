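# Methods

This note documents the models and procedures implemented in `covar`,
the choices made where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## The pipeline

Given a control and a perturbed expression matrix over one gene
universe, the pipeline has six stages.

**1. Gene filtering.** Genes are filtered on pooled control+perturbed
samples by mean expression and by the geNorm-style M-value — the mean,
over partner genes, of the standard deviation (denominator S−1) of
per-sample log2 expression ratios, computed with a pseudocount (default
1.0) inside the ratio to guard zero expression. Genes are kept when the
M-value is **at or above** the cutoff: unlike geNorm's usual search for
stable reference genes, the pipeline wants the genes *affected* by the
perturbation. Defaults (M ≥ 0.32, mean ≥ 60) follow the published
evaluation settings. Two caveats: the M-value depends on the partner
universe, so re-filtering an already-filtered matrix is only a no-op
when genes are not borderline; and statistics are pooled across
conditions so that both inferred networks share one gene list (a
per-condition variant would allow the two conditions to disagree about
the universe, breaking the variationality comparison downstream).

**2. Influence-network inference.** For each condition, a directed
weighted network is inferred following the GENIE3 recipe: each gene in
turn is the target of a random-forest regression (default; extra-trees
available) from all other genes, with K = sqrt(N−1) candidate features
per split and the target standardized to unit variance. The
impurity-based importance of predictor u (total variance reduction),
normalized to sum to one over predictors, is the weight W[u, v] ∈
[0, 1]; column normalization is what bounds weights to that interval.
A constant target yields an all-zero column. Genes are canonicalised
to sorted order internally and per-target seeds are spawned from the
master seed by sorted position, so results are bit-reproducible and
exactly equivariant under input gene permutations. The published
evaluations use 10000 trees per target (the config default); desk-scale
analyses here use 100–500.

**3. Variationality.** Each gene's neighborhood is summarised by its
concatenated weight profile — out-weights then in-weights, length 2N,
self positions structurally zero — and scored by the mean squared error
between its control and perturbed profiles (divisor 2N; the structural
zeros are retained, matching the profile's defined length). Genes
strictly above the linear-interpolation empirical percentile (default
97.5) of the MSE distribution are variational. Strict inequality plus
linear interpolation makes selection deterministic and monotone in the
percentile; an explicit top-n override exists because a percentile rule
cannot reproduce every published gene count exactly.

**4. Nearest-neighbor network.** From the perturbed network only, a
threshold tau is set at the Z-th percentile (default 99.95) of all
N(N−1) off-diagonal weights. Starting from the variational set, the
single highest-weight edge (either direction) crossing from inside to
outside is repeatedly taken — admitting the outside node — while its
weight is ≥ tau; ties break by (source, target) gene order. When no
crossing edge remains, every edge ≥ tau between admitted nodes is
included. Note the scale coupling: the super-threshold edge budget is
N(N−1)·(1−Z/100) ≈ 2700 edges at N = 2318 but only ~20 at N = 200, so
at small N any single run's nearest-neighbor network is necessarily
small, and the integrated network (stage 6) is what accumulates
coverage.

**5. Modules and cores.** The network's undirected, unweighted
projection is partitioned by Girvan-Newman: repeatedly remove the
highest-betweenness edge (ties by lexicographically smallest edge
label), recomputing betweenness each step. The default stop rule keeps
the partition maximizing Newman modularity along the removal sequence,
scanned up to a module-count cap (default 12) since modularity on these
networks peaks at a handful of modules and each removal costs a full
betweenness recomputation; a fixed-count rule is available. Each
module's **core** is its maximal k-core — the non-empty k-core with the
largest k — peeled on the undirected projection (default) or by total
in+out degree (directed mode). Cores are characterized by
*coordination* (directed density |E|/(|V|(|V|−1)), 0 for singletons)
and *reachability* (fraction of all network nodes with a directed path
of length ≥ 0 from at least one core node; core nodes count as
reached).

**6. Ensemble integration.** Tree ensembles are stochastic, so stages
2–4 are repeated n_runs times with child seeds seed+i (control and
perturbed inferences within a run use 2·(seed+i) and 2·(seed+i)+1).
Integration unions the per-run networks, drops edges supported by fewer
than ρ runs (weights averaged over supporting runs), then drops
isolated nodes; modules and cores are extracted from the integrated
network. ρ has no published value; the package default is the majority
rule ceil(n_runs/2). **At desk scale this default can be infeasible:**
with ~20 super-threshold edges per run at N = 200 the extreme weight
tail is dominated by near-ties that different runs resolve differently,
so no edge recurs in a majority of runs and the consensus is empty (the
pipeline raises rather than returning an empty network). The simulated
experiments therefore pass ρ = 1 explicitly — integration then
*accumulates* the near-tied top edges across runs, which is also the
only regime in which a final network much larger than any single run's
(as in the published simulated-data experiment) can arise. Per-gene
variational and core frequencies are tallied per run, before
integration.

## Synthetic generators

**Preferential-attachment networks.** A directed small-world graph
grows from a seed clique of m+1 mutually connected nodes; each arriving
node draws m distinct existing nodes without replacement with
probability proportional to out-degree + k and receives edges from them
(old → new). The additive constant k tunes hubbiness: k = 0 gives
heavy-tailed out-degrees, k → ∞ uniform attachment. Edges run from the
chosen well-connected node to the newcomer so that preference acts on a
degree that attachment itself grows (the alternative orientation makes
the preference degenerate to uniform) and so that early nodes reach
most of the network along directed paths, which is what makes core
reachability a meaningful benchmark. m is not published; the default
m = 2 is the smallest value giving non-trivial cores.

**Core-vs-random benchmark.** On each generated network the whole-graph
maximal k-core is extracted and its coordination and reachability
compared against one uniformly random node set of the same size. The
benchmark peels in **directed** (total-degree) mode: with m edges per
newcomer the graph has minimum undirected degree m and is m-degenerate,
so the maximal *undirected* k-core is provably the entire node set and
the comparison would be vacuous. Total-degree peeling sees the doubled
seed-clique edges and isolates the dense early region. Under this
procedure a random set never strictly exceeds the core's coordination,
and the probability that it ties the core's (total) reachability decays
with N — the tie requires the random set to contain one of the few
nodes that reach the whole network. The published benchmark reports a
tie fraction that *grows* with N (0.121 at N = 100 to 0.415 at
N = 500); no reading of the printed generator and core rule that we
could derive reproduces that growth, and the N = 500 tie fraction here
(~0.01) should be read with that caveat.

**Latent-factor expression data.** Two conditions × N genes × S
samples. Module gene g in module m: x = a_{g,c}·F_{c,m} + b_g·F_c + ε,
with a fresh module factor per condition × module (sd sigma_module = 2)
and the signed loading a_{g,c} redrawn per condition (magnitude
U(0.5, 1.5), random sign). Redrawing the signed loadings is the
mechanism that makes within-module *covariation patterns* genuinely
differ between conditions — with loadings shared across conditions the
population correlation of every module pair is identical in both
conditions and there is nothing differential to detect. Null genes
replace the module term with one signed loading times one null factor
(sd sigma_null = 2), both shared across conditions: a coherent
background module whose joint structure is preserved. All genes share
the per-condition global factor F_c (sd sigma_condition = 1, loading
shared); measurement noise sd sigma_noise = 0.5; values are shifted
non-negative (|global min| + 1). Defaults give the published shape:
200 genes = 4 × 25 module genes + 100 null, 15 samples per condition.
What this does *not* emulate: count noise (no negative-binomial layer,
no mean-variance coupling), library-size artifacts, dropout, and any
regulatory directionality — influence edges inferred from factor data
reflect co-membership, not causal direction. Passing tests on this
generator therefore demonstrates recovery of planted covariation
structure, not performance on real RNA-seq.

## Desk-scale experiment sizes

The simulated-data experiments (acceptance script and acceptance tests)
use 200 trees × 10 runs with ρ = 1 on the 200-gene default simulation;
the network benchmark uses 1000 networks at N = 100 and N = 500. These
sizes keep a full experiment under ~15 minutes on one core while
preserving each measured quantity's regime; the published evaluations
use 10000 trees × 25 runs. The correlation between variationality and
the correlation-change statistic S is reported pooled across runs (each
run's per-gene MSE against the run-independent S). The Fisher-z
degree-vs-S correlation needs no pipeline run and its single-dataset
sampling spread (sd ≈ 0.21 across generator seeds) exceeds any
meaningful tolerance, so it is reported as the mean over 8 generator
replicates.

## Numerical conventions

- Percentiles: numpy linear interpolation, selections strictly above
  the threshold.
- Correlations are clipped to ±(1 − 1e-7) before Fisher's z; BH
  controls FDR over all gene pairs.
- PCA condition distance: both of a gene's condition vectors enter one
  pooled 2-component PCA; distances are invariant to axis sign. A
  per-gene PCA is not well defined, so published distance figures are
  not bit-reproducible.
- The correlation-change statistic S skips pairs whose correlation is
  undefined (zero variance) and errors only if every pair is undefined.
- Degenerate inputs: singleton modules are their own cores with k = 0
  and density 0; an empty core has reachability 0; constant inference
  targets give all-zero columns.

## Known limitations

- Girvan-Newman cannot merge components: if the integrated network is
  disconnected, its components are a floor on the module count, and
  sparse unions fragment planted modules rather than merging them.
- The maximal-k-core rule on very sparse modules yields broad, shallow
  cores (k = 1 admits whole trees).
- Run-to-run MSE noise at small tree counts attenuates the correlation
  between variationality and S; tree count trades directly against
  wall-clock time.
- All inference is on one CPU core; runs execute sequentially.
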