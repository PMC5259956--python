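# Methods

## Model and procedure

`pathrewire` detects pathways whose *interaction structure* — not their mean
expression — changes between two phenotypes. The procedure has three stages.

**Weighted networks.** The PPI graph fixes which gene pairs may interact;
expression fixes how strongly they co-vary in each phenotype. Edge weights
are `a_ij = |cor(x_i, x_j)|^β` with Pearson correlation computed within each
phenotype separately. The absolute value treats co-activation and mutual
exclusion alike as evidence of interaction intensity; `β` (default 1)
sharpens the weight spectrum if raised, with 0 and 1 as fixed points. Edges
whose endpoints are unmeasured are dropped from the topology (both networks
keep identical node and edge sets, which the scoring stage relies on);
edges with weight exactly 0 stay in the topology but carry no degree and are
never traversed. Constant expression vectors give weight 0 rather than an
error — flat probes are routine in real matrices. With missing values the
correlation uses pairwise-complete samples and falls back to 0 below three
complete pairs.

**Absorbing-walk expansion.** For seed set `S` and start `x ∈ S`, the walk
follows `P_ij = a_ij / d_i` and the other seeds absorb. With transient block
`Q` and absorbing block `R`, the probability a walk of length `L` crosses
the directed edge `(i, j)` at step `k` is `[Q^k]_{xi} Q_{ij} [Q^{L-k-2} R 1]_j`
for transient `j` (and `[Q^{L-1}]_{xi} R_{ij}` at the final step for
absorbing `j`); the walk-length law is `P[L] = [Q^{L-1} R 1]_x`. Two
aggregations over lengths are provided:

- `weighted` (default): the conditional expectation
  `E[e(x,i,j) | L ≤ L_max]`, i.e. the sum of all joint probabilities
  divided by the absorption mass `P[L ≤ L_max]`. This is what a simulation
  of absorbed walks estimates, and it stays bounded as `L_max` grows.
- `literal`: the plain sum `Σ_L E[e(x,i,j) | L]` of per-length conditional
  expectations, each defined as 0 where `P[L] = 0`. This form weights every
  feasible length equally and grows with `L_max`; it is kept as an explicit
  alternative because the two differ exactly when absorption-length
  probabilities are unequal.

The implementation collapses the weighted-mode double sum into one
convolution of forward vectors `a_k = e_x Q^k` and cumulative backward
absorption vectors, which is O(L_max · t²) per start for `t` transient
nodes; the literal mode keeps the per-length loop (O(L_max² · t²)) and is
intended for small graphs. Both are verified against an explicit
walk-enumeration oracle, a plain matrix-power transcription of the
formulas, and a Monte-Carlo simulator (`simulate_walks`).

Edge relevance sums `l_x · |net flow|` over starts, `l` uniform over `S` by
default (the initial distribution is a free choice of the method; uniform is
the least informative). A start whose absorption mass within `L_max` is
below 1e−12 — a seed cut off from the rest of `S` — is skipped and `l` is
renormalized over the remaining starts, so one stray seed cannot void a
pathway; if every start is skipped the pathway is reported unconnectable.

**Threshold and union.** θ is the largest realized relevance value whose
`ER ≥ θ` cut keeps all contributing seeds in one connected component, found
by a descending scan over distinct values with union–find (ties enter as a
group). The comparison is `≥` because θ is drawn from realized values — a
strict cut would always lose the critical connecting edge. Candidate
thresholds are restricted to *positive* relevance values: a zero-relevance
edge carries no walk flow, and admitting θ = 0 would degenerate the
expansion to the entire network. Seeds connectable only through
zero-relevance territory are therefore reported `skipped_unconnectable`.
The subnetwork keeps all edges at or above θ; its node set is `S` plus the
kept-edge endpoints, so isolated seeds remain members. The cross-phenotype
union is an *edge-set* union (not a node-induced subgraph): it is the edge
set that gives the two weight vectors one shared dimension. Both phenotype
expansions must succeed for a pathway to be scored.

**Score.** `Score = 1 − |Corr(T_w, N_w)|` with the Pearson correlation of
the union's weight vectors under one canonical (lexicographic) edge
ordering. The score is symmetric under phenotype exchange and equals 0
whenever the two networks agree. It is a ranking statistic, not a p-value;
no multiple-testing machinery applies. Ties in the ranking break by pathway
id for reproducibility. Unions with fewer than two edges or a constant
weight vector are reported `skipped_degenerate_vectors` — imputing 0 or 1
would distort the ranking. Scores are written to six decimals.

## Synthetic studies

The generator stands in for the matched expression/PPI/pathway inputs the
pipeline consumes in practice. Topology: Barabási–Albert preferential
attachment by default (PPI degree distributions are heavy-tailed), with a
uniform G(n, m) alternative; both connected and seed-deterministic.
Pathways are random connected subsets so that in-module edges exist; one
deliberate single-gene pathway exercises the skip rule.

Co-expression uses a module-factor construction: each pathway is a module
with one latent standard-normal factor, member gene `i` loads with
`sqrt(q_i)`, and residual noise tops the gene's variance up to exactly 1.
In-module edge correlations are then `sqrt(q_i q_j)` in expectation. The
per-gene strengths are drawn once — centered on the module's target with
uniform spread `loading_spread` — and shared between phenotypes, so an
edge's expected weight is a reproducible gene-pair property. That
reproducible heterogeneity is essential: the score measures preservation of
the weight *pattern* across edges, so a generator with one homogeneous
correlation level everywhere gives every pathway an asymptotically constant
weight vector and leaves the score undefined (and, at finite samples,
driven purely by noise). Decoy modules use the background center in both
phenotypes; the planted module uses its phenotype-specific centers, a
center of 0 removing the factor entirely. Decoy membership excludes planted
genes, since a decoy sharing genes with the planted module would itself be
differentially wired. Genes in several overlapping modules are rescaled
into the unit variance budget (logged); targets are approximate by contract
in that case, exact otherwise.

Default study conditions: 300 genes, ~900 edges, 100 samples per phenotype,
20 decoys centered at 0.5 in both phenotypes, one planted module at 0.8 vs
0.0, pathway sizes 10–20 mapped genes (the scale at which typical curated
pathways intersect a network), loading spread 0.35, residual-noise floor
0.2. Under these conditions the planted pathway ranks first in ≈19/20
replicate studies; with the planted centers equalized the planted label's
rank is uniform over replicates (chi-square p ≈ 0.2 over 50 reduced-size
runs).

What the generator does *not* emulate: realistic expression marginals
(counts, skewness, heteroskedasticity), batch or covariate structure,
more than two phenotypes, and negative or signed co-expression patterns
(weights are absolute correlations anyway). Passing tests therefore show
the method recovers planted differential wiring under a clean factor model,
not that it is robust to the full messiness of real cohorts.

## Numerical choices and degenerate inputs

- `L_max` defaults to 50; the absorption-mass cutoff for skipping a start is
  1e−12. Masses are monotone in `L_max` and bounded by 1.
- Literal-mode per-length terms use `P[L] > 0` exactly; on reducible
  chains infeasible lengths produce exact floating zeros, and the per-length
  expectation is bounded by `L`, so no amplification occurs near the cutoff.
- Correlations are clipped into [−1, 1] before use; weight computation
  standardizes rows once per phenotype (NaN-free fast path) or falls back to
  pairwise-complete per-edge handling.
- Walk simulation is vectorized over walks with per-step inverse-CDF
  sampling; unabsorbed walks past `L_max` are discarded, matching the
  conditional expectation being estimated. Counts use uint8/uint16 by
  `L_max`; the simulator is deliberately capped at 64 nodes — it is a
  verification oracle, not a production path.
- All tie-breaks (threshold groups, rank order, edge ordering) are
  deterministic; reruns on identical inputs are byte-identical.

## Known limitations

- Dense transition blocks make a start's cost O(L_max · n²): comfortable to
  a few thousand network genes, not engineered for a 15,000-node
  genome-scale network in one desk session (the per-pathway loop is
  embarrassingly parallel, which a future version could exploit).
- The score ignores the *identity* of rewired edges; two pathways with equal
  decorrelation are indistinguishable even if one rewires its core and the
  other its periphery.
- Expansion in a phenotype where the seeds are mutually uncorrelated picks
  essentially arbitrary connecting paths, so the union can dilute strong
  one-phenotype signals — visible in the synthetic studies as planted scores
  below 1 even at large sample sizes.
- Gene identifiers are opaque strings; any protein-to-gene mapping or symbol
  harmonization must happen upstream.
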