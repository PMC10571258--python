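# Methods

## The clustering objective

SpeakEasy 2 (SE2) clusters an undirected, weighted, possibly signed
network by maximizing *label specificity*.  Every node carries one label
at a time; for node *i* and label *ℓ*,

    spec(i, ℓ) = obs(i, ℓ) − p_ℓ · s_i

where

* `obs(i, ℓ) = Σ_{j∈N(i)} w_ij · 1[L(j)=ℓ]` is the edge weight from *i*
  to neighbors currently carrying *ℓ* (self-connections included, with
  their stored weight);
* `s_i = Σ_j w_ij` is *i*'s total strength;
* `p_ℓ = Σ_{j: L(j)=ℓ} |s_j| / Σ_j |s_j|` is the global popularity of
  *ℓ*, weighted by absolute strengths so signed networks keep
  popularities non-negative and summing to one.

The popularity correction is the algorithm's defining feature: a label
is attractive only when it is *more* common among a node's neighbors
than its global share predicts, so large clusters cannot grow merely by
being large.  Negative edges contribute with their sign — a node
connected by negative weight to a label's holders is pushed away from
that label.  Two useful identities follow directly: the rows of the
specificity matrix sum to zero (Σ_ℓ obs = s_i and Σ_ℓ p_ℓ s_i = s_i),
and a network carrying a single label scores zero everywhere, which is
why an extra mechanism (the bubble stage) is needed to escape that
fixed point.

## Input preprocessing

Edge weights must land in [−1, 1] with maximum magnitude 1:

1. if the maximum absolute off-diagonal weight is below one, all weights
   are divided by it;
2. weights already spanning [−1, 1] with low skew pass through
   untouched;
3. if the positive off-diagonal weight distribution has sample skewness
   above 2 (a conventional reading of "highly skewed"), each node's
   self-connection weight is replaced by its average off-diagonal edge
   weight.  The self-weight feeds `obs(i, own)`, so this recenters the
   stay-versus-leave balance for heavy-tailed weight distributions such
   as correlation networks after soft thresholding.

Weights outside [−1, 1] after rescaling are an error rather than being
clipped: silent clipping would change the network the user thinks they
are clustering.  Preprocessing is idempotent and never alters the
off-diagonal sparsity pattern.

## Label dynamics

One *run* initializes labels and loops the four-stage schedule
`stage_passes_per_partition` (default 5) times; one *pass* is:

    up to 10 standard steps (early exit when < 1% of nodes change)
    → bubble → 5 nurture steps → merge

The within-pass step counts (10 standard, 5 nurture, the 1% convergence
cut) are this package's choices, exposed on `SE2Params`
(`max_steps_per_stage`, `nurture_steps`, `convergence_fraction`); they
were set so that the n≈2000 benchmarks used throughout the test suite
converge well inside one pass, and they trade off runtime against how
far each pass relaxes the configuration.

**Initialization.** Labels are overloaded: `max(1, round(0.01·n))`
distinct labels are spread uniformly over the nodes (1% of n by
default).  Far fewer labels than nodes means almost all update work is
spent on labels that survive.

**Standard step.** A uniformly re-drawn 90% of *nodes*
(`update_fraction`) simultaneously adopt their argmax-specificity
label.  Only the most recent label configuration is consulted; no label
history is kept.  The 10% hold-back breaks the two-cycle oscillations
that full synchronous updates produce on small bipartite-ish binary
graphs.  Candidate labels are those incident to the node through any
edge, plus its own; for nodes with negative incident edges all live
labels are scanned, because with negative evidence an absent label
(spec = −p_ℓ·s_i > 0 when s_i < 0) can win.  Ties are broken uniformly
at random from the seeded stream (tolerance 1e−12).

**Bubble stage.** Clusters above the 90th percentile of current cluster
sizes (`bubble_size_quantile`) burst: their least-secure half
(`bubble_disperse_fraction = 0.5`), ranked by the security margin
`spec(i, own) − max_{ℓ≠own} spec(i, ℓ)`, is scattered over fresh random
labels (⌈size/median size⌉ of them, at least 2).  The largest cluster
qualifies whenever it has ≥ 4 members even if it does not exceed the
quantile — necessary because a single label covering everything is
otherwise a fixed point of every other stage.  Splitting is random by
design: structure-aware splits were considered and rejected as costing
more while recovering no better, and the subsequent nurture and merge
stages repair any damage to genuinely coherent clusters.

**Nurture stage.** Only nodes in the worst 30%
(`nurture_fit_quantile`) of current-label specificity update, by the
standard rule.  Proto-clusters with good fit persist and recruit the
stragglers instead of being churned away.

**Merge stage.** Label-level updates: the observed inter-label weight
`M_ab` is compared with the configuration-model expectation
`E_ab = S_a·S_b / (2W)` (S_x total strength of label x, W total edge
weight), the most above-chance pair is fused, and the stage repeats
until no pair is above chance.  Each merge removes a label, bounding the
stage by the label count.  Using the configuration-model null matters:
a null half this size makes every pair of genuine communities look
above-chance once half the edges run between clusters, and the dynamics
then collapse to a single community on benchmarks that are still easily
clusterable (planted-partition Q ≈ 0.4).

## Consensus and reproducibility

`independent_runs` (default 10) fully independent runs each contribute
their final label state to a partition pool, together with the dense
per-node specificity scores toward that partition's communities.  The
final partition is the pool *medoid* under pairwise NMI — the most
typical partition, deliberately not the highest-scoring one.  Ties
resolve to the lowest run index.

All randomness flows from a single root seed through
`numpy.random.SeedSequence.spawn`, one child per run, so results are
reproducible and runs could be distributed without changing output.

## Multi-community nomination

A node belonging to several communities oscillates between them across
independent runs.  Nomination uses the pool: in each partition the
node's specificity scores toward that partition's communities are
ranked, and a near-tie is recorded when `second ≥ margin · best` with
`best > 0`.  A node is flagged when near-ties occur in at least
`consistency_fraction` (default 0.5) of partitions.  Its membership
count m is the modal number of near-best communities across partitions
(clipped to [2, `max_memberships`], default cap 4), and it is placed
into the m communities of the *final* partition with the highest
scores; flagging is independent of placement.

`margin_threshold` defaults to 0.5, calibrated on the package's own
overlapping benchmarks (5% planted two-membership nodes, μ = 0.2,
n = 2000, degree 30): margins of 0.7–0.8 miss most planted nodes
(sensitivity 0.2–0.35) because a planted node's two genuine scores
fluctuate by tens of percent around parity, while 0.5 recovers
0.75–0.8 of them with specificity 1.0 and produces zero false calls on
disjoint benchmarks.  The modal rule for m is likewise a package
choice; any reasonable summary (mode, median) coincides on the
benchmarks tested.

A geometry worth knowing: when the network holds exactly two
communities, the popularity correction gives a perfectly balanced
boundary node a *positive* score toward the smaller community and a
*negative* one toward its own, so no relative margin fires.  Nomination
is therefore most informative when the network has three or more
communities — the regime every overlapping benchmark here exercises.

## Metrics

* **NMI** — mutual information normalized by the arithmetic mean of the
  two entropies (computed via scikit-learn).  The normalization choice
  is recorded because every pinned regression value depends on it.
* **ARI** — pair-counting Rand index adjusted under the permutation
  model (scikit-learn).
* **Signed modularity** — `Q = (w⁺·Q⁺ − w⁻·Q⁻)/(w⁺ + w⁻)`, with Q±
  classic Newman–Girvan modularity of the positive / negated-negative
  subgraphs; reduces exactly to classic Q when no negative edges exist.
* **Modularity density (Qds)** — per-community modularity weighted by
  internal density `d_c = 2w_in/(n_c(n_c−1))`, minus the squared
  density-weighted strength term, minus split penalties
  `(w_cc'/2W)·(w_cc'/(n_c·n_c'))` over community pairs.  Weighted
  graphs use weighted densities.  Negative edges are dropped with a
  warning — density is not meaningful below zero.
* **Omega index** — chance-adjusted agreement over node pairs on the
  *number* of shared communities; identical to ARI when both covers are
  disjoint (a property-tested identity).
* **Overlapping NMI** — the set-based best-match formulation standard
  in the benchmark literature: per-community conditional entropies
  against the best admissible match, normalized, averaged, and folded
  into `1 − (H(X|Y)ₙ + H(Y|X)ₙ)/2`.
* **Overlapping Q / Qds** — belonging coefficients split each node
  equally over its memberships (α_ic = 1/|M_i|); community sizes become
  effective sizes Σ_i α_ic.  Both reduce exactly (to 1e−12) to the
  disjoint measures on partitions.
* **Multi-community F1** — node-level confusion counts with "positive"
  meaning ≥ 2 memberships; F1 is the harmonic mean of precision and
  sensitivity, with zero denominators yielding 0.

## The benchmark generator

An LFR-style generator, not a port of any particular LFR code: its
contract is the parameter semantics and the planted-structure
properties, not byte-level agreement with other implementations.

* **Degrees** are drawn from a bounded power law with exponent
  `degree_exponent` on [lo, √(n·k̄)], where lo is solved (Brent) so the
  truncated-distribution mean equals `avg_degree` — the same pinning
  real LFR performs.
* **Community sizes** come from their own power law on
  [2·k̄, n/4], drawn until they fill n slots (plus one extra slot per
  extra membership of each overlapping node).
* **Membership**: exactly `round(overlap_fraction·n)` nodes get
  `memberships` distinct communities, chosen with probability
  proportional to remaining capacity; the rest get one.  Multi-
  community nodes split their internal degree budget equally across
  memberships.
* **Wiring**: each node aims `round((1−μ)·d)` stubs inside its
  communit(ies) and the rest outside.  Internal stubs are matched
  within each community; external stubs are matched globally with
  rejection of self-loops, duplicate edges and pairs that already share
  a community, with up to 30 reshuffle rounds before residual stubs are
  discarded.  Realized mixing tracks nominal μ to within ±0.03 at
  n = 2000.
* **Weights** are power-law draws on [0.1, 1]; cross-community edges
  are multiplied by `μ_w/(1−μ_w)` (neutral at μ_w = 0.5), then the
  whole network is rescaled so the maximum weight is 1.  The three
  regimes set the effective μ_w: `covary` ties it to μ,
  `constant_proportion` frees it while μ stays fixed, and
  `constant_weight` pins it at 0.5 while μ varies.
* Generation is a pure function of the `BenchmarkSpec`, including its
  seed; grids enumerate the Cartesian product of value lists in
  deterministic order with per-cell derived seeds.

Default exponents are degree 3.0, community size 1.5, weight 1.5 — one
cell of the conventional {1.5, 3} benchmark ranges, chosen once:
exponent 3 keeps the degree tail realistic for biological networks
while 1.5 on community sizes produces the wide size spread that makes
resolution behavior visible.

**What the generator does not emulate.**  Real expression and
interaction networks have weight–topology correlations (hub strengths,
module-specific weight scales), transitivity beyond what stub matching
induces, and noise that is not power-law.  Passing recovery tests here
shows the label dynamics find planted block structure under controlled
mixing; it does not certify performance on any particular biological
dataset.

## Numerical and degenerate-input choices

* Argmax ties anywhere in the dynamics: uniform among candidates within
  1e−12 of the row maximum, decided by the seeded stream.
* Label ids are compacted (empty labels purged) after every stage.
* Empty graphs are an error; a single-node graph returns one community
  without iterating.
* Isolated nodes have zero strength, score zero for every label, and
  simply keep whatever label initialization gave them.
* An edgeless graph's label popularity falls back to plain node counts.
* Quantile thresholds (`bubble_size_quantile`, `nurture_fit_quantile`)
  use NumPy's linear-interpolation quantile; comparisons are ≥ for
  nurture (the worst quantile updates) and strict > for bubble except
  the largest-cluster rule above.

## Problem sizes

The test suite and the reproduction script run the full pipeline at
n = 2000 and average degree 30 (the canonical benchmark cell), with 10
seeds for low-mixing recovery, 5 replicates per μ for the degradation
curve at 5 independent runs per consensus, and 3–5 seeds for
overlapping recovery; toys of 4–20 nodes carry the exactly-checkable
arithmetic.  These sizes were chosen as the smallest at which the
benchmark properties are stable across seeds.

## Known limitations

* The per-step specificity matrix is dense (n × live labels); fine to
  tens of thousands of nodes, not engineered for millions.
* The generator's shared-community lookup is an n × n boolean matrix,
  which bounds comfortable generation to n ≲ 2·10⁴.
* Qds and overlapping Qds ignore negative edges (with a warning) rather
  than defining a signed density.
* Multi-community nomination needs ≥ 3 communities to be informative
  (see above).
* The consensus medoid costs O(runs² · n) NMI evaluations; negligible
  for the default pool of 10.
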