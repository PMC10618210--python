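# Methods

## Scope and data model

`nethub` analyzes the structure of signed, directed regulatory networks and
simulates their probabilistic Boolean dynamics. A `Network` is an ordered
node list plus a directed edge list; each edge carries a sign (activating,
inhibiting, or unsigned) and optionally an interaction probability
p ∈ [0, 1]. All structural analysis runs on the *undirected projection*:
directions and signs are dropped, antiparallel edge pairs collapse to one
undirected edge, and edges are canonically ordered by sorted label pair so
that archives and tie-breaks are deterministic. When antiparallel edges
carry different probabilities the collapsed edge takes the maximum p
(minimum cost) by default — the strongest evidence that the interaction
exists — with `mean` and `min` available, since there is no canonical answer
for merging the two directions. A network is weighted only if *every* edge
has a probability; otherwise all Kruskal costs are 0 and decoding tie-breaks
purely on edge index, which keeps unweighted runs reproducible.

## Dense spanning trees

The DST objective is the total pairwise hop distance over *ordered* node
pairs (twice the unordered sum; the argmin is unchanged — the ordered
convention is the literal reading of the double sum with i ≠ j). Distance is
integer hop count along the unique tree path, never cost-weighted.

The search is a restarted genetic algorithm over edge-subset chromosomes
decoded by Kruskal's algorithm on the induced subgraph, scanning edges in
ascending (cost, index) order:

| parameter | default | notes |
|---|---|---|
| population | 200 | tournament selection, size 3 |
| generations | 500 (cap) | early stop after `patience`=30 stale generations |
| crossover | 0.8 | uniform over the union of parent gene sets |
| mutation | 0.05 / gene | replace with a uniformly random edge index |
| restarts | 10 | independent populations, common archive |
| chromosome length | N − 1 | see below |
| elitism | 1 | best individual carried over |

**Chromosome length.** Chromosomes are tree-sized (N − 1 distinct edge
indices): a connected chromosome decodes to itself, so *every* spanning tree
is representable and the co-optimal archive can in principle be complete.
Longer chromosomes are configurable, but with equal costs the index-ordered
Kruskal scan then biases which trees are reachable (on K4 the full-length
chromosome can only decode to one of the four optimal stars), which silently
truncates tie sets — hence the tree-sized default.

**Repair.** Offspring are repaired to feasibility rather than penalized
away: a union-find pass over the genes (in random order) splits them into a
spanning forest and cycle extras; random component-crossing edges are added
until the forest spans, then cycle extras are dropped to restore the length.
Chromosomes that still fail to cover or connect (possible only for
hand-supplied inputs) receive a penalty that grows with the number of
uncovered vertices and are never archived.

**Archive.** Every feasible decoded tree whose objective ties the best value
seen so far (across all restarts and generations) is stored, keyed by its
sorted edge-index signature; a strictly better value resets the archive. The
archive is a lower bound on the true co-optimal set — the GA cannot certify
exhaustiveness — which is why `brute_force_search` (enumerate all spanning
trees, score, keep the optima) serves as the oracle wherever exhaustive
enumeration is tractable. Enumeration filters all C(M, N−1) edge subsets
through an acyclicity check and its counts are cross-validated against the
Kirchhoff matrix-tree determinant and networkx's spanning-tree iterator in
the test suite.

## Minimum dense spanning trees

With edge costs w = 1 − p the problem becomes bi-objective: minimize total
distance and total selected-edge cost. The default resolution is
lexicographic — distance strictly first, cost as tie-break, with an absolute
tolerance of 1e−9 on cost equality (floating-point sums of costs must not
split genuine ties). Lexicographic ordering yields a single well-defined
"objective value" shared by all archived trees, which matches how a unique
co-optimal MDST set is naturally reported; a weighted-sum scalarization
(distance + λ·cost) is available for sensitivity analysis. Under the
lexicographic order every MDST is a DST, so the MDST archive is always a
subset of the DST archive, and with uniform costs the two coincide — both
facts are asserted as invariants.

## Hub statistics

A hub is a node with above-average connectivity. Because the co-optimal
tree set is typically large and different trees elevate different nodes,
hubs are called on the per-node *mean degree across the whole archive*. The
means always sum to exactly 2(N − 1) (each tree has N − 1 edges), a
conservation law the tests check to 1e−9. Two calling rules: `above_mean`
(mean degree strictly above 2(N − 1)/N, the tree-wide average) and `top_k`
(ties broken lexicographically for determinism). `above_mean` can flag many
marginal nodes on path-like trees, which is why `top_k` exists; ranked means
are always reported. Candidate transition pathways between two hubs are all
simple paths in the undirected projection with at most `max_length`
intermediate nodes, shortest first.

## Probabilistic Boolean simulation

Rules are per-node lookup tables: P(ON) for each combination of the node's
parents, rows in binary counting order with the first parent as the most
significant bit; parentless nodes carry a single basal probability. One
iteration = one node update: a node is drawn uniformly from the non-clamped
nodes and its bit is resampled from its table row. Clamped nodes are
excluded from the draw rather than drawn-and-reforced; the marginal dynamics
of the free nodes are identical and no iterations are wasted. A run stops
when the state equals the target (or any member of a target set, since a
phenotype may have several equivalent Boolean states) or at `max_iter`,
default 10⁶ for full-size networks. A target that violates the clamp
triggers a warning and the run proceeds (it can then only stop at
`max_iter`). Trajectories log every iteration (node, new bit) and are
exactly reproducible from (rules, init, target, clamp, max_iter, seed).

Interaction probabilities are derived from the rules as the difference of
conditional means: for parent → child, ΔP = P(child ON | parent ON) −
P(child ON | parent OFF), averaged uniformly over the 2^(k−1) configurations
of the child's other parents (no state sample is assumed; empirical-state
weighting can be supplied). Inhibitory parents give negative ΔP; the edge
probability is |ΔP| so that w = 1 − p stays in [0, 1], and the signed value
is returned alongside.

## LCS distance and pattern analysis

d_LCS(v₁, v₂) = A(v₁, v₁) + A(v₂, v₂) − 2A(v₁, v₂), with A the classic
longest-common-subsequence length (dynamic program over a rolling row;
vectors may differ in length). For equal-length binary vectors
d_LCS = 2(m − LCS), hence even, zero iff equal; the suite checks these
properties plus agreement with an independent recursive-memoized oracle.
A Hamming mode exists as a config flag for equal-length comparisons but is
not analyzed further.

The distance series holds the distance of the (clamped) initial state
followed by the distance after every iteration; a resample that leaves a bit
unchanged cannot move the distance and is recorded as a plateau without
recomputing the DP. Patterns are maximal windows whose strict changes share
one sign: a strict change opens or extends a window, plateaus are absorbed
into the open window, an opposite-sign change closes it. Leading/trailing
all-plateau stretches belong to no pattern, so strict changes partition
exactly into patterns (asserted per trajectory, together with the accounting
identity increases + decreases + plateaus = iterations). Only strict-change
steps attribute their updated node to a pattern — a plateau update did not
move the state toward or away from the target. Frequency tables count a node
once per pattern; per-iteration increase counts and the probability of each
node being ON in the states initiating decreasing patterns are reported as
well. A `min_strict_changes` filter (default 1, i.e. off) can suppress
single-step windows when analyzing noisy runs.

## Synthetic data

`generate_network` emulates a curated TF network: defaults of 35 nodes and
239 signed directed interactions (the scale of the real network the method
was developed on), a random-attachment tree backbone guaranteeing
connectivity, planted hubs receiving a configurable share (default 0.6) of
the extra edges, a 50/50 activator/inhibitor split, and interaction
probabilities drawn from Beta(2, 2) scaled to [0.05, 0.95] — spanning the
range without degenerate 0/1 costs. Everything is deterministic per seed.

`generate_threshold_rules` builds full 2^k lookup tables from the signed
structure: P(ON) = 1 − ε when active activators outnumber active inhibitors,
ε when they are outnumbered, 0.5 on a tie. Ties at 0.5 are what produce
genuine stochastic wandering during simulations, mimicking long noisy
transitions at reduced scale. Default ε = 0.05; nodes with more than 12
parents are refused (table blow-up).

**The bistable fixture** is a hand-specified nine-node system: an NE-like
module (hub H1, members A1–A3 in an activation ring) and a NON-NE-like
module (hub H2, members B1–B3) that mutually inhibit, joined by bridge BR on
the pathway H1–BR–H2. Each member has two activators and two inhibitors, so
in either attractor every net input sits at ±2 and no single noise flip
opens a tie: both basins are deep. H2 has exactly two activators (B1, B2)
and two inhibitors (H1, BR), so clamping H1 and BR ON turns its rule row
into the 0.5 tie and the NON-NE-like state unravels node by node — the
pathway-activation experiment. Both hubs are adjacent to every other node,
so the DST optimum is attained exactly by the two hub-centered stars (the
only spanning trees of diameter 2), making {H1, H2} the top-2 mean-degree
pair by construction. The fixture is built at ε = 0.001: at this nine-node
scale a 5% per-update noise would let coordinated double flips erode the
basins within a typical run, defeating the bistability the fixture exists to
demonstrate, while the clamp-driven dynamics run entirely through 0.5 ties
and are insensitive to ε. Build-time validation scans all 2⁹ states and
asserts that deterministic rounding fixes exactly the two named attractors
(`find_fixed_points`; a row probability of exactly 0.5 counts as unstable).

**What the generators do not emulate:** realistic degree distributions
beyond planted hubs, correlated rule tables fitted from expression data,
basin asymmetries of real attractor landscapes, or attractors that are limit
cycles rather than fixed points. Passing tests therefore demonstrate the
correctness of the algorithms under controlled conditions, not biological
conclusions about any particular network.

## Study sizes and numerical choices

- Oracle studies: 50 random connected graphs with N ∈ [5, 8] and
  m = n − 1 + U{1..4} edges — sparse enough for exhaustive enumeration while
  leaving non-trivial cycle space; GA at default configuration.
- Hub recovery: 20 planted-hub networks of 20 nodes / 45 edges, GA at a
  reduced configuration (population 100, generations 150, restarts 3) sized
  to the instance.
- Fixture transition ensembles: 50 seeded runs per clamp condition with
  `max_iter` = 20,000 — transitions at this scale complete in O(10²–10³)
  iterations, so the cap is comfortably above the typical transition length,
  mirroring the role of the 10⁶ production default on full-size networks.
- Cost-tie tolerance 1e−9 (absolute) wherever MDST objective values are
  compared; degree conservation asserted to 1e−9.
- Seeds: the pipeline fans a single base seed out to per-stage seeds via
  CRC32 of the stage name, so stages can be rerun independently; ensemble
  run r uses base_seed + r.

## Known limitations

- The GA archive is a lower bound on the co-optimal set; completeness is
  verified only where brute force is tractable (N ≤ 9 here). On large dense
  networks the true tie-set size is unknown.
- Directed spanning-arborescence variants of the objectives are out of
  scope, as is fitting rule tables from expression data (rule tables are
  consumed, not inferred) and alternative hub notions (betweenness,
  closeness).
- `find_fixed_points` detects only deterministic-rounding fixed points, not
  cyclic or probabilistic attractors.
- Pattern segmentation at plateau boundaries follows the convention above;
  other conventions (e.g. splitting plateaus between adjacent windows) would
  shift window boundaries but not the strict-change attribution that the
  frequency statistics are built on.
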