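# Methods

`targetspread` addresses the *localized-target spreading* problem: given an
undirected contact network and a small set of target nodes concentrated in
one region of the graph, which node should seed an epidemic-style process so
that as many targets as possible are eventually reached — ideally while
infecting few non-targets? Classical influence rankings (degree,
betweenness, k-shell) answer the global question "who infects the most
nodes" and can point far away from a localized target group; the reversed
local path (RLP) score answers the targeted question directly.

## The spreading model

We use the discrete-time SIR model on an undirected simple graph. At each
synchronous step, every infectious node transmits independently to each
currently susceptible neighbor with probability λ; a node contacted
successfully by any infector becomes infectious at the next step; the
recovery probability is fixed at 1, so every node is infectious for exactly
one step and immune afterwards. The process starts from a single seed and
stops when no infectious nodes remain.

Per candidate seed *i* and target set *T* (|T| = m) we measure, over R
Monte-Carlo realizations,

- spreading ability ρ_i — mean fraction of targets recovered at absorption,
- leakage v_i — mean fraction of non-target nodes recovered,
- 〈d_i〉 — mean shortest-path distance from the seed to the (reachable)
  targets.

Targets are never eligible as seeds (the target group is assumed
uncontactable or unwilling to initiate); the global-target benchmark
(T = all nodes) is the one exception and must be requested explicitly.

The epidemic threshold is estimated with the heterogeneous-mean-field
formula λc = 〈k〉/(〈k²〉 − 〈k〉). This is an estimate, not an exact
threshold: it is exact only at mean-field level on uncorrelated networks,
and is reported as infinite on degenerate graphs with 〈k²〉 ≤ 〈k〉 (e.g. a
perfect matching). Its role here is to anchor λ grids ("near-critical" vs
"supercritical"), not to be a precise critical point.

## The RLP score

Let A be the adjacency matrix and f the 0/1 row indicator of the target
set. The RLP score of node j is

    s(j) = Σ_{l=0}^{K-1} ε^l (f A^{l+1})_j ,      K = 3, ε = 0.1 by default,

i.e. a count of walks of length 1..K from the targets to j, discounted by ε
per extra hop. Two facts matter:

- **walks, not simple paths**: A^l counts walks, which may revisit nodes
  (including targets). On the 5-node path t–a–b–c–d with target {t}, node a
  scores 1 + 2ε² = 1.02, because *two* length-3 walks end at a (t→a→t→a and
  t→a→b→a). The implementation counts walks faithfully.
- **reversed direction**: the sum is propagated outward from the targets
  (f, fA, fA², …), so the cost scales with the size of the K-ball around
  the target set, O(m·k^K), rather than with N. Nodes farther than K from
  every target score exactly zero. The frontier implementation records how
  many nodes it touched; a test asserts this stays within the 3-ball even
  on a 10⁵-node graph.

ε plays the role of an effective per-hop transmission weight (Katz-style
attenuation); 0.1 is near-optimal across the benchmark networks, and both ε
and K are exposed (`RLPParams`). Scores are linear in f, hence additive
over targets and monotone under adding targets — both are property-tested.
A dense matrix-power implementation (`rlp_scores_dense`) exists purely as a
cross-check oracle; frontier and dense agree to 1e-12.

## Baseline rankings

- **degree** — neighbor count.
- **betweenness** — raw unordered-pair sum b_i = Σ_{a<b, a≠i≠b}
  n_ab(i)/n_ab with no normalization; computed by Brandes dependency
  accumulation (igraph), asserted equal to a brute-force all-shortest-path
  enumeration oracle on random graphs. Scale is irrelevant to rank
  correlations, but the oracle must match the implementation exactly.
- **k-shell** — iterative peeling index (core number). On WS/BA graphs it
  is nearly constant and therefore uninformative; experiments may omit it.
- **local degree (LD)** — degree inside Ω (nodes within distance 3 of the
  target set, the same radius as RLP's default K), zero outside.

## Target placement

- *random*: m distinct nodes, uniform without replacement.
- *localized*: a center plus m−1 nodes drawn uniformly from the
  shortest-path ball of radius L around it (the center is itself a target).
  When no center is given, centers are drawn uniformly and re-drawn (budget:
  100) until the ball is large enough; a structural infeasibility (no node
  has a radius-L ball with m−1 others, e.g. m=20 within L=2 on a WS ring
  with 〈k〉=4, whose 2-balls hold at most ~18 nodes) raises an error that
  reports the largest ball seen. With L = ∞ localized placement reduces
  exactly to random placement on a connected graph (chi-squared-tested).

## Ranking evaluation

Accuracy is Kendall's tau between a method's scores and the simulated ρ of
all candidate (non-target) seeds. The default is tau-a — concordant minus
discordant pairs over C(n,2), ties contributing zero — matching the sign
formula; tau-b (tie-corrected, via scipy) is available because degree and
k-shell produce heavy ties. Every result row records which variant was
used. Inside one accuracy evaluation, ρ is estimated with R_sir
realizations per candidate seed (default 100); outer averaging is over
independent redraws of the network and target set. All experiment rows
carry the RNG seeds used, and rerunning any harness with the same base seed
is byte-reproducible.

### Coverage curves and the matched global benchmark

`coverage_curves` estimates 〈ρ〉(λ) for three scenarios — global targets,
m random targets, m localized targets — averaging over fresh target sets,
uniform eligible seeds and single SIR runs. Because the seed-eligibility
constraint holds in every scenario, the global benchmark reports the attack
rate among *non-seed* nodes, (|recovered|−1)/(N−1). This is the estimand
matched to "fraction of targets infected when the seed is never a target":
with it, the random-target curve equals the global curve in expectation
exactly (uniform non-seed targets are exchangeable with uniform non-seed
nodes), whereas counting the always-recovered seed in the global attack
rate would leave a structural +1/N offset that dominates the Monte-Carlo
error at subcritical λ. The localized curve falls below the benchmark in
the subcritical regime; mechanically, a localized target cluster is a
seed-poor neighborhood (its surroundings are mostly targets, which cannot
seed), so small outbreaks rarely reach it.

### ρ–v trade-off

`rho_v_tradeoff` takes each method's top-ranked candidate seed (ties broken
by smallest internal index, recorded in the output) and traces its (v, ρ)
pair across λ. Comparisons between methods are made at matched leakage by
interpolating one method's ρ over the other's v values.

## Synthetic networks

Generators (networkx-backed, seed-deterministic): Barabási–Albert
preferential attachment (default N=500, 2 links per arrival, 〈k〉≈4),
Watts–Strogatz (N=500, ring degree 4, rewiring 0.1 — rewiring preserves
the edge count so 〈k〉=4 exactly), and a planted-partition (GN-style)
community benchmark parameterized by the fraction of links kept inside a
community. These are the benchmark conditions used throughout the tests
and the acceptance script. What they emulate: heavy-tailed degrees and
hubs (BA), homogeneous small-world structure with tunable locality (WS),
community structure (GN). What they do not emulate: degree-degree
correlations, clustering patterns, and the very large diameters of real
collaboration/protein networks, where the localization effect is stronger
— passing tests on these generators shows the machinery and the
qualitative orderings, not the magnitudes reported for any real network.
The harness loads any whitespace-delimited edge list, so real networks can
be analyzed when the user supplies them.

## Problem sizes and numerical choices

- Scaled-down experiment sizes used by the acceptance checks: N=500
  networks; τ-vs-λ with 200 outer redraws × R_sir=100 (tests) or 60 outer
  redraws (`scripts/acceptance.py`); the (m, L) grid with 100 (tests) / 50
  (script) redraws; coverage curves with 5000 realizations per (scenario,
  λ) point — the realization count used for synthetic-network sweeps, and
  the level at which the subcritical localized departure (an absolute
  effect of ~10⁻³ on WS) is statistically resolvable; trade-off with 100
  redraws.
- λ grids default to 12 points on [0.2 λc, 3 λc], capped at 1.
- Monte-Carlo batches run in numba-compiled kernels seeded explicitly
  (MT19937); a fixed root seed gives bit-identical results. The kernel
  skips redundant contact draws on nodes already infected within a step —
  distributionally identical, since infection occurs if any contact
  succeeds.
- Frontier/dense RLP agreement is asserted at 1e-12 absolute; betweenness
  vs oracle at 1e-9; closed-form SIR checks at 3 standard errors with
  R=10⁴.
- Degenerate inputs: empty target sets, all-target seed pools, infeasible
  localized placements, disconnected targets in 〈d〉, and 〈k²〉≤〈k〉
  thresholds all raise typed errors or report inf/NaN as documented rather
  than failing silently.

## Known limitations

- Only μ=1 (one-step infectiousness) SIR; no SIS/SEIR, no continuous time,
  no weighted or directed edges.
- λc is a mean-field estimate; on small or highly clustered graphs the
  effective threshold can differ noticeably.
- tau-a with heavily tied scores (k-shell on WS) is depressed toward zero
  by construction; use tau-b when tie correction matters.
- Betweenness cost on very large graphs is O(N·E); the experiment harness
  recomputes it per network redraw.
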