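# Methods

## Diffusion model

Diffusion follows the discrete-time SI model on an undirected simple graph
with a fixed, symmetric per-edge transmission probability `P_uv` drawn once
per edge from Uniform(0, 1) (the network is a static weighted object, not
re-randomized per attempt). Updates are synchronous: the set of nodes
infected at step `t` is computed entirely from the state at `t − 1`, and a
susceptible node's one-step infection probability is the noisy-or hazard
`λ(v) = 1 − Π_{u∈I_v}(1 − P_uv)` over its currently infected neighbors.
Infected nodes never recover. The marginal recursion
`P_I(v,t) = λ(v,t)·P_S(v,t−1) + P_I(v,t−1)` is not solved as a separate
deterministic system; the simulator is validated against the hazard's
closed form by Monte-Carlo in the test suite instead.

A run stops at the first step after which the infected fraction *strictly
exceeds* `stop_fraction` (default 0.30), or at `max_steps` (default
`10·|V|`, a safety cap that guarantees termination, e.g. when every edge
probability is vanishingly small), or when the frontier empties (a fully
infected component). Because the check happens after a full synchronous
step, the final snapshot can overshoot the nominal fraction considerably:
on ER networks with mean degree 10 a single explosive step routinely doubles
the infected set, so a 30% stop commonly yields 55–65% infected. This is an
inherent property of a post-step threshold under synchronous dynamics and
is deliberately not smoothed away; consumers who need snapshots near a
target fraction should use smaller stop fractions.

## Score stack and locators

The entropy stack follows the definitions listed in the README. Numerical
conventions, all of which matter in edge cases:

* `0·log2 0 := 0` in both entropies (needed when `ξ = 0`).
* Contribution ratios `ψ > 1` are kept as negative entropy terms — `AE`
  and `NE` may be negative; nothing is clamped or normalized.
* `ξ` is computed over the **full-network** neighborhood (counting
  uninfected neighbors is its purpose), while the sums in `η`, `ψ`, `AE`
  and the core-set comparison run over **infected** neighbors only. This
  guarantees `η_j > 0` for every infected `j` that has an infected
  neighbor (the `t = i` term is strictly positive), so `ψ` is always
  defined inside `AE`. A switch (`eta_neighbors="all"`) extends the `η`
  sum to all neighbors for sensitivity analysis.
* An isolated node's `ξ` is undefined; it is taken as 0 with a warning.
  An infected node with no infected neighbors gets `AE := 0` and
  qualifies for the core set vacuously — it is plausibly an un-spread seed.
* If the strict local-maximum rule selects nothing (possible only on
  perfectly NE-symmetric snapshots such as a fully infected cycle), the
  core set falls back to the single node of globally maximal NE, ties to
  the smallest node id: a locator must always return at least one node.
* `α` defaults to 4, the setting at which localization performs best in
  our replicated benchmarks; it is exposed everywhere.

## Cluster division

The infected set is divided around the `r` cores in two deterministic
steps, with all neighborhoods taken in the infected subgraph (the division
operates on the infection network):

1. Each infected direct neighbor of a core joins the most similar core
   under the second-order common-neighbor similarity
   `Sim(n1,n2) = Com(n1,n2)/|N(n1)∪N(n2)| + Σ_{i∈N(n1)}Σ_{j∈N(n2)} Com(i,j)/|N(i)∪N(j)|`,
   where the double sum includes every pair literally and `Com(x,x) :=
   |N(x)|`. Ties go to the core with larger NE, then the smaller id.
   Because common-neighbor counts vanish identically on tree-like or
   disconnected regions, the argmax ranges only over cores with *positive*
   similarity; when every similarity is zero the node stays with a core it
   is directly adjacent to. Without this restriction, an all-zero tie
   would ship nodes to a lexicographically-first core in a different
   component, which contradicts the intent that disconnected infected
   components form separate clusters.
2. The remaining infected nodes are swept breadth-first outward from the
   assigned frontier (nodes at equal depth in ascending id order). Each
   joins the cluster(s) with which it shares the most edges among
   already-assigned neighbors; an exact tie places it in *all* tied
   clusters — the only way overlapping membership arises. Nodes in
   components containing no core fall back to the nearest core by shortest
   path, ties to the smallest cluster index.

Cores are members of their own cluster (and no other), so a cluster's
cohesion maximizer can coincide with its core and the SLBIC union then
adds nothing for that cluster.

## Cohesion and SLBIC

Within each cluster, a member's cohesion blends a distance-histogram
centrality with its NE, 50/50. Distances are shortest paths in the
infected subgraph — paths may traverse infected non-members, since that is
the network the information actually moved through, and cluster-induced
subgraphs can be disconnected by overlap ties. Unreachable members are
omitted from the histogram; an empty histogram (singleton cluster) leaves
only the `0.5·NE` term. The normalizer `APN` is the number of *distinct*
distance values by default; `apn="reachable"` divides by the number of
reachable members instead, making the histogram weights a probability
distribution. Both conventions are tested against an independent
re-implementation. The NE term enters raw by default (mixed scales and
all); `normalize_ne=True` min–max rescales NE within the cluster.
Per-cluster argmax ties break by larger NE, then smaller id.

SLBIC predicts `C_s ∪ C_s1`; the SLBNE prediction is always contained in
it, so SLBIC's recall dominates SLBNE's replicate by replicate while its
precision may drop — SLBIC suits recall-first settings with many sources.

## Evaluation protocol

Precision/recall/F with β = 1; F is 0 when both components are 0. The
average error distance Δ averages, over true sources, the distance to the
nearest prediction, then adds `ρ·||S*|−|Ŝ||` (ρ = 0.5) once inside the
`1/|S*|` factor — the only reading that makes Δ a single number.
Unreachable pairs are capped at `|V|` so Δ stays finite on disconnected
graphs. Count accuracy is the fraction of replicates with
`|Ŝ| = |S*|`.

The harness repeats the full protocol per replicate: draw the network
(synthetic families are re-drawn each replicate so results describe the
ensemble, not one instance), sample `m` seeds uniformly (adjacent seeds
are allowed), assign Uniform(0, 1) edge probabilities, diffuse, locate,
score. Every replicate's randomness is spawned from one master
`SeedSequence`, making runs bit-reproducible. The random-guess control is
size-matched to SLBNE's prediction on the same replicate, so its F-score
is exactly the chance level for that prediction size.

## Problem sizes

The shipped benchmarks and the reproduction script use ER(N = 500, mean
degree 10) with m = 5 sources and 50 replicates, plus the 34-node karate
fixture; these sizes give stable means (SE of mean F ≈ 0.02) while keeping
a full reproduction run around a minute on one core. Larger grids
(N = 1000, degrees 8–12, BA networks) are a `BenchmarkConfig` away.

## Synthetic data: what it does and does not emulate

The generator produces ER/BA topologies with i.i.d. Uniform(0, 1) edge
transmissibilities and uniformly placed seeds. It does not emulate degree
assortativity, community structure, temporal contact patterns, or
heterogeneous per-node susceptibility; passing benchmarks here show the
locators beat chance under the stated diffusion model, not that they
transfer to any particular real contact network. The karate fixture
provides one small real topology (its clustering 0.5706 and mean shortest
path 2.408 are asserted in tests).

## Known limitations

* The entropy signal degrades as the infected fraction grows: deep inside
  a large infected ball, boundary effects vanish and NE approaches a hub
  score. Localization is markedly better on early snapshots (asserted as a
  trend test at 10% vs 20% stops).
* `|C_s|` typically exceeds the true source count on dense snapshots
  (local maxima are plentiful), so count accuracy is low in that regime;
  the strict-maximum rule also cannot place two adjacent sources in `C_s`,
  which is exactly the gap SLBIC narrows.
* Undirected graphs only; no SIR/SEIR compartments, no continuous-time
  dynamics, no temporal networks.
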