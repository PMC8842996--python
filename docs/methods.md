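# Methods

This note documents the models and procedures implemented in `hiaerpart`,
the assumptions behind them, the tunable parameters and their defaults, and
the design decisions taken where more than one reasonable choice existed.

## The mapping problem

A spiking neural network is, for mapping purposes, a directed multigraph of
synapses over N neurons. The target machine is a tree of routers (HiAER: a
hierarchical address-event representation interconnect): K leaf cores, each
holding about N/K neurons and their synaptic tables, grouped recursively by
branching factors `b_top x ... x b_1` (written e.g. `2x4x8`, top level
first). Spikes travel as address events; intra-core fan-out (level 0) is
free, and crossing a level-ℓ boundary costs one message on the level-ℓ
interconnect, which is assumed progressively more expensive with ℓ. Because
synaptic weights are stored at the destination, one routed connection per
(neuron, destination core) pair serves any fan-out within that core. The
mapping problem is to choose (a) a balanced neuron→core assignment and (b) a
core→tree-slot placement that together minimize per-level message counts.

All of this is purely topological: no weights, delays, spike timing or
activity models enter anywhere. Message counts assume unit firing — every
neuron fires exactly once — so the reported traffic is the static per-spike
connection count, not a rate estimate.

## Routing-cost model

Both routing modes are counted by a recursion over the address tree, with an
independent carrier-queue simulator (`simulate_delivery`) used in the test
suite to cross-check the counters case-exhaustively.

**Multicast (mask routing).** A carrier core that must reach destination
cores at divergence level ℓ emits *one* message at level ℓ whose destination
field is a mask of sibling subtrees. In each masked subtree the message
lands on the core with the carrier's relative address ("same core index");
if that subtree contains destination cores other than the landing core, the
landing core re-emits locally, one level down, and so on.

**Unicast.** Every message addresses exactly one core. For each destination
subtree at level ℓ the carrier sends one message to the lowest-addressed
destination core inside it (a deterministic tie-break; the scheme needs
*some* representative and no rule is canonical), which then forwards to the
remaining cores of that subtree.

**Relay connections.** A message is counted as a relay connection iff it is
emitted by a core other than the original source, or its recipient must
forward the event further. Direct terminal messages from the source are not
relays. This definition reproduces the worked two-cluster example in both
modes (unicast: one L2 relay to the representative core plus two L1 relays
it emits; multicast: one L2 relay plus one relay-emitted L1 mask per
destination cluster).

Properties that hold by construction and are asserted in tests: per-neuron
multicast top-level messages never exceed unicast's; with a top branching
factor of 2 the top-level counts of the two modes coincide (at most one
remote top group per neuron); adding a destination core never decreases any
level's count; purely intra-core connectivity routes nothing.

## Partitioning

**Flat partition.** The synapse graph is symmetrized, deduplicated and
stripped of weights (duplicate directed synapses are retained in the graph
object but deliberately do *not* weight the partition), then split into K
parts. Balance is enforced as `max part ≤ ceil((N/K)(1+ε))` with
`ε = 0.03` by default, plus a floor of `floor(N/K)` per part so sizes stay
within one neuron of even when N does not divide K.

**Backend.** The balanced k-way step is a pluggable callable. The built-in
backend is recursive bisection: a greedy graph-growing initial split (absorb
the frontier vertex most connected to the growing side; the best of several
seeded starts on small subproblems), followed by Fiduccia–Mattheyses-style
single-vertex gain refinement inside the balance band, with vertex locking
per pass and a diminishing-returns cutoff (a pass must improve the cut by at
least 0.05%). When a split must be *exactly* balanced — as in core
placement, where groups have rigid sizes — refinement uses Kernighan–Lin
pair swaps on a dense view instead, since single moves cannot preserve exact
balance. Uneven part counts (e.g. K = 3) are handled by proportional-size
bisection. The backend is deterministic given its seed. On small
block-structured instances (K ≤ 8) it matches the optimum found by
exhaustive enumeration of all balanced groupings, which the tests verify.

**Hierarchical placement.** From a flat assignment, the core adjacency
A[i][j] counts neurons in core i with at least one postsynaptic target in
core j (each (neuron, destination core) pair once). Its symmetrization
B = A + Aᵀ is the communication-cost graph. Placement recurses top-down:
split the K cores into `b_top` equal groups minimizing cut weight of B,
restrict B to each group (connections to other groups are dropped), and
recurse with the remaining branching factors. Top-down ordering encodes the
assumption that the highest levels are the most expensive to cross. Within
a bottom-level group, cores take slots in ascending core-id order — sibling
order at every node is traffic-invariant, so this is purely cosmetic.
Hierarchies whose prefix products do not divide K are rejected rather than
approximated.

**Baselines.** `random_assignment` chops a uniform permutation into K
near-equal blocks (the balanced-random baseline all reductions are measured
against); `flat` keeps the flat partition but places cores at uniformly
random tree slots (optimal for a single-level router, baseline for deeper
trees). Random assignment uses the identity placement, which is
distributionally equivalent to any other placement under a uniform random
assignment.

## Synthetic network generator

The generator emulates locally-dense, globally-sparse connectivity with
known ground truth. Neurons live in K blocks of `n_per_core` (default 1000)
under the identity placement. For a source core, let `n_i` be the number of
candidate destination neurons at divergence level i (`n_0 = n_per_core`
locally). With spread factor λ ∈ [0, 1], level i carries total probability
`u·λ^i·n_i`, normalized by `u·Σ_i n_i·λ^i = 1`, uniform within the level.
λ = 1 is a uniformly random graph; λ = 0 is purely intra-core.

Each neuron emits exactly `fan_out` synapses (constant out-degree, not
merely an average — this makes the total exactly `K·n_per_core·fan_out` and
pins down the full-scale network sizes exactly, e.g. 32,000 neurons × 256 =
8,192,000 synapses for `4x8`). Destinations are distinct within a neuron
and exclude the neuron itself.

**Sampling scheme.** Per-neuron level counts are drawn from
`Multinomial(fan_out, level masses)`, then destinations are chosen uniformly
without replacement inside each (disjoint) level pool. This stratified
scheme keeps per-level counts exactly binomial — the property the
generator's statistical test checks — whereas strict successive weighted
sampling without replacement would bias level marginals noticeably once
`fan_out` is a sizable fraction of the local pool (256 draws against a
1000-neuron local pool). If a drawn count exceeds a pool's capacity (only
possible when `fan_out` approaches the pool size), the row is redrawn; after
20 failed rounds the counts are clamped to capacity and the excess is
reallocated to levels with room, proportionally to their remaining mass.

**Other generators.** Small-world networks are Watts–Strogatz ring lattices
(k even neighbours, per-edge rewiring probability p, duplicate/self edges
skipped so the undirected edge count is exactly nk/2), materialized as two
directed synapses per edge so the direction-aware router is well defined.
The rewiring probability is exposed as a required parameter (default 0.1)
and recorded in every report. Feedforward stacks are complete bipartite
between consecutive layers with no intra-layer or feedback synapses.
`shuffle_labels` applies a uniform relabeling before partitioning so the
generative block structure cannot leak into the partitioner, returning the
permutation for ground-truth bookkeeping.

**What the generator does not emulate.** Real connectomes have heavy-tailed
degree distributions, reciprocity structure, cell-type-specific wiring and
spatially inhomogeneous density; the synthetic model has constant
out-degree and exchangeable neurons within a level. Passing the λ-limit
tests therefore demonstrates that the pipeline recovers planted hierarchical
structure and degrades gracefully to random — not that equal reductions will
be obtained on any particular biological network.

## Experiment harness

An experiment fixes a network and hierarchy, then averages `trials` (default 5)
re-seeded repetitions on the *same* graph: per trial, the label shuffle, the
partitioner seed and the random baselines are re-drawn from
`SeedSequence([base_seed, trial])`. The flat partition is computed once per
trial and shared by the hierarchical and flat methods. Reports store
absolute per-level message and relay counts, reductions versus both the
random and flat baselines (both comparisons are emitted because either can
be the relevant reference), per-trial seeds, and library versions; re-running
with the same config and seed reproduces every number bit-for-bit. Mean and
sample standard deviation are reported per cell even when the sd is tiny.
A reduction against a zero baseline with nonzero method traffic is flagged
as undefined (`null`) rather than fabricated.

## Problem sizes and numerical choices

Desk-scale presets (50–200 neurons/core, K ≤ 64) are the package's default
experiment sizes; the full-scale `4x8`/`2x4x8` generator configurations
(1000 neurons/core, fan-out 256) are included as named presets and used for
the exact synapse-total checks. The spread-factor limit experiments run at
`4x8`, 200 neurons/core, fan-out 64, 5 trials — large enough for the limit
behaviour (λ = 1 reductions within a fraction of a percent of zero;
λ = 0.001 top-level reduction above 99%) to be stable across seeds while
keeping a full run in minutes on one core.

Numerical notes: level masses are normalized in double precision and sum to
1 within 1e-12; `0^0 = 1` so the local term always carries mass at λ = 0;
all randomness flows through `numpy.random.Generator` seeded explicitly, and
every derived seed is reduced below 2^31. Partition-refinement tie-breaks
(equal gains, equal cuts) resolve by lowest vertex index, making the backend
reproducible; ties among equal-cost placements are resolved by the backend
seed and averaged over trials.

## Known limitations

* The router counts messages, not congestion, latency, energy or queueing;
  mask capacity is assumed sufficient for any subtree fan-out.
* The multicast landing rule is the literal "same relative index"; landing
  directly on a destination core when one exists in the masked subtree might
  be cheaper but is not modelled.
* The built-in partitioner is a single-level recursive-bisection heuristic,
  not a multilevel coarsening scheme; on very large graphs (millions of
  neurons) a multilevel backend plugged into `PartitionConfig.backend` will
  be both faster and better.
* Hierarchies must divide K exactly at every level; ragged trees are out of
  scope.
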