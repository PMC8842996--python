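# hiaerpart

Hierarchical, hardware-aware partitioning of spiking neural networks onto
tree-structured multi-core neuromorphic systems, with a routing-cost model
for scoring the result.

## The problem

Large-scale spiking network models have locally dense, globally sparse
connectivity. Neuromorphic machines built around hierarchical address-event
routing (HiAER) exploit this: K compute cores, each holding ~N/K neurons and
their synaptic tables, sit at the leaves of a tree of routers described by
branching factors `b_top x ... x b_1` (e.g. `2x4x8` = 64 cores). Intra-core
fan-out (level L0) is free; every crossing of a level-ℓ boundary costs a
message on that level's interconnect, and higher levels are more expensive.
Because weights live at the destination, one routed connection per
(neuron, destination core) serves any fan-out inside that core.

Mapping a network onto such a machine therefore has two coupled halves,
both provided by this package:

1. **Flat partition** — a balanced K-way split of the (symmetrized,
   unweighted) synapse graph assigning neurons to cores.
2. **Hierarchical placement** — build the core-adjacency matrix
   `A[i][j]` = number of neurons in core i with ≥1 postsynaptic target in
   core j, symmetrize `B = A + Aᵀ`, and recursively partition the K-core
   weighted graph top-down along the branching factors so that heavily
   communicating cores share subtrees.

Quality is *not* edge cut: it is the number of messages per level under two
routing schemes — **multicast** (one masked message per level crossing,
landing at the carrier's relative core index in each masked subtree, with
relay re-emission below) and **unicast** (one message per destination
subtree to its lowest-addressed destination core, which forwards the rest).
Both are compared against balanced random assignment, the percent message
reduction per level being the figure of merit.

The package also ships the generators used to exercise the method: a
hierarchical synthetic generator with planted ground truth (level-i
connection probability ∝ `u·λ^i`, spread factor λ ∈ [0,1]; λ=1 uniform
random, λ→0 purely local), Watts–Strogatz small-world networks, and deep
feedforward stacks. Real connectome edge lists (CSV/TSV or MatrixMarket)
load through the same interface.

## Worked example

Partition a 6,400-neuron synthetic network (32 cores of 200 neurons,
fan-out 64, spread factor λ = 0.01) onto a `4x8` hierarchy, and compare the
hierarchical mapping against the flat (random-placement) and
balanced-random baselines over 5 re-seeded trials:

```python
from hiaerpart import ExperimentConfig, HierarchySpec, run_experiment, summary_table

cfg = ExperimentConfig(
    spec=HierarchySpec((4, 8)),
    network={"type": "synthetic", "n_per_core": 200, "fan_out": 64, "lambda": 0.01},
    trials=5,
    seed=1,
)
report = run_experiment(cfg)
print(summary_table(report).round(2).to_string(index=False))
```

which prints (columns abridged):

```
      method      mode  level  messages_mean  messages_sd  reduction_vs_random_pct_mean  reduction_vs_flat_pct_mean
        flat multicast      1        14077.8       382.68                         45.01                        0.00
        flat multicast      2         6147.2        82.94                          3.95                        0.00
hierarchical multicast      1         7095.2        13.48                         72.28                       49.57
hierarchical multicast      2          834.0         0.00                         86.97                       86.43
hierarchical   unicast      1        20359.0         0.00                         86.75                     -111.77
hierarchical   unicast      2          872.0         0.00                         95.46                       92.40
      random multicast      1        25600.0         0.00                          0.00                      -81.96
      random multicast      2         6400.0         0.00                          0.00                       -4.13
```

Reading it: every neuron fires once, and `messages_mean` counts the
resulting per-level messages. The hierarchical mapping cuts top-level (L2)
multicast traffic by 87% against balanced random assignment and by 86%
against the same partition with random core placement — the placement, not
just the partition, carries the gain. Unicast L1 messages *rise* versus the
flat baseline (−112%) while L2 falls 92%: the placement deliberately trades
expensive top-level crossings for cheap within-cluster relays. Standard
deviations across the 5 trials are small, and the identical `seed` makes
every number bit-for-bit reproducible.

The same pipeline is scriptable from a shell:

```bash
hiaerpart run --preset desk_synthetic --spec 4x8 --trials 5 --seed 1 --out results/demo
hiaerpart generate --config gen.yaml --out net.csv
hiaerpart partition --graph net.csv --spec 4x8 --seed 2 --out part.csv
hiaerpart place --graph net.csv --partition part.csv --spec 4x8 --out plc.csv
hiaerpart evaluate --graph net.csv --partition part.csv --placement plc.csv --spec 4x8
```

See `docs/methods.md` for the routing semantics (including what counts as a
relay connection), the partitioning backend, the generator's sampling
scheme, and known limitations.

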