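"""Test-network generators: hierarchical synthetic, small-world, feedforward.

The synthetic generator emulates the locally-dense / globally-sparse
connectivity the HiAER tree is designed for.  Neurons live in K cores of
``n_per_core`` neurons each, laid out in blocks (core c holds neurons
``[c*n_per_core, (c+1)*n_per_core)``) under the identity core placement.
Each neuron draws a fixed number ``fan_out`` of distinct postsynaptic
destinations from a level-structured probability density: the probability of
targeting any particular neuron at hierarchy distance i from the source core
is ``u * lambda**i``, where the spread factor ``lambda`` in [0, 1] controls
how quickly connectivity decays with hierarchy level and u normalizes
``u * sum_i n_i * lambda**i = 1`` over the per-level candidate pools n_i.
``lambda = 1`` is a uniformly random graph; ``lambda -> 0`` is purely local.

Because the generator knows the block layout it also returns the generative
ground-truth assignment and placement, so partitioning experiments can
measure recovery after the neuron labels are shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_model import (
    CoreAssignment,
    CorePlacement,
    HierarchySpec,
    NeuronGraph,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "LevelPDF",
    "level_connection_pdf",
    "generate_synthetic",
    "generate_small_world",
    "generate_feedforward",
    "shuffle_labels",
    "generate_from_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the hierarchical synthetic network.

    ``n_per_core`` defaults to 1000 neurons per core; ``fan_out`` is the
    exact out-degree of every neuron (constant, not merely average, so
    synapse totals are exact); ``spread`` is the spread factor lambda
    in [0, 1].
    """

    spec: HierarchySpec
    n_per_core: int = 1000
    fan_out: int = 64
    spread: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spread <= 1.0:
            raise ValidationError(f"spread factor must be in [0, 1]: {self.spread}")
        if self.n_per_core < 1 or self.fan_out < 1:
            raise ValidationError("n_per_core and fan_out must be positive")

    @property
    def n_neurons(self) -> int:
        return self.n_per_core * self.spec.n_cores


@dataclass(frozen=True)
class LevelPDF:
    """Normalized per-level connection distribution for one source core.

    ``level_mass[i]`` is the total probability of targeting level i
    (``u * spread**i * level_pool[i]``); within a level every candidate
    neuron is equally likely.  Level 0 is the source's own core.
    """

    u: float
    level_mass: dict[int, float]
    level_pool: dict[int, int]

    def masses_array(self, n_levels: int) -> np.ndarray:
        return np.array([self.level_mass[i] for i in range(n_levels + 1)])


def _level_core_lists(spec: HierarchySpec, source_core: int) -> list[np.ndarray]:
    """Cores grouped by divergence level from ``source_core`` (levels 0..n)."""
    comps = np.empty((spec.n_cores, spec.n_levels), dtype=np.int64)
    rem = np.arange(spec.n_cores)
    for i, b in enumerate(reversed(spec.branching)):
        comps[:, spec.n_levels - 1 - i] = rem % b
        rem //= b
    diffs = comps != comps[source_core]
    lvl = np.where(diffs.any(axis=1), spec.n_levels - np.argmax(diffs, axis=1), 0)
    return [np.flatnonzero(lvl == i) for i in range(spec.n_levels + 1)]


def level_connection_pdf(config: SyntheticConfig, source_core: int) -> LevelPDF:
    """Evaluate the per-level connection distribution for one source core."""
    spec = config.spec
    if not 0 <= source_core < spec.n_cores:
        raise ValidationError(f"source core {source_core} out of range")
    groups = _level_core_lists(spec, source_core)
    pools = {i: int(groups[i].size) * config.n_per_core for i in range(spec.n_levels + 1)}
    # lambda**0 == 1 even at lambda == 0: the local term always carries mass
    weights = np.array(
        [pools[i] * config.spread**i for i in range(spec.n_levels + 1)], dtype=float
    )
    total = weights.sum()
    if total <= 0:
        raise ValidationError("degenerate level distribution: no candidate neurons")
    u = 1.0 / total
    masses = {i: float(weights[i] * u) for i in range(spec.n_levels + 1)}
    # feasibility: fan_out distinct draws must fit in the pools that carry mass
    capacity = sum(
        (pools[i] - (1 if i == 0 else 0)) for i in range(spec.n_levels + 1)
        if masses[i] > 0
    )
    if config.fan_out > capacity:
        raise ValidationError(
            f"fan_out={config.fan_out} exceeds the {capacity} reachable neurons"
        )
    return LevelPDF(u=u, level_mass=masses, level_pool=pools)


def _sample_distinct(rng: np.random.Generator, pool: int, k: int) -> np.ndarray:
    """k distinct uniform draws from range(pool)."""
    if k > pool:
        raise ValidationError(f"cannot draw {k} distinct values from pool of {pool}")
    if 3 * k >= pool:
        return rng.permutation(pool)[:k]
    out = np.unique(rng.integers(0, pool, size=k))
    while out.size < k:
        out = np.union1d(out, rng.integers(0, pool, size=k - out.size))
    return out


def generate_synthetic(
    config: SyntheticConfig,
) -> tuple[NeuronGraph, CoreAssignment, CorePlacement]:
    """Generate a hierarchical synthetic network with known ground truth.

    Every neuron emits exactly ``fan_out`` synapses onto distinct
    destinations (self excluded): per-neuron level counts are drawn from
    Multinomial(fan_out, level masses) and destinations are then chosen
    uniformly without replacement inside each (disjoint) level pool.  Total
    synapse count is exactly ``K * n_per_core * fan_out``.  Returns the graph
    together with the generative block assignment and identity placement.
    """
    spec = config.spec
    n0, K, fan = config.n_per_core, spec.n_cores, config.fan_out
    N = n0 * K
    if fan >= N:
        raise ValidationError(f"fan_out={fan} must be < N={N}")
    rng = np.random.default_rng(config.seed)
    nL = spec.n_levels

    pre = np.empty(N * fan, dtype=np.int64)
    post = np.empty(N * fan, dtype=np.int64)
    pre[:] = np.repeat(np.arange(N), fan)

    for core in range(K):
        pdf = level_connection_pdf(config, core)
        groups = _level_core_lists(spec, core)
        masses = pdf.masses_array(nL)
        caps = np.array(
            [pdf.level_pool[i] - (1 if i == 0 else 0) for i in range(nL + 1)]
        )
        counts = rng.multinomial(fan, masses, size=n0)
        bad = np.flatnonzero((counts > caps).any(axis=1))
        tries = 0
        while bad.size and tries < 20:  # vanishingly rare unless fan_out ~ pool size
            counts[bad] = rng.multinomial(fan, masses, size=bad.size)
            bad = bad[(counts[bad] > caps).any(axis=1)]
            tries += 1
        for j in bad:
            # saturated pools: clamp to capacity and reallocate the excess to
            # levels with room, proportionally to their remaining mass
            row = np.minimum(counts[j], caps)
            excess = fan - int(row.sum())
            while excess > 0:
                w = masses * (row < caps)
                w_sum = w.sum()
                if w_sum <= 0:
                    w = (row < caps).astype(float)
                    w_sum = w.sum()
                lvl = int(rng.choice(nL + 1, p=w / w_sum))
                row[lvl] += 1
                excess -= 1
            counts[j] = row
        base = core * n0
        for j in range(n0):
            row = counts[j]
            offset = (base + j) * fan
            filled = 0
            for lvl in range(nL + 1):
                k = int(row[lvl])
                if k == 0:
                    continue
                if lvl == 0:
                    idx = _sample_distinct(rng, n0 - 1, k)
                    idx = idx + (idx >= j)  # skip self
                    dest = base + idx
                else:
                    u = _sample_distinct(rng, pdf.level_pool[lvl], k)
                    dest = groups[lvl][u // n0] * n0 + (u % n0)
                post[offset + filled : offset + filled + k] = dest
                filled += k

    graph = NeuronGraph(n_neurons=N, pre=pre, post=post)
    assignment = CoreAssignment(core_of=np.repeat(np.arange(K), n0), n_cores=K)
    placement = CorePlacement.identity(spec)
    return graph, assignment, placement


def generate_small_world(n: int, k: int, p: float, seed: int) -> NeuronGraph:
    """Watts-Strogatz ring lattice with per-edge uniform rewiring.

    Each node starts connected to its ``k`` nearest ring neighbours (k even:
    k/2 per side); each edge is rewired with probability ``p`` to a uniformly
    chosen new endpoint, skipping self-loops and duplicates, so the
    undirected edge count stays exactly ``n*k/2``.  Each undirected edge is
    materialized as two directed synapses (routing is direction-aware), so
    per-neuron out-degree averages k.
    """
    if k % 2 != 0:
        raise ValidationError(f"k must be even (k/2 neighbours per side): k={k}")
    if k >= n:
        raise ValidationError(f"k must be < n: k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"rewiring probability must be in [0, 1]: p={p}")
    g = nx.watts_strogatz_graph(n, k, p, seed=int(seed))
    edges = np.asarray(list(g.edges()), dtype=np.int64)
    if edges.size == 0:
        return NeuronGraph(n_neurons=n, pre=np.empty(0, np.int64), post=np.empty(0, np.int64))
    pre = np.concatenate([edges[:, 0], edges[:, 1]])
    post = np.concatenate([edges[:, 1], edges[:, 0]])
    return NeuronGraph(n_neurons=n, pre=pre, post=post)


def generate_feedforward(layer_sizes: list[int]) -> NeuronGraph:
    """Fully-connected feedforward stack: complete bipartite between
    consecutive layers only, no intra-layer or feedback synapses."""
    if len(layer_sizes) < 2:
        raise ValidationError("need at least two layers")
    if any(s < 1 for s in layer_sizes):
        raise ValidationError("all layer sizes must be >= 1")
    offsets = np.concatenate([[0], np.cumsum(layer_sizes)])
    pres, posts = [], []
    for a, b, oa, ob in zip(layer_sizes, layer_sizes[1:], offsets, offsets[1:]):
        pres.append(np.repeat(np.arange(oa, oa + a), b))
        posts.append(np.tile(np.arange(ob, ob + b), a))
    return NeuronGraph(
        n_neurons=int(offsets[-1]),
        pre=np.concatenate(pres),
        post=np.concatenate(posts),
    )


def shuffle_labels(
    graph: NeuronGraph, seed: int
) -> tuple[NeuronGraph, np.ndarray]:
    """Relabel neurons by a uniform random permutation.

    Returns the shuffled graph and the permutation ``perm`` with
    ``perm[old_id] = new_id``, kept for ground-truth bookkeeping.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(graph.n_neurons)
    shuffled = NeuronGraph(
        n_neurons=graph.n_neurons, pre=perm[graph.pre], post=perm[graph.post]
    )
    return shuffled, perm


def generate_from_config(cfg: dict) -> tuple[NeuronGraph, CoreAssignment | None]:
    """Build a network from a generator config mapping (YAML/JSON friendly).

    Keys: ``type`` in {synthetic, small_world, feedforward} plus the
    generator's own parameters.  Returns the graph and, for the synthetic
    generator, its ground-truth assignment (None otherwise).
    """
    kind = cfg.get("type")
    if kind == "synthetic":
        spec = cfg["spec"]
        spec = spec if isinstance(spec, HierarchySpec) else HierarchySpec(tuple(spec))
        sc = SyntheticConfig(
            spec=spec,
            n_per_core=int(cfg.get("n_per_core", 1000)),
            fan_out=int(cfg.get("fan_out", 64)),
            spread=float(cfg.get("lambda", cfg.get("spread", 0.01))),
            seed=int(cfg.get("seed", 0)),
        )
        graph, assignment, _ = generate_synthetic(sc)
        return graph, assignment
    if kind == "small_world":
        return (
            generate_small_world(
                int(cfg["n"]), int(cfg["k"]),
                float(cfg.get("p", 0.1)), int(cfg.get("seed", 0)),
            ),
            None,
        )
    if kind == "feedforward":
        return generate_feedforward([int(s) for s in cfg["layer_sizes"]]), None
    raise ValidationError(f"unknown generator type {kind!r}")
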