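"""Balanced neuron-to-core partitioning and hierarchical core placement.

Two stages, mirroring the compiler flow for a HiAER machine:

1. ``flat_partition`` — split the N-neuron synapse graph into K balanced
   parts (cores) minimizing edge cut, using only the unweighted, undirected,
   deduplicated connectivity.
2. ``hierarchical_placement`` — build the core-to-core traffic matrix
   (``build_core_adjacency``) and recursively partition the K-core weighted
   graph top-down along the hierarchy's branching factors, so that heavily
   communicating cores land in the same subtree.  Higher levels are split
   first because crossing them is assumed most expensive.

The balanced k-way backend is pluggable (``PartitionConfig.backend``).  The
built-in backend is recursive bisection: greedy graph growing for the
initial split, then Fiduccia–Mattheyses-style single-node gain refinement
under the balance band (numba kernels), or Kernighan–Lin pair swaps when the
split must be exactly balanced, as in core placement.  Random baselines
(``random_assignment``, ``random_placement``) match the evaluation protocol:
balanced random neuron assignment, and random core-to-slot placement for the
"flat" baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from numba import njit

from .graph_model import (
    CoreAdjacency,
    CoreAssignment,
    CorePlacement,
    HierarchySpec,
    NeuronGraph,
    ValidationError,
)

__all__ = [
    "PartitionConfig",
    "PartitioningError",
    "flat_partition",
    "build_core_adjacency",
    "hierarchical_placement",
    "random_assignment",
    "random_placement",
    "kway_partition",
]


class PartitioningError(RuntimeError):
    """The backend failed or the balance constraint is infeasible."""


@dataclass(frozen=True)
class PartitionConfig:
    """Partitioning run configuration.

    ``balance_tolerance`` bounds core population at
    ``ceil((N/K)(1+tolerance))``; ``trials`` is the number of re-seeded
    repetitions experiments average over.  ``backend``, when given, replaces
    the built-in k-way partitioner: it is called as
    ``backend(csr_adjacency, k, part_cap, seed)`` and must return integer
    labels in ``[0, k)``.
    """

    spec: HierarchySpec
    balance_tolerance: float = 0.03
    backend_seed: int = 0
    trials: int = 5
    backend: Callable | None = None

    @property
    def n_cores(self) -> int:
        return self.spec.n_cores


# ---------------------------------------------------------------------------
# Built-in balanced k-way backend
# ---------------------------------------------------------------------------


@njit(cache=True)
def _grow(indptr, indices, data, seed_vertex, target, n):
    """Greedy graph growing: absorb the vertex most connected to the set."""
    in_set = np.zeros(n, np.bool_)
    conn = np.zeros(n, np.float64)
    in_set[seed_vertex] = True
    for e in range(indptr[seed_vertex], indptr[seed_vertex + 1]):
        conn[indices[e]] += data[e]
    size = 1
    while size < target:
        best = -1
        best_c = -1.0
        for v in range(n):
            if not in_set[v] and conn[v] > best_c:
                best_c = conn[v]
                best = v
        in_set[best] = True
        size += 1
        for e in range(indptr[best], indptr[best + 1]):
            conn[indices[e]] += data[e]
    return in_set


@njit(cache=True)
def _fm_refine(indptr, indices, data, side, n_left, l_min, l_max, max_passes, min_pass_gain):
    """Positive-gain single-node moves within the balance band [l_min, l_max].

    ``side[v]`` is True when v is in the left part; returns the new left
    size.  Vertices lock for the rest of a pass once moved; passes stop when
    a full pass improves the cut by less than ``min_pass_gain``.
    """
    n = side.size
    gain = np.zeros(n, np.float64)
    for _ in range(max_passes):
        for v in range(n):
            g = 0.0
            sv = side[v]
            for e in range(indptr[v], indptr[v + 1]):
                if side[indices[e]] == sv:
                    g -= data[e]
                else:
                    g += data[e]
            gain[v] = g
        locked = np.zeros(n, np.bool_)
        moved = 0
        pass_gain = 0.0
        while True:
            best = -1
            best_g = 0.0
            for v in range(n):
                if locked[v] or gain[v] <= 0.0:
                    continue
                if side[v]:
                    if n_left - 1 < l_min:
                        continue
                elif n_left + 1 > l_max:
                    continue
                if best == -1 or gain[v] > best_g:
                    best_g = gain[v]
                    best = v
            if best == -1:
                break
            sv = side[best]
            side[best] = not sv
            n_left += -1 if sv else 1
            locked[best] = True
            for e in range(indptr[best], indptr[best + 1]):
                u = indices[e]
                if side[u] == sv:
                    gain[u] += 2.0 * data[e]
                else:
                    gain[u] -= 2.0 * data[e]
            gain[best] = -best_g
            moved += 1
            pass_gain += best_g
        if moved == 0 or pass_gain < min_pass_gain:
            break
    return n_left


@njit(cache=True)
def _cut_weight(indptr, indices, data, side):
    c = 0.0
    for v in range(side.size):
        for e in range(indptr[v], indptr[v + 1]):
            u = indices[e]
            if u > v and side[u] != side[v]:
                c += data[e]
    return c


def _kl_swap_refine(W: np.ndarray, side: np.ndarray, max_rounds: int = 200) -> None:
    """Kernighan–Lin pair swaps for exactly balanced bisections (dense, small n)."""
    for _ in range(max_rounds):
        ext = W @ side - W @ (~side)  # per-vertex: weight to left minus to right
        # gain of moving v to the other part
        gain = np.where(side, -ext, ext) - 0.0
        left = np.flatnonzero(side)
        right = np.flatnonzero(~side)
        if left.size == 0 or right.size == 0:
            return
        pair_gain = gain[left][:, None] + gain[right][None, :] - 2.0 * W[np.ix_(left, right)]
        i, j = np.unravel_index(np.argmax(pair_gain), pair_gain.shape)
        if pair_gain[i, j] <= 1e-12:
            return
        a, b = left[i], right[j]
        side[a] = False
        side[b] = True


def _bisect(
    W: sp.csr_matrix,
    target: int,
    l_min: int,
    l_max: int,
    rng: np.random.Generator,
    max_passes: int = 8,
) -> np.ndarray:
    """Split W's vertices into a left part of size in [l_min, l_max] near
    ``target``, minimizing cut weight.  Returns a boolean left mask."""
    n = W.shape[0]
    indptr = W.indptr.astype(np.int64)
    indices = W.indices.astype(np.int64)
    data = W.data.astype(np.float64)
    exact = l_min == l_max
    n_starts = 3 if n <= 1024 else 1  # multi-start only where it is cheap
    best_side = None
    best_cut = np.inf
    seeds = rng.integers(0, n, size=n_starts)
    # diminishing-returns cutoff: stop refining once a pass gains < 0.05% of the cut
    for s in seeds:
        side = _grow(indptr, indices, data, int(s), int(target), n)
        if exact:
            dense = np.asarray(W.todense(), dtype=np.float64)
            _kl_swap_refine(dense, side)
        else:
            start_cut = _cut_weight(indptr, indices, data, side)
            _fm_refine(
                indptr, indices, data, side, int(side.sum()),
                int(l_min), int(l_max), max_passes, 5e-4 * max(start_cut, 1.0),
            )
        cut = _cut_weight(indptr, indices, data, side)
        if cut < best_cut:
            best_cut = cut
            best_side = side.copy()
    return best_side


def kway_partition(
    W: sp.csr_matrix,
    k: int,
    seed: int = 0,
    part_cap: int | None = None,
    part_floor: int | None = None,
    exact_sizes: bool = False,
) -> np.ndarray:
    """Balanced k-way partition of a symmetric weighted graph by recursive
    bisection; returns integer labels in ``[0, k)``.

    ``part_cap``/``part_floor`` bound every part's size (defaults:
    ceil(n/k) / floor(n/k)); with ``exact_sizes`` every part gets exactly
    n/k vertices (n must divide).
    """
    n = W.shape[0]
    if k < 1 or k > n:
        raise PartitioningError(f"cannot split {n} vertices into {k} parts")
    if exact_sizes and n % k != 0:
        raise PartitioningError(f"{n} vertices do not divide into {k} equal parts")
    cap = part_cap if part_cap is not None else math.ceil(n / k)
    floor = part_floor if part_floor is not None else n // k
    floor = max(1, min(floor, n // k))
    if cap * k < n or floor * k > n:
        raise PartitioningError(
            f"size bounds [{floor}, {cap}] cannot hold {n} vertices in {k} parts"
        )
    W = sp.csr_matrix(W).astype(np.float64)
    if W.diagonal().any():
        coo = W.tocoo()
        keep = coo.row != coo.col
        W = sp.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=W.shape
        )
    W.eliminate_zeros()
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    next_label = [0]

    def recurse(nodes: np.ndarray, k_here: int) -> None:
        if k_here == 1:
            labels[nodes] = next_label[0]
            next_label[0] += 1
            return
        m = nodes.size
        k1 = k_here // 2
        k2 = k_here - k1
        if exact_sizes:
            l_min = l_max = target = m * k1 // k_here
        else:
            # both sides must stay within [floor, cap] per part they contain
            l_max = min(k1 * cap, m - k2 * floor)
            l_min = max(k1 * floor, m - k2 * cap)
            if l_min > l_max:
                raise PartitioningError("balance constraint infeasible")
            target = min(max(round(m * k1 / k_here), l_min), l_max)
        sub = W[nodes][:, nodes].tocsr()
        side = _bisect(sub, target, l_min, l_max, rng)
        recurse(nodes[side], k1)
        recurse(nodes[~side], k2)

    recurse(np.arange(n), k)
    return labels


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def flat_partition(graph: NeuronGraph, cfg: PartitionConfig) -> CoreAssignment:
    """Balanced K-way partition of the neuron graph onto cores.

    The backend sees only the symmetrized, deduplicated, unweighted
    connectivity; duplicate directed synapses never become weights.
    Deterministic for a fixed ``backend_seed``.
    """
    K = cfg.n_cores
    N = graph.n_neurons
    if K > N:
        raise PartitioningError(f"K={K} exceeds N={N}")
    cap = math.ceil(N / K * (1.0 + cfg.balance_tolerance))
    if K == 1:
        assignment = CoreAssignment(core_of=np.zeros(N, dtype=np.int64), n_cores=1)
    else:
        W = graph.undirected_csr()
        if cfg.backend is not None:
            labels = np.asarray(cfg.backend(W, K, cap, cfg.backend_seed))
        else:
            labels = kway_partition(W, K, seed=cfg.backend_seed, part_cap=cap)
        assignment = CoreAssignment(core_of=labels, n_cores=K)
    assignment.check_balance(cfg.balance_tolerance)
    return assignment


def build_core_adjacency(
    graph: NeuronGraph, assignment: CoreAssignment
) -> CoreAdjacency:
    """Core-to-core connection counts in address-event terms.

    ``A[i, j]`` counts neurons in core i with >= 1 postsynaptic neuron in
    core j != i — each (neuron, destination core) pair once, regardless of
    synapse multiplicity, because one routed connection serves any fan-out
    within the destination core.  ``B = A + A^T`` symmetrizes into the total
    communication cost used as placement edge weights.
    """
    if assignment.n_neurons != graph.n_neurons:
        raise ValidationError("assignment does not cover the graph")
    K = assignment.n_cores
    dest_core = assignment.core_of[graph.post]
    pairs = np.unique(graph.pre * np.int64(K) + dest_core)
    src_core = assignment.core_of[pairs // K]
    dst = pairs % K
    remote = src_core != dst
    A = np.zeros((K, K), dtype=np.int64)
    np.add.at(A, (src_core[remote], dst[remote]), 1)
    return CoreAdjacency(A=A)


def hierarchical_placement(
    adjacency: CoreAdjacency, cfg: PartitionConfig
) -> CorePlacement:
    """Recursive top-down placement of cores into the hierarchy tree.

    Partition the K-core graph (edge weights B) into ``b_top`` equal groups;
    restrict B to each group (dropping connections to other groups) and
    recurse with the remaining branching factors.  The nested memberships
    define each core's address; within a bottom-level group cores take slots
    in ascending core-id order.
    """
    spec = cfg.spec
    K = adjacency.n_cores
    if K != spec.n_cores:
        raise ValidationError(f"adjacency has {K} cores but spec {spec} needs {spec.n_cores}")
    running = 1
    for b in spec.branching:
        running *= b
        if K % running != 0:
            raise ValidationError(
                f"K={K} not divisible by branching prefix product {running} of {spec}"
            )
    B = sp.csr_matrix(adjacency.B.astype(np.float64))
    rng = np.random.default_rng(cfg.backend_seed)
    slot_of = np.empty(K, dtype=np.int64)

    def place(cores: np.ndarray, branching: tuple[int, ...], base: int) -> None:
        if len(branching) == 1 or cores.size == 1:
            for i, c in enumerate(np.sort(cores)):
                slot_of[c] = base + i
            return
        b = branching[0]
        rest = math.prod(branching[1:])
        sub = B[cores][:, cores].tocsr()
        labels = kway_partition(
            sub, b, seed=int(rng.integers(0, 2**31 - 1)), exact_sizes=True
        )
        for g in range(b):
            place(cores[labels == g], branching[1:], base + g * rest)

    place(np.arange(K), spec.branching, 0)
    return CorePlacement(spec, slot_of)


def random_assignment(n_neurons: int, K: int, seed: int) -> CoreAssignment:
    """Balanced random baseline: a uniform permutation chopped into K
    contiguous blocks of size floor(N/K) or ceil(N/K)."""
    if K > n_neurons:
        raise PartitioningError(f"K={K} exceeds N={n_neurons}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_neurons)
    base, extra = divmod(n_neurons, K)
    sizes = np.full(K, base, dtype=np.int64)
    sizes[:extra] += 1
    core_of = np.empty(n_neurons, dtype=np.int64)
    core_of[perm] = np.repeat(np.arange(K), sizes)
    return CoreAssignment(core_of=core_of, n_cores=K)


def random_placement(K: int, spec: HierarchySpec, seed: int) -> CorePlacement:
    """Uniform random core-to-slot bijection (the "flat" baseline placement)."""
    if spec.n_cores != K:
        raise ValidationError(f"spec {spec} does not have {K} cores")
    rng = np.random.default_rng(seed)
    return CorePlacement(spec, rng.permutation(K))
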