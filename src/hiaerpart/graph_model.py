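"""Domain types, graph I/O and hierarchy-address arithmetic.

The objects here are shared by every other module: a directed synapse graph
(:class:`NeuronGraph`), the tree of cores it is mapped onto
(:class:`HierarchySpec`), the two halves of a mapping — neurons to cores
(:class:`CoreAssignment`) and cores to tree slots (:class:`CorePlacement`) —
and the per-level traffic tallies produced by the router
(:class:`LevelTraffic`).

Conventions
-----------
* Neuron ids and core ids are 0-based everywhere.
* A core address is a plain tuple of integers, one component per hierarchy
  level, top level first.  Addresses are bijective with core ids under
  mixed-radix encoding (top component most significant).
* Hierarchy levels are numbered from the bottom: level 0 is intra-core
  (never routed, never counted), level ``n_levels`` is the topmost boundary.
* Self-loop synapses are dropped at ingest: they cost no routing and the
  partition objective ignores them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("hiaerpart")

__all__ = [
    "ValidationError",
    "GraphFormatError",
    "NeuronGraph",
    "HierarchySpec",
    "CoreAssignment",
    "CorePlacement",
    "CoreAdjacency",
    "LevelTraffic",
    "core_id_to_address",
    "address_to_core_id",
    "divergence_level",
    "load_edge_list",
    "save_edge_list",
    "load_adjacency_matrix",
    "save_adjacency_matrix",
    "load_partition",
    "save_partition",
    "load_placement",
    "save_placement",
]


class ValidationError(ValueError):
    """An input violates a structural precondition (range, arity, balance)."""


class GraphFormatError(ValueError):
    """A graph file could not be parsed; the message names the line."""


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronGraph:
    """A directed synapse graph over ``n_neurons`` neurons.

    Synapses are stored as parallel integer arrays ``pre`` / ``post``.
    Duplicate directed pairs are legal and retained (multiplicity may carry
    information for partitioning); they collapse to a single entry in
    destination-core sets during routing, because address-event routing needs
    only one connection per (neuron, destination core).  The graph is purely
    topological: no weights, delays or neuron state.
    """

    n_neurons: int
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=np.int64)
        post = np.asarray(self.post, dtype=np.int64)
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValidationError("pre/post must be 1-D arrays of equal length")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        if self.n_neurons < 0:
            raise ValidationError("n_neurons must be nonnegative")
        if pre.size:
            lo = min(pre.min(), post.min())
            hi = max(pre.max(), post.max())
            if lo < 0 or hi >= self.n_neurons:
                raise ValidationError(
                    f"neuron ids must lie in [0, {self.n_neurons}); found [{lo}, {hi}]"
                )
            if np.any(pre == post):
                raise ValidationError("self-loop synapses are not permitted")

    @property
    def n_synapses(self) -> int:
        return int(self.pre.size)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n_neurons)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.n_neurons)

    def to_coo(self) -> sp.coo_matrix:
        """Sparse adjacency with duplicate synapses summed as multiplicity."""
        data = np.ones(self.n_synapses, dtype=np.int64)
        return sp.coo_matrix(
            (data, (self.pre, self.post)), shape=(self.n_neurons, self.n_neurons)
        )

    def undirected_csr(self) -> sp.csr_matrix:
        """Symmetrized, deduplicated, unweighted adjacency (the partitioner's view)."""
        a = self.to_coo().tocsr()
        sym = a + a.T
        sym.data[:] = 1
        return sym


@dataclass(frozen=True)
class HierarchySpec:
    """Ordered branching factors of the HiAER tree, top level first.

    ``AxBxC`` notation maps to ``branching = (A, B, C)``: the K = A*B*C cores
    are first grouped into A top-level groups, each split into B clusters of
    C cores.  A core address has one component per level, top first.
    """

    branching: tuple[int, ...]

    def __post_init__(self) -> None:
        branching = tuple(int(b) for b in self.branching)
        object.__setattr__(self, "branching", branching)
        if not branching or any(b < 1 for b in branching):
            raise ValidationError(f"branching factors must all be >= 1: {branching}")

    @classmethod
    def parse(cls, text: str) -> "HierarchySpec":
        """Parse ``"2x4x8"`` (also accepts ``,`` or whitespace separators)."""
        parts = text.replace("x", " ").replace("X", " ").replace(",", " ").split()
        if not parts:
            raise ValidationError(f"cannot parse hierarchy spec {text!r}")
        return cls(tuple(int(p) for p in parts))

    @property
    def n_cores(self) -> int:
        return math.prod(self.branching)

    @property
    def n_levels(self) -> int:
        return len(self.branching)

    def addresses(self) -> list[tuple[int, ...]]:
        return [core_id_to_address(c, self) for c in range(self.n_cores)]

    def __str__(self) -> str:
        return "x".join(str(b) for b in self.branching)


def core_id_to_address(core: int, spec: HierarchySpec) -> tuple[int, ...]:
    """Mixed-radix encoding of a core id, top component most significant."""
    if not 0 <= core < spec.n_cores:
        raise ValidationError(f"core {core} out of range [0, {spec.n_cores})")
    comps = []
    rem = int(core)
    for b in reversed(spec.branching):
        comps.append(rem % b)
        rem //= b
    return tuple(reversed(comps))


def address_to_core_id(address: tuple[int, ...], spec: HierarchySpec) -> int:
    """Inverse of :func:`core_id_to_address`."""
    if len(address) != spec.n_levels:
        raise ValidationError(
            f"address arity {len(address)} != {spec.n_levels} levels of {spec}"
        )
    core = 0
    for comp, b in zip(address, spec.branching):
        if not 0 <= comp < b:
            raise ValidationError(f"address component {comp} out of range [0, {b})")
        core = core * b + comp
    return core


def divergence_level(
    a: tuple[int, ...], b: tuple[int, ...], spec: HierarchySpec
) -> int:
    """Hierarchy level a message between cores ``a`` and ``b`` must cross.

    Returns 0 when the addresses are equal (intra-core, free).  Otherwise the
    level is counted from the bottom: cores in the same innermost cluster
    diverge at level 1; cores differing in the top component of an n-level
    spec diverge at level n.
    """
    if len(a) != spec.n_levels or len(b) != spec.n_levels:
        raise ValidationError("address arity does not match hierarchy spec")
    for i in range(spec.n_levels):
        if a[i] != b[i]:
            return spec.n_levels - i
    return 0


@dataclass(frozen=True)
class CoreAssignment:
    """Map neuron id -> core id (the "flat" half of a mapping)."""

    core_of: np.ndarray
    n_cores: int

    def __post_init__(self) -> None:
        core_of = np.asarray(self.core_of, dtype=np.int64)
        object.__setattr__(self, "core_of", core_of)
        if core_of.ndim != 1:
            raise ValidationError("core_of must be 1-D")
        if core_of.size and (core_of.min() < 0 or core_of.max() >= self.n_cores):
            raise ValidationError("core ids out of range")

    @property
    def n_neurons(self) -> int:
        return int(self.core_of.size)

    def core_sizes(self) -> np.ndarray:
        return np.bincount(self.core_of, minlength=self.n_cores)

    def check_balance(self, tolerance: float = 0.03) -> None:
        """Assert max core population <= ceil((N/K)(1+tolerance))."""
        cap = math.ceil(self.n_neurons / self.n_cores * (1.0 + tolerance))
        biggest = int(self.core_sizes().max())
        if biggest > cap:
            raise ValidationError(
                f"assignment unbalanced: largest core holds {biggest} neurons, "
                f"cap is {cap} (N={self.n_neurons}, K={self.n_cores}, "
                f"tolerance={tolerance})"
            )


@dataclass(frozen=True)
class CorePlacement:
    """Bijection core id -> tree address for a given hierarchy spec.

    Stored as ``slot_of[core]`` = the mixed-radix slot index whose address the
    core occupies, so the address of core ``c`` is
    ``core_id_to_address(slot_of[c], spec)``.
    """

    spec: HierarchySpec
    slot_of: np.ndarray

    def __post_init__(self) -> None:
        slot_of = np.asarray(self.slot_of, dtype=np.int64)
        object.__setattr__(self, "slot_of", slot_of)
        k = self.spec.n_cores
        if slot_of.shape != (k,):
            raise ValidationError(f"slot_of must have shape ({k},)")
        if sorted(slot_of.tolist()) != list(range(k)):
            raise ValidationError("placement must be a bijection over all cores")

    @classmethod
    def identity(cls, spec: HierarchySpec) -> "CorePlacement":
        return cls(spec, np.arange(spec.n_cores))

    def address_of(self, core: int) -> tuple[int, ...]:
        return core_id_to_address(int(self.slot_of[core]), self.spec)

    def address_components(self) -> np.ndarray:
        """(K, n_levels) integer array of each core's address, top first."""
        out = np.empty((self.spec.n_cores, self.spec.n_levels), dtype=np.int64)
        for c in range(self.spec.n_cores):
            out[c] = self.address_of(c)
        return out


@dataclass(frozen=True)
class CoreAdjacency:
    """Directed (A) and symmetrized (B = A + A^T) core-to-core connection counts.

    ``A[i, j]`` is the number of neurons resident in core i that have at least
    one postsynaptic target in core j (each neuron counted once per
    destination core, regardless of synapse multiplicity).  The diagonal is
    zero: intra-core connectivity never routes.
    """

    A: np.ndarray
    B: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.int64)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("A must be square")
        if np.any(np.diag(A) != 0):
            raise ValidationError("A must have a zero diagonal")
        if np.any(A < 0):
            raise ValidationError("A must be nonnegative")
        B = self.B if self.B is not None else A + A.T
        B = np.asarray(B, dtype=np.int64)
        if not np.array_equal(B, A + A.T):
            raise ValidationError("B must equal A + A^T exactly")
        object.__setattr__(self, "B", B)

    @property
    def n_cores(self) -> int:
        return int(self.A.shape[0])


@dataclass
class LevelTraffic:
    """Per-level message and relay-connection counts for one routing mode.

    ``messages[l]`` counts every message crossing a level-l boundary;
    ``relays[l]`` counts the subset that are relay connections — messages
    emitted by a core other than the original source, or whose recipient must
    forward the event further.  Level 0 (intra-core) is free and never
    appears.
    """

    mode: str
    n_levels: int
    messages: dict[int, int] = field(default_factory=dict)
    relays: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("multicast", "unicast"):
            raise ValidationError(f"unknown routing mode {self.mode!r}")
        for lvl in range(1, self.n_levels + 1):
            self.messages.setdefault(lvl, 0)
            self.relays.setdefault(lvl, 0)
        for lvl in range(1, self.n_levels + 1):
            if self.relays[lvl] > self.messages[lvl] or self.messages[lvl] < 0:
                raise ValidationError("relay count exceeds message count")

    def add(self, other: "LevelTraffic") -> "LevelTraffic":
        if other.mode != self.mode or other.n_levels != self.n_levels:
            raise ValidationError("traffic tallies have mismatched mode/levels")
        for lvl in range(1, self.n_levels + 1):
            self.messages[lvl] += other.messages[lvl]
            self.relays[lvl] += other.relays[lvl]
        return self

    @property
    def total_messages(self) -> int:
        return sum(self.messages.values())

    @property
    def total_relays(self) -> int:
        return sum(self.relays.values())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "per_level": {
                str(lvl): {
                    "messages": int(self.messages[lvl]),
                    "relays": int(self.relays[lvl]),
                }
                for lvl in range(1, self.n_levels + 1)
            },
            "totals": {
                "messages": int(self.total_messages),
                "relays": int(self.total_relays),
            },
        }


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

_HEADER_KEY = "n_neurons"


def load_edge_list(
    path: str | Path, delimiter: str | None = None
) -> NeuronGraph:
    """Read a directed synapse graph from a two-column edge-list file.

    Format: one ``pre<delim>post`` pair of integer neuron ids per line;
    ``#`` starts a comment; an optional header line ``n_neurons=<int>``
    (bare or inside a comment) declares the neuron count, which otherwise
    defaults to ``1 + max id``.  Self-loops are dropped with a logged count;
    duplicate directed pairs are retained as multiplicity.
    """
    path = Path(path)
    delimiter = delimiter or ("\t" if path.suffix in (".tsv", ".tab") else ",")
    declared_n: int | None = None
    pres: list[int] = []
    posts: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[-1] if raw.lstrip().startswith("#") else raw
            line = line.strip()
            if not line:
                continue
            if _HEADER_KEY in line and "=" in line:
                try:
                    declared_n = int(line.split("=", 1)[1].strip())
                    continue
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: malformed header {line!r}"
                    ) from exc
            if raw.lstrip().startswith("#"):
                continue
            parts = [p for p in line.replace(delimiter, " ").split() if p]
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two integer ids, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two integer ids, got {line!r}"
                ) from exc
            if u < 0 or v < 0:
                raise ValidationError(f"{path}:{lineno}: negative neuron id")
            pres.append(u)
            posts.append(v)
    pre = np.asarray(pres, dtype=np.int64)
    post = np.asarray(posts, dtype=np.int64)
    keep = pre != post
    n_dropped = int(np.size(keep) - np.count_nonzero(keep))
    if n_dropped:
        logger.info("dropped %d self-loop synapse(s) while loading %s", n_dropped, path)
        pre, post = pre[keep], post[keep]
    n = declared_n if declared_n is not None else (int(max(pre.max(initial=-1), post.max(initial=-1))) + 1 if pre.size else 0)
    return NeuronGraph(n_neurons=n, pre=pre, post=post)


def save_edge_list(
    graph: NeuronGraph, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    delimiter = delimiter or ("\t" if path.suffix in (".tsv", ".tab") else ",")
    with open(path, "w") as fh:
        fh.write(f"# {_HEADER_KEY}={graph.n_neurons}\n")
        df = pd.DataFrame({"pre": graph.pre, "post": graph.post})
        df.to_csv(fh, sep=delimiter, header=False, index=False)


def load_adjacency_matrix(path: str | Path) -> NeuronGraph:
    """Read a synapse graph from MatrixMarket coordinate format.

    Integer entries are synapse multiplicities; diagonal entries (self-loops)
    are dropped with a logged count.
    """
    mat = sp.coo_matrix(mmread(str(path)))
    if mat.shape[0] != mat.shape[1]:
        raise GraphFormatError(f"{path}: adjacency matrix must be square")
    counts = np.rint(mat.data).astype(np.int64)
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative synapse multiplicity")
    keep = (mat.row != mat.col) & (counts > 0)
    dropped = int(counts[mat.row == mat.col].sum())
    if dropped:
        logger.info("dropped %d self-loop synapse(s) while loading %s", dropped, path)
    pre = np.repeat(mat.row[keep], counts[keep])
    post = np.repeat(mat.col[keep], counts[keep])
    return NeuronGraph(n_neurons=int(mat.shape[0]), pre=pre, post=post)


def save_adjacency_matrix(graph: NeuronGraph, path: str | Path) -> None:
    mmwrite(str(path), graph.to_coo())


def load_partition(path: str | Path, n_cores: int | None = None) -> CoreAssignment:
    """Read a ``neuron_id,core_id`` CSV into a CoreAssignment."""
    df = pd.read_csv(path, comment="#")
    df = df.sort_values(df.columns[0])
    neuron = df.iloc[:, 0].to_numpy(dtype=np.int64)
    core = df.iloc[:, 1].to_numpy(dtype=np.int64)
    if not np.array_equal(neuron, np.arange(len(neuron))):
        raise GraphFormatError(f"{path}: neuron ids must cover 0..N-1 exactly")
    k = n_cores if n_cores is not None else int(core.max()) + 1
    return CoreAssignment(core_of=core, n_cores=k)


def save_partition(assignment: CoreAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"neuron_id": np.arange(assignment.n_neurons), "core_id": assignment.core_of}
    ).to_csv(path, index=False)


def load_placement(path: str | Path, spec: HierarchySpec) -> CorePlacement:
    """Read a ``core_id,addr_top,...,addr_1`` CSV into a CorePlacement."""
    df = pd.read_csv(path, comment="#").sort_values("core_id")
    if df.shape[1] != 1 + spec.n_levels:
        raise GraphFormatError(
            f"{path}: expected {1 + spec.n_levels} columns for spec {spec}"
        )
    slots = [
        address_to_core_id(tuple(int(x) for x in row[1:]), spec)
        for row in df.itertuples(index=False)
    ]
    return CorePlacement(spec, np.asarray(slots, dtype=np.int64))


def save_placement(placement: CorePlacement, path: str | Path) -> None:
    spec = placement.spec
    comps = placement.address_components()
    cols = {"core_id": np.arange(spec.n_cores)}
    for i in range(spec.n_levels):
        cols[f"addr_l{spec.n_levels - i}"] = comps[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
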