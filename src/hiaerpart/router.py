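"""HiAER routing-cost model: per-level message and relay counting.

Address-event routing sends one connection per (source neuron, destination
core) — fan-out *within* a destination core is free, so the router's unit of
work is the neuron's set of remote destination cores.  Two delivery schemes
are modelled over the core tree:

* **multicast** — at each tree level the carrier emits at most one message
  whose destination field is a mask of sibling subtrees; in every masked
  subtree it lands on the core sharing the carrier's relative address, which
  re-emits locally if more cores in that subtree must be reached.
* **unicast** — every message addresses exactly one core; crossing a
  hierarchy boundary takes one message per destination subtree, sent to the
  lowest-addressed destination core there, which then forwards to the rest.

A *relay connection* is any message that is part of the forwarding cascade:
either emitted by a core other than the original source, or received by a
core that must forward it further.  Terminal direct messages from the source
are not relays.  Counts assume each neuron fires once (static per-spike
connection counts); level 0 (intra-core) never appears.

``simulate_delivery`` is an independent carrier-queue formulation of the
same semantics, used to cross-check the recursive counters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_model import (
    CoreAssignment,
    CorePlacement,
    HierarchySpec,
    LevelTraffic,
    NeuronGraph,
    ValidationError,
    divergence_level,
)

__all__ = [
    "DestinationProfile",
    "destination_profile",
    "route_multicast",
    "route_unicast",
    "simulate_delivery",
    "count_traffic",
    "reduction_report",
]

Address = tuple[int, ...]


@dataclass(frozen=True)
class DestinationProfile:
    """Per-neuron deduplicated remote destination-core sets.

    ``dest_cores`` maps neuron id -> sorted array of destination core ids
    (own core excluded); neurons whose targets are all intra-core are absent.
    """

    n_cores: int
    dest_cores: dict[int, np.ndarray]


def destination_profile(
    graph: NeuronGraph, assignment: CoreAssignment, placement: CorePlacement
) -> DestinationProfile:
    """Deduplicate each neuron's postsynaptic targets into core sets."""
    if assignment.n_neurons != graph.n_neurons:
        raise ValidationError("assignment does not cover the graph")
    if placement.spec.n_cores != assignment.n_cores:
        raise ValidationError("placement hierarchy does not match assignment core count")
    K = np.int64(assignment.n_cores)
    dest_core = assignment.core_of[graph.post]
    pairs = np.unique(graph.pre * K + dest_core)
    neuron = pairs // K
    core = pairs % K
    remote = assignment.core_of[neuron] != core
    neuron, core = neuron[remote], core[remote]
    out: dict[int, np.ndarray] = {}
    if neuron.size:
        bounds = np.flatnonzero(np.diff(neuron)) + 1
        for ids, cs in zip(
            np.split(neuron, bounds), np.split(core, bounds)
        ):
            out[int(ids[0])] = cs
    return DestinationProfile(n_cores=int(K), dest_cores=out)


def _check_route_args(
    source: Address, dests, spec: HierarchySpec
) -> list[Address]:
    dests = [tuple(d) for d in dests]
    for d in dests + [tuple(source)]:
        if len(d) != spec.n_levels:
            raise ValidationError(f"address {d} has wrong arity for spec {spec}")
    if tuple(source) in dests:
        raise ValidationError("source must not be among the destinations")
    return dests


def route_multicast(
    source: Address, dests, spec: HierarchySpec
) -> LevelTraffic:
    """Count mask-routed messages from one neuron to its destination cores."""
    dests = _check_route_args(source, dests, spec)
    traffic = LevelTraffic("multicast", spec.n_levels)
    n_levels = spec.n_levels

    def go(anchor: Address, dset: list[Address], level: int, from_source: bool) -> None:
        if not dset:
            return
        i = n_levels - level
        groups: dict[int, list[Address]] = {}
        for d in dset:
            groups.setdefault(d[i], []).append(d)
        a = anchor[i]
        others = [g for g in groups if g != a]
        if others:
            traffic.messages[level] += 1
            triggered = False
            for g in others:
                landing = anchor[:i] + (g,) + anchor[i + 1:]
                rest = [d for d in groups[g] if d != landing]
                if rest:
                    triggered = True
                    go(landing, rest, level - 1, False)
            if triggered or not from_source:
                traffic.relays[level] += 1
        if a in groups:
            go(anchor, groups[a], level - 1, from_source)

    go(tuple(source), dests, n_levels, True)
    return traffic


def route_unicast(
    source: Address, dests, spec: HierarchySpec
) -> LevelTraffic:
    """Count single-destination messages from one neuron to its cores."""
    dests = _check_route_args(source, dests, spec)
    traffic = LevelTraffic("unicast", spec.n_levels)
    n_levels = spec.n_levels

    def go(anchor: Address, dset: list[Address], level: int, from_source: bool) -> None:
        if not dset:
            return
        i = n_levels - level
        groups: dict[int, list[Address]] = {}
        for d in dset:
            groups.setdefault(d[i], []).append(d)
        a = anchor[i]
        for g in sorted(groups):
            if g == a:
                continue
            sub = groups[g]
            target = min(sub)  # deterministic relay choice: lowest address
            traffic.messages[level] += 1
            rest = [d for d in sub if d != target]
            if rest or not from_source:
                traffic.relays[level] += 1
            if rest:
                go(target, rest, level - 1, False)
        if a in groups:
            go(anchor, groups[a], level - 1, from_source)

    go(tuple(source), dests, n_levels, True)
    return traffic


def simulate_delivery(
    source: Address, dests, spec: HierarchySpec, mode: str
) -> LevelTraffic:
    """Explicit carrier-queue delivery simulation (cross-check oracle).

    Materializes every message as an event: a carrier holding a pending set
    of destination cores groups them by divergence level, emits the messages
    that scheme's rules demand, and enqueues each recipient that still has
    cores left to cover.  No tree recursion: forwarding responsibility is
    recomputed from scratch at each carrier via ``divergence_level``.
    """
    if mode not in ("multicast", "unicast"):
        raise ValidationError(f"unknown routing mode {mode!r}")
    dests = _check_route_args(source, dests, spec)
    n_levels = spec.n_levels
    traffic = LevelTraffic(mode, n_levels)
    queue: list[tuple[Address, frozenset, bool]] = [
        (tuple(source), frozenset(dests), True)
    ]
    while queue:
        carrier, pending, is_source = queue.pop()
        by_level: dict[int, set[Address]] = {}
        for d in pending:
            by_level.setdefault(divergence_level(carrier, d, spec), set()).add(d)
        for lvl, ds in by_level.items():
            i = n_levels - lvl
            if mode == "multicast":
                landings: dict[Address, set[Address]] = {}
                for d in ds:
                    landing = carrier[:i] + (d[i],) + carrier[i + 1:]
                    landings.setdefault(landing, set()).add(d)
                forwards = False
                for landing, covered in landings.items():
                    leftover = covered - {landing}
                    if leftover:
                        forwards = True
                        queue.append((landing, frozenset(leftover), False))
                traffic.messages[lvl] += 1
                if forwards or not is_source:
                    traffic.relays[lvl] += 1
            else:
                by_subtree: dict[int, set[Address]] = {}
                for d in ds:
                    by_subtree.setdefault(d[i], set()).add(d)
                for covered in by_subtree.values():
                    target = min(covered)
                    leftover = covered - {target}
                    if leftover:
                        queue.append((target, frozenset(leftover), False))
                    traffic.messages[lvl] += 1
                    if leftover or not is_source:
                        traffic.relays[lvl] += 1
    return traffic


def count_traffic(
    graph: NeuronGraph,
    assignment: CoreAssignment,
    placement: CorePlacement,
    mode: str,
) -> LevelTraffic:
    """Network-wide per-level traffic, each neuron firing once.

    Sums the per-neuron routing of every neuron's destination profile;
    deterministic given its inputs.
    """
    if mode not in ("multicast", "unicast"):
        raise ValidationError(f"unknown routing mode {mode!r}")
    spec = placement.spec
    route = route_multicast if mode == "multicast" else route_unicast
    profile = destination_profile(graph, assignment, placement)
    comps = placement.address_components()
    addresses = [tuple(int(x) for x in row) for row in comps]
    total = LevelTraffic(mode, spec.n_levels)
    for neuron, cores in profile.dest_cores.items():
        src = addresses[assignment.core_of[neuron]]
        total.add(route(src, [addresses[c] for c in cores], spec))
    return total


def reduction_report(
    method: LevelTraffic, baseline: LevelTraffic
) -> dict[int, float | None]:
    """Per-level percent message reduction of ``method`` versus ``baseline``.

    ``100 * (baseline - method) / baseline``; 0% when both are zero;
    negative when the method is worse; ``None`` (undefined, flagged) when
    the baseline is zero but the method is not.
    """
    if method.mode != baseline.mode or method.n_levels != baseline.n_levels:
        raise ValidationError("traffic tallies have mismatched mode/levels")
    out: dict[int, float | None] = {}
    for lvl in range(1, method.n_levels + 1):
        b = baseline.messages[lvl]
        m = method.messages[lvl]
        if b == 0:
            out[lvl] = 0.0 if m == 0 else None
        else:
            out[lvl] = 100.0 * (b - m) / b
    return out
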