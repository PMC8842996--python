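"""Experiment harness: generate -> shuffle -> partition -> place -> evaluate.

Reproduces the evaluation protocol: a network is generated (or loaded), its
neuron labels are shuffled so the partitioner cannot see generative block
structure, and three mapping methods are compared under multicast and
unicast routing:

* ``hierarchical`` — balanced flat partition + recursive hierarchical core
  placement (the method under study);
* ``flat`` — the same flat partition with cores placed at random tree slots
  (optimal for a single-level router, baseline for deeper trees);
* ``random`` — balanced random neuron assignment with identity placement
  (placement is distributionally irrelevant under random assignment).

Results are the mean over ``trials`` re-seeded repetitions (default 5) on
the same graph; every stochastic stage (label shuffle, partitioner seed,
random baselines) is re-seeded per trial from (base seed, trial index).
Reports store absolute per-level message/relay counts alongside percent
reductions so alternative baselines can be recomputed offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .generators import generate_from_config
from .graph_model import (
    CoreAssignment,
    CorePlacement,
    HierarchySpec,
    NeuronGraph,
    ValidationError,
    load_edge_list,
)
from .partitioner import (
    PartitionConfig,
    build_core_adjacency,
    flat_partition,
    hierarchical_placement,
    random_assignment,
    random_placement,
)
from .router import count_traffic, reduction_report

__all__ = ["ExperimentConfig", "run_experiment", "summarize", "summary_table", "PRESETS"]

_MODES = ("multicast", "unicast")
_METHODS = ("hierarchical", "flat", "random")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a network source, a hierarchy, and what to compare.

    ``network`` is a generator config mapping (``{"type": "synthetic", ...}``),
    a path to an edge-list file, or an in-memory :class:`NeuronGraph`.
    """

    spec: HierarchySpec
    network: dict | str | Path | NeuronGraph
    trials: int = 5
    seed: int = 0
    modes: tuple[str, ...] = _MODES
    methods: tuple[str, ...] = _METHODS
    balance_tolerance: float = 0.03
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValidationError("trials must be >= 1")
        if not self.modes or any(m not in _MODES for m in self.modes):
            raise ValidationError(f"modes must be a nonempty subset of {_MODES}")
        if not self.methods or any(m not in _METHODS for m in self.methods):
            raise ValidationError(f"methods must be a nonempty subset of {_METHODS}")


# named desk-scale and full-scale generator presets
PRESETS: dict[str, dict] = {
    "smoke": {
        "type": "synthetic", "spec": [2, 2], "n_per_core": 50,
        "fan_out": 10, "lambda": 0.05,
    },
    "desk_synthetic": {
        "type": "synthetic", "spec": [4, 8], "n_per_core": 200,
        "fan_out": 64, "lambda": 0.01,
    },
    "desk_small_world": {"type": "small_world", "n": 2000, "k": 10, "p": 0.1},
    # full-scale configurations (long-running)
    "full_4x8": {
        "type": "synthetic", "spec": [4, 8], "n_per_core": 1000,
        "fan_out": 256, "lambda": 0.01,
    },
    "full_2x4x8": {
        "type": "synthetic", "spec": [2, 4, 8], "n_per_core": 1000,
        "fan_out": 256, "lambda": 0.01,
    },
}


def _trial_seeds(base_seed: int, trial: int) -> dict[str, int]:
    words = np.random.SeedSequence([int(base_seed), int(trial)]).generate_state(4)
    names = ("shuffle", "backend", "flat_placement", "random_assignment")
    return {k: int(w % (2**31 - 1)) for k, w in zip(names, words)}


def _resolve_network(cfg: ExperimentConfig) -> NeuronGraph:
    net = cfg.network
    if isinstance(net, NeuronGraph):
        return net
    if isinstance(net, dict):
        net = dict(net)
        net.setdefault("spec", list(cfg.spec.branching))
        net.setdefault("seed", cfg.seed)
        graph, _ = generate_from_config(net)
        return graph
    return load_edge_list(net)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run all trials and return the full report (JSON-serializable).

    Per trial the flat partition is computed once and shared by the
    ``hierarchical`` and ``flat`` methods (they differ only in placement).
    When ``cfg.out_dir`` is set, ``report.json`` and ``summary.csv`` are
    written there; trial records are flushed as they complete.
    """
    from .generators import shuffle_labels

    spec = cfg.spec
    K = spec.n_cores
    graph = _resolve_network(cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": {
            "spec": list(spec.branching),
            "network": cfg.network if isinstance(cfg.network, dict) else str(
                getattr(cfg.network, "n_neurons", cfg.network)
            ),
            "n_neurons": graph.n_neurons,
            "n_synapses": graph.n_synapses,
            "trials": cfg.trials,
            "seed": cfg.seed,
            "modes": list(cfg.modes),
            "methods": list(cfg.methods),
            "balance_tolerance": cfg.balance_tolerance,
            "versions": _library_versions(),
        },
        "trials": [],
    }

    for t in range(cfg.trials):
        seeds = _trial_seeds(cfg.seed, t)
        shuffled, _perm = shuffle_labels(graph, seeds["shuffle"])
        pcfg = PartitionConfig(
            spec=spec,
            balance_tolerance=cfg.balance_tolerance,
            backend_seed=seeds["backend"],
            trials=cfg.trials,
        )
        mappings: dict[str, tuple[CoreAssignment, CorePlacement]] = {}
        need_flat = {"hierarchical", "flat"} & set(cfg.methods)
        if need_flat:
            assignment = flat_partition(shuffled, pcfg)
            assignment.check_balance(cfg.balance_tolerance)
            if "hierarchical" in cfg.methods:
                adjacency = build_core_adjacency(shuffled, assignment)
                mappings["hierarchical"] = (
                    assignment, hierarchical_placement(adjacency, pcfg)
                )
            if "flat" in cfg.methods:
                mappings["flat"] = (
                    assignment, random_placement(K, spec, seeds["flat_placement"])
                )
        if "random" in cfg.methods:
            rnd = random_assignment(graph.n_neurons, K, seeds["random_assignment"])
            rnd.check_balance(cfg.balance_tolerance)
            mappings["random"] = (rnd, CorePlacement.identity(spec))

        record: dict = {"trial": t, "seeds": seeds, "methods": {}, "reductions": {}}
        traffic = {
            method: {
                mode: count_traffic(shuffled, asg, plc, mode) for mode in cfg.modes
            }
            for method, (asg, plc) in mappings.items()
        }
        for method in mappings:
            record["methods"][method] = {
                mode: traffic[method][mode].to_dict() for mode in cfg.modes
            }
        for mode in cfg.modes:
            record["reductions"][mode] = {}
            for method in mappings:
                entry = {}
                for base_name in ("random", "flat"):
                    if base_name in traffic:
                        entry[f"vs_{base_name}"] = {
                            str(lvl): val
                            for lvl, val in reduction_report(
                                traffic[method][mode], traffic[base_name][mode]
                            ).items()
                        }
                record["reductions"][mode][method] = entry
        report["trials"].append(record)
        if out_dir is not None:  # flush partial results per trial
            (out_dir / "report.json").write_text(json.dumps(report, indent=2))

    report["summary"] = summarize(report["trials"])
    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        summary_table(report).to_csv(out_dir / "summary.csv", index=False)
    return report


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy

    return {
        "hiaerpart": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
    }


def _mean_sd(values: list[float | None]) -> dict[str, float | None]:
    if any(v is None for v in values):
        return {"mean": None, "sd": None}
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


def summarize(trial_records: list[dict]) -> dict:
    """Mean and sample standard deviation per (method, mode, level) cell.

    All trial records must share the same schema; the sd is reported even
    when it is tiny or exactly zero.
    """
    if not trial_records:
        raise ValidationError("no trials to summarize")
    first = trial_records[0]
    for rec in trial_records[1:]:
        if rec["methods"].keys() != first["methods"].keys():
            raise ValidationError("trial records have mismatched method sets")
    summary: dict = {"methods": {}, "reductions": {}}
    for method, modes in first["methods"].items():
        summary["methods"][method] = {}
        for mode, tdict in modes.items():
            if any(
                rec["methods"][method][mode]["per_level"].keys()
                != tdict["per_level"].keys()
                for rec in trial_records
            ):
                raise ValidationError("trial records have mismatched level sets")
            cell: dict = {"per_level": {}, "totals": {}}
            for lvl in tdict["per_level"]:
                cell["per_level"][lvl] = {
                    key: _mean_sd(
                        [
                            rec["methods"][method][mode]["per_level"][lvl][key]
                            for rec in trial_records
                        ]
                    )
                    for key in ("messages", "relays")
                }
            for key in ("messages", "relays"):
                cell["totals"][key] = _mean_sd(
                    [rec["methods"][method][mode]["totals"][key] for rec in trial_records]
                )
            summary["methods"][method][mode] = cell
    for mode, methods in first.get("reductions", {}).items():
        summary["reductions"][mode] = {}
        for method, bases in methods.items():
            summary["reductions"][mode][method] = {
                base: {
                    lvl: _mean_sd(
                        [
                            rec["reductions"][mode][method][base][lvl]
                            for rec in trial_records
                        ]
                    )
                    for lvl in levels
                }
                for base, levels in bases.items()
            }
    return summary


def summary_table(report: dict) -> pd.DataFrame:
    """Long-format summary: one row per (method, mode, level)."""
    rows = []
    summary = report["summary"]
    for method, modes in summary["methods"].items():
        for mode, cell in modes.items():
            for lvl, stats in cell["per_level"].items():
                row = {
                    "method": method,
                    "mode": mode,
                    "level": int(lvl),
                    "messages_mean": stats["messages"]["mean"],
                    "messages_sd": stats["messages"]["sd"],
                    "relays_mean": stats["relays"]["mean"],
                    "relays_sd": stats["relays"]["sd"],
                }
                reds = summary["reductions"].get(mode, {}).get(method, {})
                for base, levels in reds.items():
                    row[f"reduction_{base}_pct_mean"] = levels[lvl]["mean"]
                    row[f"reduction_{base}_pct_sd"] = levels[lvl]["sd"]
                rows.append(row)
    return pd.DataFrame(rows).sort_values(["method", "mode", "level"]).reset_index(
        drop=True
    )
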