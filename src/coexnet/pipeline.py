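"""End-to-end orchestration: expression -> networks -> communities -> PPNs.

A single :class:`RunConfig` (YAML-loadable) drives the run; all randomness
flows from one seed. Each stage logs its counts and writes its artifacts
before the next stage starts, so a failing stage aborts with the stage
name while partial outputs remain on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import communities as comm
from . import network as netmod
from . import pathways as pw
from .exceptions import StageError
from .expression import (
    ExpressionMatrix,
    ProbeGeneMap,
    collapse_probes,
    load_condition_labels,
    load_expression,
    split_by_condition,
)
from .synthetic import SyntheticSpec, evaluate_recovery, generate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Either ``expression``/``labels`` paths or a ``synthetic`` spec must be
    given. Defaults: tau = 0.8 correlation threshold, minimum sub-network
    cardinality 100 for pathway projection.
    """

    outdir: str | Path = "coexnet_out"
    expression: str | Path | None = None
    labels: str | Path | None = None
    probe_map: str | Path | None = None
    annotations: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    tau: float = 0.8
    min_cardinality: int = 100
    seed: int = 0
    top_k: int = 5
    reference_condition: str = "normal"
    disease_condition: str = "dmd"
    largest_component_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("synthetic"), dict):
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        return cls(**raw)


def _run_stage(stage: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", stage)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(stage, str(exc)) from exc
            if exc is None:
                log.info("stage %s: done", stage)
            return False

    return _Ctx()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return (and write) the summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "tau": config.tau,
        "min_cardinality": config.min_cardinality,
        "seed": config.seed,
    }
    truth = None

    with _run_stage("load"):
        if config.synthetic is not None:
            spec = config.synthetic
            exprs, truth, annotation = generate(spec)
            ref, dis = spec.condition_a, spec.condition_b
        else:
            if config.expression is None or config.labels is None:
                raise ValueError("expression and labels paths (or synthetic spec) required")
            label_map = load_condition_labels(config.labels)
            expr = load_expression(config.expression, label_map)
            summary["n_rows_dropped_missing"] = expr.n_dropped_missing
            if config.probe_map is not None:
                expr = collapse_probes(expr, ProbeGeneMap.from_tsv(config.probe_map))
            exprs = split_by_condition(expr)
            annotation = (
                pw.PathwayAnnotation.from_tsv(config.annotations)
                if config.annotations
                else None
            )
            ref, dis = config.reference_condition, config.disease_condition
        summary["conditions"] = {c: e.n_samples for c, e in exprs.items()}
        summary["n_genes"] = next(iter(exprs.values())).n_genes

    networks: dict[str, netmod.InteractionNetwork] = {}
    stats_panel: dict[str, dict[str, float]] = {}
    with _run_stage("networks"):
        for cond, expr in exprs.items():
            corr = netmod.correlation_matrix(expr)
            net = netmod.build_network(corr, config.tau)
            networks[cond] = net
            netmod.write_edgelist(net, outdir / f"network_{cond}.tsv")
            netmod.write_graphml(net, outdir / f"network_{cond}.graphml")
            if net.n_vertices > 0:
                stats_panel[cond] = netmod.network_stats(net).as_dict()
            else:
                stats_panel[cond] = {}
                log.warning("network for condition '%s' is empty", cond)
            entry = {
                "n_vertices": net.n_vertices,
                "n_edges": net.n_edges,
                "n_isolated": len(net.isolated),
            }
            if net.n_vertices > 0:
                lcc = netmod.largest_component(net)
                entry["largest_component"] = {
                    "n_vertices": lcc.n_vertices,
                    "n_edges": lcc.n_edges,
                }
            summary.setdefault("networks", {})[cond] = entry
        pd.DataFrame(stats_panel).to_csv(outdir / "network_stats.tsv", sep="\t")

    community_sets: dict[str, comm.CommunitySet] = {}
    with _run_stage("communities"):
        for cond, net in networks.items():
            if net.n_edges == 0:
                raise ValueError(f"network for condition '{cond}' has no edges")
            target = netmod.largest_component(net) if config.largest_component_only else net
            dendro = comm.ng_dendrogram(target, seed=config.seed)
            cs = comm.best_partition(dendro)
            community_sets[cond] = cs
            comm.write_communities_tsv(cs, outdir / f"communities_{cond}.tsv")
            comm.write_summary_json(cs, config.seed, outdir / f"communities_{cond}.json")
            entry: dict[str, Any] = {
                "n_communities": cs.n_communities,
                "q_max": cs.q_max,
            }
            if truth is not None:
                restricted = {
                    v: truth.assignment[v] for v in cs.partition.assignment
                }
                entry["ari_vs_truth"] = evaluate_recovery(
                    cs.partition, comm.Partition.from_labels(restricted)
                )
            summary.setdefault("communities", {})[cond] = entry

    if annotation is not None and ref in community_sets and dis in networks:
        with _run_stage("pathway_projection"):
            subnets = [
                pw.condition_specific_subnetwork(c, networks[ref], networks[dis])
                for c in community_sets[ref].communities
            ]
            kept = pw.filter_by_cardinality(subnets, config.min_cardinality)
            summary["ppn"] = {
                "n_candidate_subnetworks": len(subnets),
                "n_kept": len(kept),
                "ppns": [],
            }
            for i, sub in enumerate(kept, start=1):
                assign = pw.reduce_pathways(sub, annotation)
                ppn = pw.build_ppn(sub, assign)
                pw.write_ppn_graphml(ppn, outdir / f"ppn_{i}.graphml")
                pw.write_ppn_sif(ppn, outdir / f"ppn_{i}.sif")
                entry = {
                    "n_genes": sub.n_vertices,
                    "n_assigned": ppn.n_assigned_genes,
                    "n_unannotated": len(assign.unannotated),
                    "pathways": {
                        p: ppn.graph.nodes[p]["cardinality"] for p in sorted(ppn.graph)
                    },
                }
                top2 = sorted(
                    ppn.graph.nodes,
                    key=lambda p: (-ppn.graph.nodes[p]["cardinality"], p),
                )[:2]
                if len(top2) == 2 and ppn.graph.has_edge(*top2):
                    pairs = pw.top_pairs(sub, assign, top2[0], top2[1], config.top_k)
                    pairs.to_csv(
                        outdir / f"ppn_{i}_top_pairs.tsv", sep="\t", index=False
                    )
                    entry["top_pair_pathways"] = top2
                summary["ppn"]["ppns"].append(entry)

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
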