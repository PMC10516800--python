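"""End-to-end pipeline: two uptake tables in, networks and reports out.

Stages mirror the analysis workflow: global proportional scaling, within-
group correlation matrices, jackknife-reliable edge sets, double-jackknife
group differences, density tables, graphs with degrees/hubs, ranked degree
changes, figures, and a JSON run manifest.  Everything is deterministic for
fixed inputs and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import reliable_differences_double_jackknife
from .connectivity import EdgeSet, pearson_matrix, reliable_edges_jackknife
from .metrics import (build_graph, degree_change, density_table, identify_hubs,
                      node_degrees)
from .registry import ROIRegistry, default_registry, load_registry
from .uptake import UptakeTable, global_scale, read_uptake
from .viz import graph_figure, heatmap

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end run."""

    group1_path: str
    group2_path: str
    out_dir: str
    registry_path: str | None = None  # None -> shipped default registry
    group1_name: str = "control"
    group2_name: str = "exercise"
    alpha: float = 0.05
    hub_fraction: float = 0.10
    target_mean: float = 100.0
    scale: bool = True
    strict_full_sample: bool = False
    layout_seed: int = 1
    figures: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValueError("hub_fraction must be in (0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PipelineConfig(**raw)


def _matrix_csv(mat: np.ndarray, roi_ids, path: Path) -> None:
    pd.DataFrame(mat, index=list(roi_ids), columns=list(roi_ids)).to_csv(path)


def _edges_csv(edges: EdgeSet, path: Path) -> None:
    rows = [{"roi_i": e.roi_i, "roi_j": e.roi_j,
             "sign": "+" if e.sign > 0 else "-", "r": e.r_full} for e in edges]
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "sign", "r"]).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = (load_registry(config.registry_path) if config.registry_path
                else default_registry())

    tables: dict[str, UptakeTable] = {}
    for name, path in ((config.group1_name, config.group1_path),
                       (config.group2_name, config.group2_path)):
        table = read_uptake(path, registry, group_name=name)
        if config.scale:
            table = global_scale(table, config.target_mean)
        tables[name] = table

    manifest: dict = {
        "metaconn_version": __version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "n_rois": len(registry),
        "groups": {},
    }

    graphs = {}
    degree_reports = {}
    for name, table in tables.items():
        corr = pearson_matrix(table)
        edges = reliable_edges_jackknife(table, alpha=config.alpha,
                                         strict_full_sample=config.strict_full_sample)
        _matrix_csv(corr.r, registry.roi_ids, out / f"{name}_r.csv")
        _matrix_csv(corr.z, registry.roi_ids, out / f"{name}_z.csv")
        _matrix_csv(corr.p, registry.roi_ids, out / f"{name}_p.csv")
        _edges_csv(edges, out / f"{name}_edges.csv")

        graph = build_graph(edges, registry)
        nx.write_graphml(graph, out / f"{name}_network.graphml")
        density = density_table(edges, registry)
        density.to_csv(out / f"{name}_density.csv", index=False)
        report = identify_hubs(node_degrees(graph, registry), config.hub_fraction)
        report.frame.to_csv(out / f"{name}_degrees.csv", index=False)
        graphs[name] = graph
        degree_reports[name] = report

        sig = np.zeros((len(registry), len(registry)), dtype=bool)
        for e in edges:
            i, j = registry.index_of(e.roi_i), registry.index_of(e.roi_j)
            sig[i, j] = sig[j, i] = True
        if config.figures:
            heatmap(corr.z, registry, out / f"{name}_z_heatmap.png", significant=sig,
                    title=f"{name}: Fisher-z connectivity (n={table.n_subjects})")
            graph_figure(graph, registry, out / f"{name}_network.png",
                         seed=config.layout_seed, title=f"{name} network")
        manifest["groups"][name] = {
            "n_subjects": table.n_subjects,
            "n_edges": len(edges),
            "n_positive": sum(1 for e in edges if e.sign > 0),
            "n_negative": sum(1 for e in edges if e.sign < 0),
            "hubs": report.hubs,
        }

    g1, g2 = config.group1_name, config.group2_name
    diff = reliable_differences_double_jackknife(
        tables[g1], tables[g2], alpha=config.alpha,
        strict_full_sample=config.strict_full_sample)
    _matrix_csv(diff.z, registry.roi_ids, out / "difference_Z.csv")
    _matrix_csv(diff.p, registry.roi_ids, out / "difference_p.csv")
    diff_edges = diff.reliable_edges()
    _edges_csv(diff_edges, out / "difference_edges.csv")
    if config.figures:
        heatmap(diff.z, registry, out / "difference_Z_heatmap.png",
                significant=diff.reliable_mask,
                title=f"Fisher Z: {g2} vs {g1}")
    ranked = degree_change(degree_reports[g1], degree_reports[g2])
    ranked.to_csv(out / "degree_change.csv", index=False)
    manifest["difference"] = {
        "n_reliable": len(diff_edges),
        "n_increased": sum(1 for e in diff_edges if e.sign > 0),
        "n_decreased": sum(1 for e in diff_edges if e.sign < 0),
    }
    manifest["degree_change_top"] = ranked.head(10).to_dict(orient="records")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                       encoding="utf-8")
    return manifest
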