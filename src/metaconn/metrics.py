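"""Graph-theoretic summaries of reliable connectivity networks.

A reliable :class:`~metaconn.connectivity.EdgeSet` becomes an undirected
signed graph whose node set is the *whole* registry (isolated ROIs stay in).
From it we compute:

* connectivity density — reliable-edge counts per structure pair, separately
  for positive and negative edges, as a percentage of all ROI pairs within
  or between the two structures;
* node degree (edges of either sign count equally) and hubs, the top 10% of
  nodes by degree with deterministic registry-order tie-breaking;
* ranked degree changes between two groups' networks;
* a Kamada-Kawai force-directed layout for visualisation, with isolated
  nodes placed on a peripheral ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import EdgeSet
from .registry import ROIRegistry, RegistryError, pair_count

__all__ = [
    "build_graph",
    "connectivity_density",
    "density_table",
    "node_degrees",
    "identify_hubs",
    "degree_change",
    "layout",
    "DegreeReport",
]


def build_graph(edges: EdgeSet, registry: ROIRegistry) -> nx.Graph:
    """Signed undirected graph over all registry ROIs.

    Node attributes: ``structure``; edge attributes: ``sign`` (+1/-1) and
    ``r`` (full-sample correlation or Z-derived sign source).
    """
    g = nx.Graph()
    for roi in registry:
        g.add_node(roi.roi_id, structure=roi.structure)
    for e in edges:
        if e.roi_i not in g or e.roi_j not in g:
            raise RegistryError(f"edge ({e.roi_i}, {e.roi_j}) references unknown ROI")
        g.add_edge(e.roi_i, e.roi_j, sign=e.sign, r=e.r_full)
    return g


def _edge_counts(edges: EdgeSet, registry: ROIRegistry,
                 structure_a: str, structure_b: str) -> tuple[int, int]:
    """(positive, negative) reliable-edge counts crossing a structure pair."""
    pos = neg = 0
    want = frozenset((structure_a, structure_b))
    for e in edges:
        pair = frozenset((registry.structure_of(e.roi_i), registry.structure_of(e.roi_j)))
        if pair == want:
            if e.sign > 0:
                pos += 1
            else:
                neg += 1
    return pos, neg


def connectivity_density(edges: EdgeSet, registry: ROIRegistry,
                         structure_a: str, structure_b: str, sign: int) -> float:
    """Reliable-edge count over the ROI-pair count, as a percentage.

    ``sign`` is +1 or -1; within-structure density uses ``a == b``.  E.g.
    151 positive within-caudoputamen edges over 2145 pairs give 7.04%.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    denom = pair_count(registry, structure_a, structure_b)
    if denom == 0:
        raise ValueError(
            f"density undefined: no ROI pairs for ({structure_a}, {structure_b})"
        )
    pos, neg = _edge_counts(edges, registry, structure_a, structure_b)
    count = pos if sign > 0 else neg
    return 100.0 * count / denom


def density_table(edges: EdgeSet, registry: ROIRegistry) -> pd.DataFrame:
    """Signed density report over every structure pair.

    One row per unordered structure pair (within-structure pairs included),
    with positive/negative counts, pair counts and densities in percent.
    """
    structures = registry.structures
    rows = []
    for ai, a in enumerate(structures):
        for b in structures[ai:]:
            denom = pair_count(registry, a, b)
            pos, neg = _edge_counts(edges, registry, a, b)
            rows.append({
                "structure_a": a,
                "structure_b": b,
                "pair_count": denom,
                "positive_count": pos,
                "negative_count": neg,
                "positive_density": 100.0 * pos / denom if denom else float("nan"),
                "negative_density": 100.0 * neg / denom if denom else float("nan"),
            })
    return pd.DataFrame(rows)


def density_matrix(report: pd.DataFrame, structures: list[str]) -> pd.DataFrame:
    """Square layout: positive densities on/above the diagonal, negative below."""
    mat = pd.DataFrame(0.0, index=structures, columns=structures)
    for row in report.itertuples():
        mat.loc[row.structure_a, row.structure_b] = row.positive_density
        if row.structure_a != row.structure_b:
            mat.loc[row.structure_b, row.structure_a] = row.negative_density
    return mat


@dataclass(frozen=True)
class DegreeReport:
    """Per-node degrees in registry order, with hub flags after ranking."""

    frame: pd.DataFrame  # columns: roi_id, structure, degree [, hub, rank]

    @property
    def degrees(self) -> pd.Series:
        return self.frame.set_index("roi_id")["degree"]

    @property
    def hubs(self) -> list[str]:
        if "hub" not in self.frame.columns:
            raise ValueError("run identify_hubs first")
        return list(self.frame.loc[self.frame["hub"], "roi_id"])


def node_degrees(graph: nx.Graph, registry: ROIRegistry) -> DegreeReport:
    """Degree of every registry node (isolated nodes have degree 0)."""
    frame = pd.DataFrame({
        "roi_id": registry.roi_ids,
        "structure": [r.structure for r in registry],
        "degree": [graph.degree(rid) if rid in graph else 0 for rid in registry.roi_ids],
    })
    return DegreeReport(frame)


def identify_hubs(report: DegreeReport, fraction: float = 0.10) -> DegreeReport:
    """Flag the top ``ceil(fraction * N)`` nodes by degree as hubs.

    Ties at the cutoff resolve by registry order, so the hub count is exactly
    ``ceil(fraction * N)`` (18 for the 176-ROI registry at 10%).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    frame = report.frame.copy()
    n_hubs = math.ceil(fraction * len(frame))
    # stable sort keeps registry order within equal degrees
    order = frame["degree"].to_numpy()
    ranked = np.argsort(-order, kind="stable")
    frame["rank"] = 0
    frame.loc[frame.index[ranked], "rank"] = np.arange(1, len(frame) + 1)
    frame["hub"] = frame["rank"] <= n_hubs
    return DegreeReport(frame)


def degree_change(report1: DegreeReport, report2: DegreeReport) -> pd.DataFrame:
    """Per-node degree difference (group 2 minus group 1), ranked descending.

    Ties keep registry order.  Raises if node sets differ.
    """
    f1, f2 = report1.frame, report2.frame
    if list(f1["roi_id"]) != list(f2["roi_id"]):
        raise ValueError("degree reports cover different node sets")
    out = f1[["roi_id", "structure"]].copy()
    out["degree_1"] = f1["degree"].to_numpy()
    out["degree_2"] = f2["degree"].to_numpy()
    out["degree_delta"] = out["degree_2"] - out["degree_1"]
    order = np.argsort(-out["degree_delta"].to_numpy(), kind="stable")
    return out.iloc[order].reset_index(drop=True)


def layout(graph: nx.Graph, seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic 2-D Kamada-Kawai coordinates.

    Edges are treated as unweighted and unsigned.  Each connected component
    of two or more nodes is energised separately from a seeded circular
    start and offset on a grid; isolated nodes go on a peripheral ring.
    A single-node graph maps to the origin.
    """
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    if len(nodes) == 1:
        return {nodes[0]: np.zeros(2)}
    rng = np.random.default_rng(seed)
    pos: dict[str, np.ndarray] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)[0]))
    placed, isolated = [], []
    for comp in components:
        (isolated if len(comp) == 1 else placed).append(sorted(comp))
    offset = 0.0
    for comp in placed:
        sub = graph.subgraph(comp)
        theta = 2 * np.pi * np.arange(len(comp)) / len(comp)
        jitter = 0.01 * rng.standard_normal((len(comp), 2))
        init = {n: np.array([np.cos(t), np.sin(t)]) + j
                for n, t, j in zip(comp, theta, jitter)}
        sub_pos = nx.kamada_kawai_layout(sub, pos=init, weight=None)
        for n, xy in sub_pos.items():
            pos[n] = np.asarray(xy) + np.array([offset, 0.0])
        offset += 2.5
    radius = 1.5 + offset
    for k, comp in enumerate(isolated):
        angle = 2 * np.pi * k / max(len(isolated), 1)
        pos[comp[0]] = radius * np.array([np.cos(angle), np.sin(angle)])
    return pos
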