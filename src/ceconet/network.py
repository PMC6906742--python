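"""Genus-metabolite correlation network inference and export.

Pearson correlations between genus relative abundances and metabolite peak
areas are screened across all pairs, p-values come from the exact two-tailed
t-test on n-2 degrees of freedom, the family is corrected by the
Benjamini-Hochberg step-up procedure, and surviving edges are classified as
mechanistic (the genus carries an enzyme acting on the metabolite, per the
capability map) or empirical (correlation only).  The result is a bipartite
genus-metabolite graph exportable to SIF / attribute TSVs / GraphML for
Cytoscape.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .knowledge import GenusMetaboliteMap
from .profiles import GenusProfile

__all__ = [
    "Edge",
    "BipartiteNetwork",
    "pearson_with_p",
    "bh_adjust",
    "build_network",
    "classify_edges",
    "node_fold_change",
    "export_network",
]


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with an exact two-tailed t-test p-value.

    p is the two-tailed tail probability of t = r*sqrt(n-2)/sqrt(1-r^2) on
    n-2 degrees of freedom; |r| = 1 yields p = 0.  Requires n >= 3 and two
    non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0)), n


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, q_(i) = min_{j >= i}(p_(j) * m / j), capped at 1,
    returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-d")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class Edge:
    """One significant genus-metabolite correlation."""

    genus: str
    metabolite: str
    r: float
    p: float
    q: float
    n: int
    edge_class: str = "empirical"  # "mechanistic" | "empirical"
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError("|r| must be <= 1")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass
class BipartiteNetwork:
    """Bipartite genus-metabolite graph with per-edge statistics."""

    genus_nodes: list[str]
    metabolite_nodes: list[str]
    edges: list[Edge]
    #: node -> ("increase" | "decrease" | "unchanged", log2 ratio)
    fold_changes: dict[str, tuple[str, float]] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g, m = set(self.genus_nodes), set(self.metabolite_nodes)
        for e in self.edges:
            if e.genus not in g or e.metabolite not in m:
                raise ValueError(f"edge {e.genus}-{e.metabolite} references unknown node")

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for node in self.genus_nodes:
            d, lr = self.fold_changes.get(node, ("unchanged", 0.0))
            G.add_node(node, node_type="genus", fold_direction=d, log2_ratio=lr)
        for node in self.metabolite_nodes:
            d, lr = self.fold_changes.get(node, ("unchanged", 0.0))
            G.add_node(node, node_type="metabolite", fold_direction=d, log2_ratio=lr)
        for e in self.edges:
            G.add_edge(
                e.genus,
                e.metabolite,
                r=e.r,
                p=e.p,
                q=e.q,
                n=e.n,
                edge_class=e.edge_class,
            )
        return G


def build_network(
    genus_profile: GenusProfile | pd.DataFrame,
    metabolite_areas: pd.DataFrame,
    r_min: float = 0.76,
    q_max: float = 0.05,
    use_raw_p: bool = False,
    compound_ids: Mapping[str, str] | None = None,
) -> BipartiteNetwork:
    """All-pairs Pearson screen with Benjamini-Hochberg FDR control.

    Parameters
    ----------
    genus_profile
        Genus relative abundances, samples x genera (or a
        :class:`GenusProfile`).
    metabolite_areas
        Metabolite peak areas, samples x metabolites, restricted to
        confidently identified metabolites.
    r_min, q_max
        Retain edges with \\|r\\| >= ``r_min`` and adjusted p < ``q_max``.
        With ``use_raw_p`` the raw p-value is thresholded instead (the
        adjusted value is still reported).
    compound_ids
        Optional metabolite name -> compound id mapping, used later for
        mechanistic classification.

    Constant-vector pairs are excluded before the BH family is formed, so m
    counts only testable pairs; exclusions are tallied in the report.
    """
    ra = genus_profile.relative_abundance if isinstance(genus_profile, GenusProfile) else genus_profile
    shared = ra.index.intersection(metabolite_areas.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between genus and metabolite tables")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    ra = ra.loc[shared]
    met = metabolite_areas.loc[shared]

    pairs: list[tuple[str, str, float, float, int]] = []
    excluded = 0
    for genus in ra.columns:
        x = ra[genus].to_numpy(float)
        for metab in met.columns:
            y = met[metab].to_numpy(float)
            try:
                r, p, n = pearson_with_p(x, y)
            except ValueError:
                excluded += 1
                continue
            pairs.append((genus, metab, r, p, n))

    edges: list[Edge] = []
    if pairs:
        qvals = bh_adjust([p for (_, _, _, p, _) in pairs])
        for (genus, metab, r, p, n), q in zip(pairs, qvals):
            crit = p if use_raw_p else q
            if abs(r) >= r_min and crit < q_max:
                cid = compound_ids.get(metab) if compound_ids else None
                edges.append(
                    Edge(genus=genus, metabolite=metab, r=r, p=p, q=float(q), n=n,
                         compound_id=cid)
                )

    report = {
        "pairs_tested": len(pairs),
        "pairs_excluded_constant": excluded,
        "edges_retained": len(edges),
        "n_shared_samples": int(len(shared)),
        "r_min": r_min,
        "q_max": q_max,
        "criterion": "raw_p" if use_raw_p else "bh_q",
    }
    return BipartiteNetwork(
        genus_nodes=list(ra.columns),
        metabolite_nodes=list(met.columns),
        edges=edges,
        report=report,
    )


def classify_edges(
    net: BipartiteNetwork, capability: GenusMetaboliteMap
) -> BipartiteNetwork:
    """Split edges into mechanistic and empirical.

    An edge is mechanistic when the metabolite's compound id lies in the
    genus's capability set (some member organism carries a reaction whose
    primary substrate-product pairs involve the compound); metabolites with
    no compound-id mapping stay empirical and are tallied in the report.
    """
    unmapped = 0
    new_edges = []
    for e in net.edges:
        if e.compound_id is None:
            unmapped += 1
            new_edges.append(replace(e, edge_class="empirical"))
            continue
        mechanistic = capability.can_act_on(e.genus, e.compound_id)
        new_edges.append(replace(e, edge_class="mechanistic" if mechanistic else "empirical"))
    report = dict(net.report)
    report["edges_mechanistic"] = sum(1 for e in new_edges if e.edge_class == "mechanistic")
    report["edges_empirical"] = sum(1 for e in new_edges if e.edge_class == "empirical")
    report["metabolites_without_compound_id"] = unmapped
    return BipartiteNetwork(
        genus_nodes=net.genus_nodes,
        metabolite_nodes=net.metabolite_nodes,
        edges=new_edges,
        fold_changes=dict(net.fold_changes),
        report=report,
    )


def node_fold_change(
    day1_means: Mapping[str, float],
    day7_means: Mapping[str, float],
    pseudo: float = 1e-9,
    dead_zone: float = 0.26,
) -> dict[str, tuple[str, float]]:
    """Day-1 -> day-7 fold direction per node.

    ratio = (mean_day7 + pseudo) / (mean_day1 + pseudo); a node is
    "increase" when log2(ratio) > ``dead_zone`` (default 0.26, about
    1.2-fold), "decrease" below -``dead_zone``, otherwise "unchanged".
    Nodes missing on either day are "unchanged" with a diagnostic NaN ratio.
    """
    out: dict[str, tuple[str, float]] = {}
    for node in set(day1_means) | set(day7_means):
        if node not in day1_means or node not in day7_means:
            out[node] = ("unchanged", float("nan"))
            continue
        m1, m7 = float(day1_means[node]), float(day7_means[node])
        if m1 < 0 or m7 < 0:
            raise ValueError(f"negative mean for node '{node}'")
        log2_ratio = float(np.log2((m7 + pseudo) / (m1 + pseudo)))
        if log2_ratio > dead_zone:
            direction = "increase"
        elif log2_ratio < -dead_zone:
            direction = "decrease"
        else:
            direction = "unchanged"
        out[node] = (direction, log2_ratio)
    return out


def export_network(net: BipartiteNetwork, out_dir: str) -> dict[str, str]:
    """Write network.sif, edges.tsv, nodes.tsv, network.graphml and
    report.json.  Output is byte-stable for identical input: rows follow the
    network's node and edge order with a fixed field order and float
    formatting."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "sif": os.path.join(out_dir, "network.sif"),
        "edges": os.path.join(out_dir, "edges.tsv"),
        "nodes": os.path.join(out_dir, "nodes.tsv"),
        "graphml": os.path.join(out_dir, "network.graphml"),
        "report": os.path.join(out_dir, "report.json"),
    }
    with open(paths["sif"], "w") as fh:
        for e in net.edges:
            fh.write(f"{e.genus}\tcorr\t{e.metabolite}\n")
    with open(paths["edges"], "w") as fh:
        fh.write("genus\tmetabolite\tr\tp\tq\tn\tedge_class\n")
        for e in net.edges:
            fh.write(
                f"{e.genus}\t{e.metabolite}\t{e.r:.6g}\t{e.p:.6g}\t{e.q:.6g}"
                f"\t{e.n}\t{e.edge_class}\n"
            )
    with open(paths["nodes"], "w") as fh:
        fh.write("node\ttype\tfold_direction\tlog2_ratio\n")
        for node in net.genus_nodes:
            d, lr = net.fold_changes.get(node, ("unchanged", float("nan")))
            fh.write(f"{node}\tgenus\t{d}\t{lr:.6g}\n")
        for node in net.metabolite_nodes:
            d, lr = net.fold_changes.get(node, ("unchanged", float("nan")))
            fh.write(f"{node}\tmetabolite\t{d}\t{lr:.6g}\n")
    nx.write_graphml(net.to_networkx(), paths["graphml"])
    with open(paths["report"], "w") as fh:
        json.dump(net.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_network(out_dir: str) -> BipartiteNetwork:
    """Round-trip reader for :func:`export_network` output (TSV attributes)."""
    nodes = pd.read_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t")
    edges = pd.read_csv(os.path.join(out_dir, "edges.tsv"), sep="\t")
    genus_nodes = nodes.loc[nodes["type"] == "genus", "node"].tolist()
    met_nodes = nodes.loc[nodes["type"] == "metabolite", "node"].tolist()
    fold = {
        row["node"]: (row["fold_direction"], float(row["log2_ratio"]))
        for _, row in nodes.iterrows()
    }
    edge_objs = [
        Edge(
            genus=row["genus"],
            metabolite=row["metabolite"],
            r=float(row["r"]),
            p=float(row["p"]),
            q=float(row["q"]),
            n=int(row["n"]),
            edge_class=row["edge_class"],
        )
        for _, row in edges.iterrows()
    ]
    report_path = os.path.join(out_dir, "report.json")
    report = {}
    if os.path.exists(report_path):
        with open(report_path) as fh:
            report = json.load(fh)
    return BipartiteNetwork(
        genus_nodes=genus_nodes,
        metabolite_nodes=met_nodes,
        edges=edge_objs,
        fold_changes=fold,
        report=report,
    )
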