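"""Merged dysregulation network and its topology statistics.

Significant loops are merged into one deduplicated regulatory network: node
and edge sets are unions, so a link shared by many loops counts once.  A
node's degree counts the typed links incident to it (a mutual miRNA<->TF
pair contributes two), which makes the per-class degree sums equal the
per-type link counts and the grand total equal twice the link count.
Betweenness centrality is computed with Brandes' exact algorithm on the
collapsed undirected simple graph, normalized by (n-1)(n-2)/2.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import EDGE_TYPES, FFL, _EDGE_CLASSES

log = logging.getLogger(__name__)

NODE_CLASSES = ("miRNA", "gene", "TF")


@dataclass
class RegNet:
    """Deduplicated union of loop nodes and typed directed links."""

    node_class: dict[str, str]
    links: set[tuple[str, str, str]]  # (source, target, edge_type)

    def __post_init__(self) -> None:
        for src, tgt, et in self.links:
            if src not in self.node_class or tgt not in self.node_class:
                raise ValueError(f"link ({src}, {tgt}) has an endpoint that is not a node")
            if et not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {et!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_class)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def class_nodes(self, cls: str) -> list[str]:
        return sorted(n for n, c in self.node_class.items() if c == cls)

    def class_counts(self) -> dict[str, int]:
        return {cls: len(self.class_nodes(cls)) for cls in NODE_CLASSES}

    def per_type_edge_counts(self) -> dict[str, int]:
        c = Counter(et for _, _, et in self.links)
        return {et: c.get(et, 0) for et in EDGE_TYPES}

    def degrees(self) -> dict[str, int]:
        """Incident typed-link counts (antiparallel links count separately)."""
        d = Counter()
        for src, tgt, _ in self.links:
            d[src] += 1
            d[tgt] += 1
        return {n: d.get(n, 0) for n in self.node_class}

    def undirected(self) -> nx.Graph:
        """Simple undirected view (antiparallel links collapse to one edge)."""
        g = nx.Graph()
        for n, cls in self.node_class.items():
            g.add_node(n, node_class=cls)
        for src, tgt, _ in self.links:
            g.add_edge(src, tgt)
        return g

    def directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n, cls in self.node_class.items():
            g.add_node(n, node_class=cls)
        for src, tgt, et in self.links:
            g.add_edge(src, tgt, edge_type=et)
        return g


def merge_ffls(ffls: Iterable[FFL]) -> RegNet:
    """Union the nodes and typed links of loops, deduplicating both."""
    node_class: dict[str, str] = {}
    links: set[tuple[str, str, str]] = set()
    for f in ffls:
        node_class[f.mirna] = "miRNA"
        node_class[f.tf] = "TF"
        node_class[f.gene] = "gene"
        links |= f.edges
    return RegNet(node_class=node_class, links=links)


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------

def mean_degree_from_counts(
    class_sizes: Mapping[str, int], link_counts: Mapping[str, int]
) -> dict[str, float]:
    """Class mean degrees from per-type link counts and class sizes.

    Each typed link contributes one degree to the class of its regulator and
    one to the class of its target, so e.g. the miRNA degree sum is
    mirna_gene + mirna_tf + tf_mirna.
    """
    sums = {cls: 0 for cls in NODE_CLASSES}
    for et in EDGE_TYPES:
        reg_cls, tgt_cls = _EDGE_CLASSES[et]
        sums[reg_cls] += link_counts[et]
        sums[tgt_cls] += link_counts[et]
    return {cls: sums[cls] / class_sizes[cls] for cls in NODE_CLASSES}


def degree_stats(net: RegNet) -> dict[str, tuple[float, int, int]]:
    """Per-class (mean, min, max) degree."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degrees()
    out = {}
    for cls in NODE_CLASSES:
        nodes = net.class_nodes(cls)
        if not nodes:
            continue
        ds = [deg[n] for n in nodes]
        out[cls] = (float(np.mean(ds)), int(min(ds)), int(max(ds)))
    return out


def betweenness(net: RegNet) -> dict[str, float]:
    """Exact normalized betweenness centrality on the undirected view."""
    if net.n_nodes == 0:
        return {}
    return {
        n: float(b)
        for n, b in nx.betweenness_centrality(net.undirected(), normalized=True).items()
    }


def powerlaw_fit(degrees: Mapping[str, int]) -> tuple[float, float]:
    """Least-squares line on (log10 k, log10 count(k)); returns (slope, R^2).

    Fits over observed degree values k >= 1 with count > 0.  A constant
    count profile yields slope 0 with R^2 = 1 (the flat line fits exactly).
    Requires at least 3 distinct positive degree values.
    """
    counts = Counter(d for d in degrees.values() if d >= 1)
    ks = sorted(counts)
    if len(ks) < 3:
        raise ValueError(f"need >= 3 distinct degrees, got {len(ks)}")
    x = np.log10(ks)
    y = np.log10([counts[k] for k in ks])
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Hub / betweenness selection and group comparison
# ---------------------------------------------------------------------------

def _ranked(nodes: list[str], primary: Mapping[str, float], secondary: Mapping[str, float]) -> list[str]:
    return sorted(nodes, key=lambda n: (-primary[n], -secondary.get(n, 0.0), n))


def select_hubs(
    net: RegNet, method: str = "top_k_per_class", k: int = 4
) -> dict[str, list[str]]:
    """Per-class hub nodes.

    ``top_k_per_class`` takes the k highest-degree nodes per class (ties
    broken by betweenness, then name); ``degree_threshold`` takes nodes
    whose degree is at least the class mean plus two standard deviations.
    """
    deg = net.degrees()
    bc = betweenness(net)
    out: dict[str, list[str]] = {}
    for cls in NODE_CLASSES:
        nodes = net.class_nodes(cls)
        if not nodes:
            out[cls] = []
            continue
        if method == "top_k_per_class":
            if k > len(nodes):
                log.info("class %s has only %d nodes (< k=%d); returning all", cls, len(nodes), k)
            out[cls] = _ranked(nodes, deg, bc)[:k]
        elif method == "degree_threshold":
            ds = np.array([deg[n] for n in nodes], dtype=float)
            cut = ds.mean() + 2.0 * ds.std(ddof=0)
            out[cls] = _ranked([n for n in nodes if deg[n] >= cut], deg, bc)
        else:
            raise ValueError(f"unknown hub method {method!r}")
    return out


def top_fraction_count(n: int, fraction: float) -> int:
    """Number of nodes in the top ``fraction`` of a class of size n."""
    return math.ceil(fraction * n)


def select_top_bc(net: RegNet, fraction: float = 0.05) -> dict[str, list[str]]:
    """Per class, the ceil(fraction * class size) nodes with highest BC."""
    deg = net.degrees()
    bc = betweenness(net)
    out: dict[str, list[str]] = {}
    for cls in NODE_CLASSES:
        nodes = net.class_nodes(cls)
        k = top_fraction_count(len(nodes), fraction)
        out[cls] = _ranked(nodes, bc, deg)[:k]
    return out


@dataclass
class NodeSetComparison:
    metric: str
    statistic: float
    pvalue: float
    median_flagged: float
    median_background: float


def compare_node_sets(
    net: RegNet, flagged: set[str], background: set[str], metric: str = "degree"
) -> NodeSetComparison:
    """Two-sided Wilcoxon rank-sum comparison of degree or BC between sets."""
    if metric not in ("degree", "bc"):
        raise ValueError(f"unknown metric {metric!r}")
    if flagged & background:
        raise ValueError("flagged and background sets must be disjoint")
    if len(flagged) < 2 or len(background) < 2:
        raise ValueError("both sets need >= 2 members")
    values = net.degrees() if metric == "degree" else betweenness(net)
    x = [values[n] for n in sorted(flagged)]
    y = [values[n] for n in sorted(background)]
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return NodeSetComparison(
        metric=metric,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_flagged=float(np.median(x)),
        median_background=float(np.median(y)),
    )


# ---------------------------------------------------------------------------
# Report and export
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    degrees: dict[str, int]
    bc: dict[str, float]
    powerlaw_slope: float
    powerlaw_r2: float
    hubs: dict[str, list[str]]
    top_bc: dict[str, list[str]]
    hub_method: str = "top_k_per_class"


def topology_report(
    net: RegNet,
    hub_method: str = "top_k_per_class",
    hub_k: int = 4,
    bc_fraction: float = 0.05,
) -> TopologyReport:
    deg = net.degrees()
    try:
        slope, r2 = powerlaw_fit(deg)
    except ValueError:
        slope, r2 = math.nan, math.nan
    return TopologyReport(
        degrees=deg,
        bc=betweenness(net),
        powerlaw_slope=slope,
        powerlaw_r2=r2,
        hubs=select_hubs(net, method=hub_method, k=hub_k),
        top_bc=select_top_bc(net, fraction=bc_fraction),
        hub_method=hub_method,
    )


def write_edge_list(net: RegNet, path: str | Path) -> None:
    rows = sorted(net.links)
    pd.DataFrame(rows, columns=["source", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: RegNet, path: str | Path) -> None:
    nx.write_graphml(net.directed(), path)


def write_topology_report(report: TopologyReport, net: RegNet, path: str | Path) -> None:
    deg, bc = report.degrees, report.bc
    rows = [
        (
            n,
            net.node_class[n],
            deg[n],
            bc.get(n, 0.0),
            n in report.hubs.get(net.node_class[n], []),
            n in report.top_bc.get(net.node_class[n], []),
        )
        for n in sorted(net.node_class)
    ]
    pd.DataFrame(
        rows, columns=["node", "node_class", "degree", "bc", "is_hub", "is_top_bc"]
    ).to_csv(path, sep="\t", index=False)
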