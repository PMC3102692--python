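"""Degree statistics, scale-free diagnostics, density and bait-based subnetworks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import GeneNetwork

__all__ = [
    "DegreeHistogram",
    "degree_table",
    "degree_histogram_loglog",
    "network_density",
    "bait_neighbors",
    "extract_subnetwork",
]

log = logging.getLogger(__name__)


def degree_table(net: GeneNetwork) -> dict:
    """Partner counts per network node (every node has degree >= 1)."""
    return dict(net.graph.degree())


@dataclass(frozen=True)
class DegreeHistogram:
    """log2-binned degree histogram with a least-squares tail slope.

    ``table`` has one row per occupied integer log2 bin *b* (degrees in
    [2^b, 2^(b+1))): ``log2_degree`` is the geometric bin centre b + 1/2,
    ``count`` the number of genes, ``log2_count`` its log2. ``slope`` is the
    least-squares slope of log2_count on log2_degree over the fitted bins;
    ``degenerate`` flags a single-degree-value input for which no slope is
    defined.
    """

    table: pd.DataFrame
    slope: float | None
    degenerate: bool


def degree_histogram_loglog(degrees: dict, tail_range: tuple | None = None) -> DegreeHistogram:
    """Histogram of degrees over integer log2 bins, plus a power-law tail slope.

    ``tail_range = (lo, hi)`` restricts the slope fit to bins with geometric
    centre log2-degree in [lo, hi]; by default all occupied bins are fitted.
    """
    values = np.array(sorted(degrees.values()))
    if values.size == 0 or (values <= 0).any():
        raise ValidationError("degrees must be positive")
    if len(set(values.tolist())) < 2:
        log.warning("single distinct degree value: tail slope undefined")
        b = int(np.floor(np.log2(values[0])))
        table = pd.DataFrame(
            {"log2_degree": [b + 0.5], "count": [values.size], "log2_count": [np.log2(values.size)]}
        )
        return DegreeHistogram(table, None, True)
    bins = np.floor(np.log2(values)).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    table = pd.DataFrame(
        {
            "log2_degree": uniq + 0.5,  # geometric centre of [2^b, 2^(b+1))
            "count": counts,
            "log2_count": np.log2(counts),
        }
    )
    x = table["log2_degree"].to_numpy()
    y = table["log2_count"].to_numpy()
    if tail_range is not None:
        lo, hi = tail_range
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    if x.size < 2:
        log.warning("fewer than 2 bins in the fitted range: slope undefined")
        return DegreeHistogram(table, None, True)
    slope = float(np.polyfit(x, y, 1)[0])
    return DegreeHistogram(table, slope, False)


def network_density(net: GeneNetwork, genes=None) -> float:
    """Edge-node ratio of the induced subnetwork on ``genes`` (default: whole network).

    This is the compactness measure edges / nodes, not the graph-theoretic
    2E / n(n-1).
    """
    if genes is None:
        nodes = net.nodes
    else:
        genes = set(genes)
        if not genes:
            raise ValidationError("gene subset is empty")
        nodes = genes & net.nodes
        if not nodes:
            raise ValidationError("gene subset is disjoint from the network nodes")
    n_edges = sum(1 for a, b, _ in net.edges() if a in nodes and b in nodes)
    return n_edges / len(nodes)


def bait_neighbors(net: GeneNetwork, bait, min_links: int = 1) -> set:
    """Genes outside the bait with >= ``min_links`` network partners inside it."""
    bait = set(bait)
    if not bait:
        raise ValidationError("bait set is empty")
    if min_links < 1:
        raise ValidationError("min_links must be >= 1")
    if min_links > len(bait):
        log.warning(
            "min_links (%d) exceeds bait size (%d): no gene can qualify",
            min_links,
            len(bait),
        )
        return set()
    counts: dict = {}
    for b in bait & net.nodes:
        for nb in net.graph.neighbors(b):
            if nb not in bait:
                counts[nb] = counts.get(nb, 0) + 1
    return {g for g, c in counts.items() if c >= min_links}


def extract_subnetwork(net: GeneNetwork, genes) -> GeneNetwork:
    """Induced subgraph on ``genes``; members without an induced edge are dropped."""
    genes = set(genes)
    sub = net.graph.subgraph(genes & net.nodes)
    g = nx.Graph()
    g.add_edges_from(sub.edges(data=True))
    return GeneNetwork(g, net.cutoff, net.method)
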