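"""Regulatory-pattern census of the positive E-P interaction network.

Positive pairs form a bipartite graph (enhancer and promoter nodes, one edge
per distinct interacting pair).  Each connected component is classified by
its element counts (nE enhancers, nP promoters):

* Single -- (1, 1): one enhancer, one promoter;
* MO (multi-output) -- (1, >1): one enhancer regulating several promoters;
* MI (multi-input) -- (>1, 1): one promoter regulated by several enhancers;
* MIMO -- (>1, >1): a many-to-many regulatory subnetwork.

Every edge (pair) inherits its component's label, so the labels partition
the distinct positive pairs.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome_features import EPPair

PATTERNS = ("Single", "MO", "MI", "MIMO")


def _enh_key(p: EPPair) -> tuple:
    return ("E", p.enhancer.chrom, p.enhancer.start, p.enhancer.end)


def _prom_key(p: EPPair) -> tuple:
    return ("P", p.promoter.chrom, p.promoter.start, p.promoter.end)


def build_graph(pairs: Sequence[EPPair]) -> nx.Graph:
    """Deduplicated bipartite graph of the positive pairs.

    Element identity is the exact interval (chrom, start, end); duplicate
    pair rows collapse onto one edge carrying every contributing pair_id.
    """
    g = nx.Graph()
    for p in pairs:
        if p.label != 1:
            continue
        e, pr = _enh_key(p), _prom_key(p)
        g.add_node(e, bipartite="enhancer")
        g.add_node(pr, bipartite="promoter")
        if g.has_edge(e, pr):
            g.edges[e, pr]["pair_ids"].append(p.pair_id)
        else:
            g.add_edge(e, pr, pair_ids=[p.pair_id])
    return g


def classify_component(n_enh: int, n_prom: int) -> str:
    if n_enh == 1 and n_prom == 1:
        return "Single"
    if n_enh == 1:
        return "MO"
    if n_prom == 1:
        return "MI"
    return "MIMO"


def classify_patterns(graph: nx.Graph
                      ) -> tuple[dict[str, str], Counter, pd.DataFrame]:
    """Component-level pattern label for every positive pair.

    Returns (pair_id -> label, per-label distinct-edge counts, a per-edge
    table with component ids).
    """
    labels: dict[str, str] = {}
    counts: Counter = Counter({p: 0 for p in PATTERNS})
    rows = []
    for comp_id, nodes in enumerate(nx.connected_components(graph)):
        n_enh = sum(1 for n in nodes if n[0] == "E")
        n_prom = sum(1 for n in nodes if n[0] == "P")
        label = classify_component(n_enh, n_prom)
        sub = graph.subgraph(nodes)
        for u, v, data in sub.edges(data=True):
            counts[label] += 1
            for pid in data["pair_ids"]:
                labels[pid] = label
            rows.append({"component": comp_id, "pattern": label,
                         "pair_id": data["pair_ids"][0]})
    return labels, counts, pd.DataFrame(rows)


def pattern_probability_summary(labels: Mapping[str, str],
                                predictions: Mapping[str, float]
                                ) -> pd.DataFrame:
    """Distribution of predicted probabilities per regulatory pattern.

    Rows for all four patterns are always present; a pattern with no pairs
    reports n=0 and null statistics.
    """
    missing = [pid for pid in predictions if pid not in labels]
    if missing:
        raise KeyError(f"scored pair(s) without a pattern label: {missing[:5]}")
    rows = []
    for pattern in PATTERNS:
        vals = np.asarray([score for pid, score in predictions.items()
                           if labels[pid] == pattern])
        if len(vals) == 0:
            rows.append({"pattern": pattern, "n": 0, "mean": np.nan,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
        else:
            rows.append({"pattern": pattern, "n": len(vals),
                         "mean": float(vals.mean()),
                         "median": float(np.median(vals)),
                         "q1": float(np.quantile(vals, 0.25)),
                         "q3": float(np.quantile(vals, 0.75))})
    return pd.DataFrame(rows)
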