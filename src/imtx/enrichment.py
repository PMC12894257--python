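"""Specificity enrichment (Fisher exact + BH-FDR) and PPI hub extraction.

Specificity panels are consumed as precomputed gene sets (per tissue, cell
type, or developmental window, at a stated specificity-index threshold);
interaction networks arrive as confidence-scored edge lists and hubs are the
top decile of nodes by degree on the high-confidence subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["fisher_enrichment", "bh_fdr", "hub_detection", "HubReport", "write_graphml"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    candidate: set[str] | list[str],
    panel: dict[str, list[str] | set[str]],
    background: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of a candidate gene set per label.

    Each label's set is intersected with the background universe before the
    2x2 table is formed; q-values are BH across the panel and labels are
    flagged significant at q < ``alpha``.
    """
    candidate = set(candidate)
    background = set(background)
    if not candidate or not background:
        raise ValueError("candidate and background must be nonempty")
    if not candidate <= background:
        raise ValueError("candidate genes must be a subset of the background universe")
    rows = []
    for label, genes in panel.items():
        s = set(genes) & background
        a = len(candidate & s)
        b = len(candidate - s)
        c = len(s - candidate)
        d = len(background) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"label": label, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


@dataclass
class HubReport:
    degrees: dict[str, int]
    hubs: list[str]
    cutoff: float
    fraction: float

    @property
    def n_nodes(self) -> int:
        return len(self.degrees)


def hub_detection(
    edges: pd.DataFrame,
    cutoff: float = 0.9,
    fraction: float = 0.10,
    score_col: str = "combined_score",
) -> HubReport:
    """Top-decile-degree hubs on the confidence-filtered interaction graph.

    Duplicate edges keep their maximum score; self-loops are dropped; only
    edges with score >= ``cutoff`` count.  Hubs are the top
    ceil(fraction * n) of the n nodes with at least one retained edge,
    ranked by degree with ties broken by node id.  Invariant to edge-list
    order.
    """
    G = nx.Graph()
    for a, b, s in edges[["node1", "node2", score_col]].itertuples(index=False):
        if a == b:
            continue
        if G.has_edge(a, b):
            G[a][b]["score"] = max(G[a][b]["score"], float(s))
        else:
            G.add_edge(a, b, score=float(s))
    drop = [(a, b) for a, b, d in G.edges(data=True) if d["score"] < cutoff]
    G.remove_edges_from(drop)
    G.remove_nodes_from([n for n in list(G.nodes) if G.degree(n) == 0])
    if G.number_of_nodes() == 0:
        logger.warning("no edges survive the %.2f confidence cutoff", cutoff)
        return HubReport({}, [], cutoff, fraction)
    degrees = {str(n): int(d) for n, d in G.degree()}
    k = int(np.ceil(fraction * len(degrees)))
    ranked = sorted(degrees, key=lambda n: (-degrees[n], n))
    return HubReport(degrees, ranked[:k], cutoff, fraction)


def write_graphml(edges: pd.DataFrame, path, cutoff: float | None = None,
                  score_col: str = "combined_score") -> None:
    """Export the (optionally confidence-filtered) graph for external viewers."""
    G = nx.Graph()
    for a, b, s in edges[["node1", "node2", score_col]].itertuples(index=False):
        if a == b:
            continue
        if cutoff is not None and s < cutoff:
            continue
        G.add_edge(a, b, score=float(s))
    nx.write_graphml(G, path)
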