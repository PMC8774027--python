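"""Multi-source PPI merging, DEG neighborhoods, centrality, hub nomination.

Edge lists from several interaction databases are merged into one
undirected simple graph (symbols uppercased, optional human-symbol
allow-list, self-loops and duplicate undirected pairs removed, then
degree-1 nodes pruned in a single pass).  Central proteins are the
nodes at or above the 95th percentile in BOTH degree and betweenness
centrality; the top-central set additionally excludes nodes encoded by
the DEGs themselves.  Gene-category enrichment uses a one-sided
hypergeometric (Fisher) test with a configurable background universe.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

__all__ = [
    "merge_networks",
    "neighborhood",
    "centrality",
    "central_nodes",
    "fisher_enrichment",
]


def merge_networks(
    edge_lists: list[tuple[str, pd.DataFrame]],
    allowed_symbols: set[str] | None = None,
    prune_iteratively: bool = False,
) -> nx.Graph:
    """Merge source-tagged edge lists into one simple undirected graph.

    Each DataFrame needs two identifier columns (the first two are
    used).  Symbols are uppercased; edges with an endpoint outside
    ``allowed_symbols`` (when given) are dropped; self-loops are
    dropped; duplicate undirected edges are collapsed with their source
    sets unioned.  Nodes with degree 1 are then removed -- in a single
    pass by default (nodes whose degree drops to 1 because of the pass
    survive), or iterated to the 2-core with ``prune_iteratively``.
    """
    g = nx.Graph()
    allowed = {s.upper() for s in allowed_symbols} if allowed_symbols is not None else None
    for source, df in edge_lists:
        if df.shape[1] < 2:
            raise ValueError(f"edge list {source!r} needs two identifier columns")
        a = df.iloc[:, 0].astype(str).str.upper()
        b = df.iloc[:, 1].astype(str).str.upper()
        for u, v in zip(a, b):
            if u == v:
                continue
            if allowed is not None and (u not in allowed or v not in allowed):
                continue
            if g.has_edge(u, v):
                g[u][v]["sources"].add(source)
            else:
                g.add_edge(u, v, sources={source})
    if prune_iteratively:
        g = nx.k_core(g, k=2).copy()
    else:
        leaves = [n for n, d in g.degree() if d <= 1]
        g.remove_nodes_from(leaves)
    if g.number_of_nodes() == 0:
        raise ValueError("merged graph is empty after filtering")
    return g


def neighborhood(g: nx.Graph, seeds: set[str]) -> nx.Graph:
    """Induced subgraph over the seeds present in g plus their direct interactors."""
    present = {s.upper() for s in seeds} & set(g.nodes)
    if not present:
        raise ValueError("no seed gene is present in the graph")
    nodes = set(present)
    for s in present:
        nodes.update(g.neighbors(s))
    return g.subgraph(nodes).copy()


def centrality(g: nx.Graph, deg_encoded: set[str] | None = None) -> pd.DataFrame:
    """Degree and exact unnormalized betweenness per node.

    Betweenness uses Brandes' algorithm on the unweighted undirected
    graph with equal-split credit over equal-length shortest paths
    (computed per connected component by construction).
    """
    btw = nx.betweenness_centrality(g, normalized=False)
    deg_encoded = set(deg_encoded) if deg_encoded else set()
    table = pd.DataFrame(
        {
            "degree": dict(g.degree()),
            "betweenness": btw,
        }
    ).rename_axis("node")
    table["is_deg_encoded"] = table.index.isin(deg_encoded)
    return table.sort_index()


def _nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(pct/100 * n)."""
    v = np.sort(values)
    rank = int(np.ceil(pct / 100.0 * v.size))
    return float(v[min(max(rank, 1), v.size) - 1])


def central_nodes(
    table: pd.DataFrame, deg_encoded: set[str] | None = None, pct: float = 95.0
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Nominate central and top-central nodes.

    Central: degree >= pct-th percentile of degrees AND betweenness >=
    pct-th percentile of betweenness (nearest-rank thresholds, ties at
    the threshold included).  Top-central: central minus DEG-encoded
    nodes.  Returns (central set, top-central set, annotated table).
    """
    if table.empty:
        raise ValueError("empty centrality table")
    if not 0 < pct < 100:
        raise ValueError("pct must lie in (0, 100)")
    deg_encoded = set(deg_encoded) if deg_encoded else set(
        table.index[table.get("is_deg_encoded", pd.Series(False, index=table.index))]
    )
    thr_deg = _nearest_rank(table["degree"].to_numpy(dtype=float), pct)
    thr_btw = _nearest_rank(table["betweenness"].to_numpy(dtype=float), pct)
    central_mask = (table["degree"] >= thr_deg) & (table["betweenness"] >= thr_btw)
    central = set(table.index[central_mask])
    top = central - deg_encoded
    out = table.copy()
    out["is_deg_encoded"] = out.index.isin(deg_encoded)
    out["is_central"] = central_mask
    out["is_top_central"] = central_mask & ~out["is_deg_encoded"]
    return central, top, out


def fisher_enrichment(
    hits_in_set: int, set_size: int, category_size: int, universe: int
) -> tuple[float, float]:
    """One-sided (greater) Fisher/hypergeometric enrichment test.

    p = P(X >= hits) for X ~ Hypergeometric(universe, category_size,
    set_size); the odds ratio is the conditional MLE from the 2x2
    table.  Returns (odds_ratio, p).
    """
    if not (0 <= hits_in_set <= min(set_size, category_size)):
        raise ValueError("hits_in_set must lie in [0, min(set_size, category_size)]")
    if category_size > universe or set_size > universe:
        raise ValueError("category and set must fit inside the universe")
    if universe - set_size - category_size + hits_in_set < 0:
        raise ValueError("inconsistent 2x2 table counts")
    p = float(stats.hypergeom.sf(hits_in_set - 1, universe, category_size, set_size))
    table = [
        [hits_in_set, set_size - hits_in_set],
        [category_size - hits_in_set, universe - set_size - category_size + hits_in_set],
    ]
    orr = odds_ratio(table, kind="conditional").statistic
    return float(orr), p
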