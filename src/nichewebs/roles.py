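"""Per-node topology: within-module degree Zi, participation Pi, role classes.

The Guimerà–Amaral scheme scores each node by how connected it is inside
its own module (Zi, a z-score of within-module degree over module members)
and how evenly its links spread across modules (Pi = 1 - sum_s (k_is/k_i)^2).
Thresholds Zi = 2.5 and Pi = 0.62 carve the plane into peripheral nodes,
connectors, module hubs, and network hubs.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "zi",
    "pi",
    "classify_role",
    "node_centralities",
    "node_role_table",
    "compare_by_category",
    "significance_stars",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
ROLES = ("peripheral", "connector", "module_hub", "network_hub")


def _within_degree(g: nx.Graph, partition: dict) -> dict:
    wd = {}
    for v in g.nodes:
        s = partition[v]
        wd[v] = sum(1 for u in g.neighbors(v) if partition[u] == s)
    return wd


def zi(g: nx.Graph, partition: dict) -> pd.Series:
    """Within-module degree z-score; 0 for singleton or zero-variance modules.

    Uses the population standard deviation over module members.
    """
    wd = _within_degree(g, partition)
    members = {}
    for v in g.nodes:
        members.setdefault(partition[v], []).append(v)
    out = {}
    for s, vs in members.items():
        ks = np.array([wd[v] for v in vs], dtype=float)
        mu, sd = ks.mean(), ks.std()  # population sd
        for v in vs:
            out[v] = 0.0 if sd == 0 else (wd[v] - mu) / sd
    return pd.Series(out, name="zi").loc[list(g.nodes)]


def pi(g: nx.Graph, partition: dict) -> pd.Series:
    """Participation coefficient Pi = 1 - sum_s (k_is/k_i)^2; 0 for degree-0 nodes."""
    out = {}
    for v in g.nodes:
        k = g.degree(v)
        if k == 0:
            out[v] = 0.0
            continue
        per_mod = {}
        for u in g.neighbors(v):
            per_mod[partition[u]] = per_mod.get(partition[u], 0) + 1
        out[v] = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
    return pd.Series(out, name="pi").loc[list(g.nodes)]


def classify_role(z: float, p: float) -> str:
    if z <= ZI_THRESHOLD:
        return "peripheral" if p <= PI_THRESHOLD else "connector"
    return "module_hub" if p <= PI_THRESHOLD else "network_hub"


def node_centralities(g: nx.Graph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Betweenness, closeness, neighborhood connectivity, mean shortest path.

    Closeness is (number of reachable nodes) / (sum of distances) within a
    node's component (classic Freeman form restricted to the component);
    betweenness is unnormalized by default. Neighborhood connectivity is
    the mean degree of a node's neighbors. The mean shortest path is over
    nodes reachable from each node.
    """
    btw = nx.betweenness_centrality(g, normalized=normalized_betweenness)
    cls = nx.closeness_centrality(g, wf_improved=False)
    nbr = nx.average_neighbor_degree(g)
    asp = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for v, dd in nx.all_pairs_shortest_path_length(sub):
            dists = [d for d in dd.values() if d > 0]
            asp[v] = float(np.mean(dists)) if dists else float("nan")
    out = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "betweenness": pd.Series(btw),
            "closeness": pd.Series(cls),
            "neighborhood_connectivity": pd.Series(nbr),
            "avg_shortest_path": pd.Series(asp),
        }
    )
    return out.loc[list(g.nodes)]


def node_role_table(
    g: nx.Graph,
    partition: dict,
    include_env: bool = False,
) -> pd.DataFrame:
    """Full per-node table: module, Zi, Pi, role, and centralities.

    Environment nodes are excluded from the role statistics by default
    (roles describe microbes); set ``include_env`` to keep them.
    """
    nodes = list(g.nodes)
    if not include_env:
        nodes = [v for v in nodes if g.nodes[v].get("kind", "asv") != "environment"]
    sub_z = zi(g, partition)
    sub_p = pi(g, partition)
    cent = node_centralities(g)
    df = pd.DataFrame(
        {
            "module": pd.Series({v: partition[v] for v in g.nodes}),
            "zi": sub_z,
            "pi": sub_p,
        }
    ).join(cent)
    df["role"] = [classify_role(z, p) for z, p in zip(df["zi"], df["pi"])]
    df["category"] = [g.nodes[v].get("category", "") for v in df.index]
    return df.loc[nodes]


def significance_stars(p: float) -> str:
    """Caption-style bins: *** p<0.001, ** 0.001<=p<0.01, * 0.01<=p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_by_category(
    metrics: pd.DataFrame,
    categories: pd.Series,
    test: str = "mannwhitney",
    min_group: int = 3,
) -> pd.DataFrame:
    """Pairwise two-sided tests of each metric between niche categories.

    Returns one row per (metric, category pair) with the test statistic,
    p-value, and significance stars. Categories with fewer than
    ``min_group`` nodes are skipped with a warning.
    """
    cats = categories.loc[metrics.index]
    groups = {c: metrics.index[cats == c] for c in cats.unique() if c}
    usable = {}
    for c, ids in groups.items():
        if len(ids) < min_group:
            warnings.warn(f"category {c!r} has fewer than {min_group} nodes; skipped")
        else:
            usable[c] = ids
    if len(usable) < 2:
        raise ValueError("need at least 2 categories with enough nodes")
    rows = []
    for metric in metrics.columns:
        for a, b in combinations(sorted(usable), 2):
            x = metrics.loc[usable[a], metric].dropna()
            y = metrics.loc[usable[b], metric].dropna()
            if test == "mannwhitney":
                stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            elif test == "ttest":
                stat, p = stats.ttest_ind(x, y, equal_var=False)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "statistic": float(stat),
                    "p": float(p),
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
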