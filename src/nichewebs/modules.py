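"""Module-level analyses: major modules, distribution patterns, Ward
dendrograms, environmental correlations, inter-module connectivity, and
environment subnetworks.

A module's distribution pattern is the per-sample average of its member
ASVs' feature-scaled relative abundances (min-max scaling per ASV across
samples), which puts modules of very different absolute abundance on a
common [0, 1] footing before comparing them across the gradient.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .network import CoNetwork, spearman_all_pairs
from .tables import FeatureTable, SampleMetadata

__all__ = [
    "major_modules",
    "feature_scale",
    "module_pattern",
    "module_patterns",
    "ward_cluster",
    "linkage_to_newick",
    "module_env_correlation",
    "intermodule_edges",
    "within_density",
    "between_density",
    "format_pct",
    "env_subnetwork",
]


def major_modules(
    partition: dict,
    min_fraction: float = 0.02,
    min_size: int = 5,
) -> tuple[dict, float]:
    """Flag modules whose size is >= max(min_size, min_fraction * n_nodes).

    Returns (module -> bool flags, fraction of nodes covered by majors).
    """
    if not partition:
        raise ValueError("empty partition")
    sizes = pd.Series(list(partition.values())).value_counts()
    n = len(partition)
    cutoff = max(min_size, min_fraction * n)
    flags = {m: bool(s >= cutoff) for m, s in sizes.items()}
    covered = sum(s for m, s in sizes.items() if flags[m])
    return flags, covered / n


def feature_scale(x) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to zeros (warned)."""
    arr = np.asarray(x, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("constant vector under feature scaling; returning zeros")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def module_pattern(table: FeatureTable, members) -> pd.Series:
    """Per-sample mean of the members' feature-scaled relative abundances."""
    members = [m for m in members]
    if not members:
        raise ValueError("module has no ASV members")
    rel = table.relative_abundance().loc[members]
    scaled = np.vstack([feature_scale(row) for row in rel.to_numpy()])
    return pd.Series(scaled.mean(axis=0), index=rel.columns)


def module_patterns(
    table: FeatureTable,
    partition: dict,
    graph: nx.Graph | None = None,
    major_only: bool = True,
    min_fraction: float = 0.02,
    min_size: int = 5,
) -> pd.DataFrame:
    """Distribution patterns (modules x samples) for (major) modules.

    Environment nodes never contribute to patterns; members are matched to
    the feature table's ASV ids. ``graph`` (when given) supplies node kinds.
    """
    env = set()
    if graph is not None:
        env = {v for v, d in graph.nodes(data=True) if d.get("kind") == "environment"}
    asv_ids = set(table.asv_ids)
    members_by_mod: dict = {}
    for v, m in partition.items():
        if v in env or v not in asv_ids:
            continue
        members_by_mod.setdefault(m, []).append(v)
    mods = sorted(members_by_mod)
    if major_only:
        flags, _ = major_modules(partition, min_fraction, min_size)
        mods = [m for m in mods if flags.get(m, False)]
    rows = {m: module_pattern(table, members_by_mod[m]) for m in mods
            if members_by_mod.get(m)}
    return pd.DataFrame(rows).T


def ward_cluster(patterns: pd.DataFrame, variant: str = "ward.D2") -> np.ndarray:
    """Ward dendrogram over module patterns (rows = modules).

    ``ward.D2`` (default) is the squared-Euclidean Ward criterion on
    Euclidean distances (scipy's 'ward'); ``ward.D`` applies the classic
    Lance-Williams Ward update directly to the unsquared distances.
    Returns a scipy linkage matrix with nondecreasing merge heights.
    """
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns to cluster")
    if variant == "ward.D2":
        return linkage(patterns.to_numpy(dtype=float), method="ward")
    if variant == "ward.D":
        d = squareform(pdist(patterns.to_numpy(dtype=float)))
        return _lance_williams_ward(d)
    raise ValueError(f"unknown Ward variant {variant!r}")


def _lance_williams_ward(d: np.ndarray) -> np.ndarray:
    """Naive agglomeration with the Ward Lance-Williams update on d as given."""
    n = d.shape[0]
    d = d.astype(float).copy()
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    labels = {i: i for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = []
    next_id = n
    for step in range(n - 1):
        best = min(dist, key=lambda pr: (dist[pr], tuple(sorted(pr))))
        i, j = sorted(best)
        h = dist[best]
        ni, nj = sizes[i], sizes[j]
        Z.append([labels[i], labels[j], h, ni + nj])
        # Lance-Williams Ward update against every other active cluster k
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dij = h
            tot = ni + nj + nk
            new[k] = ((ni + nk) / tot * dik + (nj + nk) / tot * djk - nk / tot * dij)
        active.remove(j)
        for pair in list(dist):
            if i in pair or j in pair:
                del dist[pair]
        sizes[i] = ni + nj
        labels[i] = next_id
        next_id += 1
        for k, v in new.items():
            dist[frozenset((i, k))] = v
    return np.array(Z, dtype=float)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    labels = list(labels)
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nid = n + idx
        nodes[nid] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[nid] = h
    return nodes[n + len(Z) - 1] + ";"


def module_env_correlation(
    patterns: pd.DataFrame,
    metadata: SampleMetadata,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (and p) between module patterns and each covariate.

    Rows are modules, columns covariates; samples are matched by id and
    covariates absent from the metadata are skipped with a warning.
    """
    cov = metadata.covariates
    shared = patterns.columns.intersection(cov.index)
    if len(shared) == 0:
        raise ValueError("no shared sample ids between patterns and metadata")
    block = pd.concat(
        [patterns[shared], cov.loc[shared].T], axis=0
    )
    res = spearman_all_pairs(block)
    mods = patterns.index
    covs = cov.columns
    return res.rho.loc[mods, covs], res.p.loc[mods, covs]


def within_density(n_edges: int, n_nodes: int) -> float:
    """Internal edge density e_s / (n_s (n_s - 1) / 2)."""
    possible = n_nodes * (n_nodes - 1) / 2.0
    return n_edges / possible if possible > 0 else float("nan")


def between_density(n_edges: int, n_s: int, n_t: int) -> float:
    """Cross-module edge density e_st / (n_s * n_t)."""
    possible = n_s * n_t
    return n_edges / possible if possible > 0 else float("nan")


def format_pct(x: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero (display convention)."""
    scale = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * 100.0 * scale + 0.5) / scale)


def intermodule_edges(
    g: nx.Graph,
    partition: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Edge counts, densities, and display percentages between module pairs.

    Diagonal entries are within-module counts/densities. The sum of all
    within- and between-module counts equals the total edge count.
    """
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:5]}")
    mods = sorted(set(partition[v] for v in g.nodes))
    sizes = {m: 0 for m in mods}
    for v in g.nodes:
        sizes[partition[v]] += 1
    counts = pd.DataFrame(0, index=mods, columns=mods)
    for u, v in g.edges:
        a, b = partition[u], partition[v]
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    dens = pd.DataFrame(np.nan, index=mods, columns=mods)
    for a in mods:
        for b in mods:
            if a == b:
                dens.loc[a, b] = within_density(counts.loc[a, a], sizes[a])
            else:
                dens.loc[a, b] = between_density(counts.loc[a, b], sizes[a], sizes[b])
    pct = dens.map(lambda x: format_pct(x) if np.isfinite(x) else np.nan)
    counts.attrs["sizes"] = sizes
    return counts, dens, pct


def env_subnetwork(
    net: CoNetwork,
    include_asv_asv: bool = False,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Subnetwork of environment nodes plus their directly linked ASVs.

    Environment nodes without edges are omitted with a warning. The
    composition table reports, per environment factor and niche category,
    the number of linked ASVs, the fraction of that factor's neighbors in
    the category, and the fraction of the whole category's network nodes
    linked to the factor. ASV-ASV edges among the selected neighbors are
    excluded unless ``include_asv_asv``.
    """
    g = net.graph
    env = net.env_nodes()
    if not env:
        raise ValueError("network contains no environment nodes")
    keep_env = []
    for e in env:
        if g.degree(e) == 0:
            warnings.warn(f"environment node {e!r} has no edges; omitted")
        else:
            keep_env.append(e)
    nodes = set(keep_env)
    for e in keep_env:
        nodes.update(g.neighbors(e))
    sub = g.subgraph(nodes).copy()
    if not include_asv_asv:
        drop = [
            (u, v)
            for u, v in sub.edges
            if sub.nodes[u].get("kind") != "environment"
            and sub.nodes[v].get("kind") != "environment"
        ]
        sub.remove_edges_from(drop)

    cat_totals: dict = {}
    for v in net.asv_nodes():
        c = g.nodes[v].get("category", "")
        cat_totals[c] = cat_totals.get(c, 0) + 1
    rows = []
    for e in keep_env:
        nbrs = [v for v in g.neighbors(e) if g.nodes[v].get("kind") != "environment"]
        if not nbrs:
            continue
        by_cat: dict = {}
        for v in nbrs:
            c = g.nodes[v].get("category", "")
            by_cat[c] = by_cat.get(c, 0) + 1
        for c, k in sorted(by_cat.items()):
            rows.append(
                {
                    "environment": e,
                    "category": c,
                    "n_linked": k,
                    "fraction_of_neighbors": k / len(nbrs),
                    "fraction_of_category": k / cat_totals[c] if cat_totals.get(c) else np.nan,
                }
            )
    comp = pd.DataFrame(
        rows,
        columns=["environment", "category", "n_linked", "fraction_of_neighbors",
                 "fraction_of_category"],
    )
    return sub, comp
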