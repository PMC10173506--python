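"""Whole-network topology, Erdős–Rényi nulls, small-worldness, Louvain modules.

Observed metrics follow the Cytoscape NetworkAnalyzer conventions:
density 2m/n(n-1); mean degree 2m/n; clustering averaged over all nodes
with degree-<2 nodes contributing 0; characteristic path length L and
diameter over connected pairs only; heterogeneity sqrt(var(k))/mean(k);
centralization (n/(n-2)) * (max(k)/(n-1) - density).

The null model is G(n, m) — uniform over simple graphs with exactly the
observed node and edge counts — and the small-world coefficient is
SW = (C/C_R) / (L/L_R) with R the null means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "TopologySummary",
    "global_topology",
    "er_null",
    "small_world",
    "louvain",
    "modularity_q",
    "summarize_with_null",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    diameter: float
    average_neighbors: float
    density: float
    heterogeneity: float
    centralization: float
    modularity: float | None = None
    clustering: float = 0.0
    path_length: float = float("nan")
    null: dict = field(default_factory=dict)       # null means per metric
    null_se: dict = field(default_factory=dict)    # standard errors
    ratios: dict = field(default_factory=dict)     # C/C_R, L/L_R
    small_world: float | None = None

    def as_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "diameter": self.diameter,
            "average_neighbors": self.average_neighbors,
            "density": self.density,
            "heterogeneity": self.heterogeneity,
            "centralization": self.centralization,
            "modularity": self.modularity,
            "clustering": self.clustering,
            "path_length": self.path_length,
            "small_world": self.small_world,
        }
        d.update({f"{k}_null": v for k, v in self.null.items()})
        d.update({f"{k}_ratio": v for k, v in self.ratios.items()})
        return d


def _path_stats(g: nx.Graph, largest_component_only: bool = False) -> tuple[float, float]:
    """(mean shortest path, diameter) over connected node pairs."""
    if largest_component_only:
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp)
    total = 0
    pairs = 0
    diam = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dd in nx.all_pairs_shortest_path_length(sub):
            for d in dd.values():
                if d > 0:
                    total += d
                    pairs += 1
                    if d > diam:
                        diam = d
    if pairs == 0:
        return float("nan"), 0.0
    return total / pairs, float(diam)


def global_topology(g: nx.Graph, largest_component_only: bool = False) -> TopologySummary:
    """Observed topology of a simple undirected graph (>= 2 nodes)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m = g.number_of_edges()
    k = np.array([d for _, d in g.degree()], dtype=float)
    density = 2.0 * m / (n * (n - 1))
    mean_k = k.mean()
    heterogeneity = float(np.sqrt(k.var()) / mean_k) if mean_k > 0 else float("nan")
    centralization = (
        (n / (n - 2.0)) * (k.max() / (n - 1.0) - density) if n > 2 else float("nan")
    )
    clustering = float(np.mean(list(nx.clustering(g).values())))
    L, diam = _path_stats(g, largest_component_only)
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        diameter=diam,
        average_neighbors=float(mean_k),
        density=float(density),
        heterogeneity=heterogeneity,
        centralization=float(centralization),
        clustering=clustering,
        path_length=L,
    )


class LouvainResult(NamedTuple):
    partition: dict
    q: float


def louvain(g: nx.Graph, seed: int = 0, resolution: float = 1.0) -> LouvainResult:
    """Louvain community detection; deterministic under a fixed seed.

    Returns a node->module mapping (module ids 0..k-1, numbered by each
    community's smallest node label for reproducibility) and the achieved
    Newman modularity Q.
    """
    if g.number_of_edges() < 1:
        raise ValueError("Louvain requires at least one edge")
    comms = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: min(map(str, c)))
    partition = {v: i for i, c in enumerate(comms) for v in c}
    return LouvainResult(partition, modularity_q(g, partition))


def modularity_q(g: nx.Graph, partition: dict, resolution: float = 1.0) -> float:
    """Newman modularity Q = sum_s (e_s/m - (d_s/2m)^2) for a hard partition."""
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:5]}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    e = {}  # within-module edge counts
    d = {}  # module total degrees
    for v, k in g.degree():
        d[partition[v]] = d.get(partition[v], 0) + k
    for u, v in g.edges:
        if partition[u] == partition[v]:
            e[partition[u]] = e.get(partition[u], 0) + 1
    q = 0.0
    for s, ds in d.items():
        q += e.get(s, 0) / m - resolution * (ds / (2.0 * m)) ** 2
    return q


def small_world(C: float, C_R: float, L: float, L_R: float) -> float:
    """SW = (C/C_R)/(L/L_R); all inputs must be positive."""
    for name, v in (("C", C), ("C_R", C_R), ("L", L), ("L_R", L_R)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (C / C_R) / (L / L_R)


NULL_METRICS = ("clustering", "path_length", "heterogeneity", "centralization", "modularity")


def er_null(
    n: int,
    m: int,
    reps: int = 100,
    seed=None,
    resolution: float = 1.0,
) -> tuple[dict, dict]:
    """Null means (and SEs) of topology metrics over G(n, m) replicates.

    Every replicate has exactly ``m`` edges. Louvain (seeded from the same
    stream) supplies each replicate's modularity.
    """
    if m > n * (n - 1) // 2:
        raise ValueError("m exceeds the number of possible edges")
    rng = np.random.default_rng(seed)
    acc = {k: [] for k in NULL_METRICS}
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        summ = global_topology(g)
        acc["clustering"].append(summ.clustering)
        acc["path_length"].append(summ.path_length)
        acc["heterogeneity"].append(summ.heterogeneity)
        acc["centralization"].append(summ.centralization)
        if m >= 1:
            part = louvain(g, seed=int(rng.integers(2**31)), resolution=resolution)
            acc["modularity"].append(part.q)
        else:
            acc["modularity"].append(0.0)
    means = {k: float(np.nanmean(v)) for k, v in acc.items()}
    ses = {
        k: float(np.nanstd(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for k, v in acc.items()
    }
    return means, ses


def summarize_with_null(
    g: nx.Graph,
    reps: int = 100,
    seed=None,
    resolution: float = 1.0,
    partition: dict | None = None,
) -> TopologySummary:
    """Observed topology plus G(n,m) null means, ratios, and SW.

    ``partition`` (e.g. from :func:`louvain`) supplies the observed
    modularity; when omitted, Louvain is run internally.
    """
    summ = global_topology(g)
    if partition is None and g.number_of_edges() >= 1:
        partition = louvain(g, seed=0 if seed is None else int(seed)).partition
    if partition is not None:
        summ.modularity = modularity_q(g, partition)
    null_means, null_ses = er_null(summ.n_nodes, summ.n_edges, reps=reps, seed=seed,
                                   resolution=resolution)
    summ.null = null_means
    summ.null_se = null_ses
    if null_means["clustering"] > 0 and summ.clustering > 0:
        summ.ratios["clustering"] = summ.clustering / null_means["clustering"]
    if null_means["path_length"] > 0 and np.isfinite(summ.path_length):
        summ.ratios["path_length"] = summ.path_length / null_means["path_length"]
    if "clustering" in summ.ratios and "path_length" in summ.ratios:
        summ.small_world = small_world(
            summ.clustering, null_means["clustering"], summ.path_length,
            null_means["path_length"],
        )
    return summ
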