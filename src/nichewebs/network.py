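"""Spearman co-occurrence networks with BH-FDR edge filtering.

Edges connect ASVs (and optionally environmental covariates) whose
abundance profiles across samples show a strong, significant positive
Spearman rank correlation. The default retention rule keeps an edge iff

    rho > 0.5  and  p < 0.001  and  q < 0.001      (strict inequalities)

where p comes from the t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
n-2 degrees of freedom and q is the Benjamini-Hochberg FDR over all tested
pairs (ASV-ASV, ASV-environment, and environment-environment treated as
one family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

__all__ = [
    "network_input_filter",
    "spearman_all_pairs",
    "bh_fdr",
    "qvalues_matrix",
    "build_network",
    "CoNetwork",
    "SpearmanResult",
]


def network_input_filter(
    table: FeatureTable,
    min_prevalence: int = 25,
    min_max_rel_abund: float = 5e-4,
) -> pd.Series:
    """Boolean mask of ASVs admissible as network nodes.

    Keeps ASVs observed in at least ``min_prevalence`` samples AND whose
    relative abundance exceeds ``min_max_rel_abund`` (0.05%) in at least
    one sample (strict >).
    """
    if table.n_asvs == 0:
        return pd.Series(dtype=bool)
    rel = table.relative_abundance()
    return (table.prevalence() >= min_prevalence) & (rel.max(axis=1) > min_max_rel_abund)


class SpearmanResult(NamedTuple):
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def _spearman_complete(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and t-approximation p for a complete (no-NaN) variables x samples block."""
    n = vals.shape[1]
    ranks = stats.rankdata(vals, axis=1)  # midranks for ties
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    # zero-variance variables have undefined correlations
    const = sd == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    p = _p_from_rho(rho, n)
    return rho, p


def _p_from_rho(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the t approximation; |rho| = 1 gives p = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    if np.ndim(p):
        np.fill_diagonal(p, 0.0)
    return p


def spearman_all_pairs(X: pd.DataFrame, min_n: int = 10) -> SpearmanResult:
    """All-pairs Spearman rho and p for a variables x samples DataFrame.

    Missing values are handled by pairwise-complete observations with the
    per-pair sample size recorded; pairs with fewer than ``min_n`` complete
    observations are not tested (NaN). Needs at least 4 samples.
    """
    vals = X.to_numpy(dtype=float)
    m, n = vals.shape
    if n < 4:
        raise ValueError("need at least 4 samples for Spearman correlation")
    if not np.isnan(vals).any():
        rho, p = _spearman_complete(vals)
        n_mat = np.full((m, m), n)
    else:
        rho = np.full((m, m), np.nan)
        p = np.full((m, m), np.nan)
        n_mat = np.zeros((m, m), dtype=int)
        for i in range(m):
            rho[i, i], p[i, i] = 1.0, 0.0
            n_mat[i, i] = int(np.sum(~np.isnan(vals[i])))
            for j in range(i + 1, m):
                mask = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
                nij = int(mask.sum())
                n_mat[i, j] = n_mat[j, i] = nij
                if nij < max(min_n, 4):
                    continue
                ri = stats.rankdata(vals[i, mask])
                rj = stats.rankdata(vals[j, mask])
                if ri.std() == 0 or rj.std() == 0:
                    continue
                r = float(np.clip(np.corrcoef(ri, rj)[0, 1], -1, 1))
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = float(_p_from_rho(np.array(r), nij))
    idx = X.index
    return SpearmanResult(
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n_mat, index=idx, columns=idx),
    )


def bh_fdr(p_values):
    """Benjamini-Hochberg q-values, preserving input order; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def qvalues_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH correction over the upper triangle of a symmetric p matrix
    (one family covering every tested pair), symmetrized back."""
    arr = p.to_numpy(dtype=float)
    iu = np.triu_indices(arr.shape[0], k=1)
    q_flat = bh_fdr(arr[iu])
    q = np.zeros_like(arr)
    q[iu] = q_flat
    q = q + q.T
    np.fill_diagonal(q, 0.0)
    return pd.DataFrame(q, index=p.index, columns=p.columns)


@dataclass
class CoNetwork:
    """Undirected co-occurrence graph over ASV and environment nodes.

    Node attributes: ``kind`` ('asv' or 'environment'), ``category``
    (niche category), ``taxonomy``. Edge attributes: ``rho``, ``p``, ``q``,
    ``env_env`` flag. ``provenance`` records the thresholds used.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def asv_nodes(self) -> list:
        return [v for v, d in self.graph.nodes(data=True) if d.get("kind") == "asv"]

    def env_nodes(self) -> list:
        return [v for v, d in self.graph.nodes(data=True) if d.get("kind") == "environment"]

    def asv_subgraph(self) -> nx.Graph:
        return self.graph.subgraph(self.asv_nodes()).copy()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "q": d["q"],
             "env_env": d.get("env_env", False)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q", "env_env"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": v, "kind": d.get("kind", "asv"), "category": d.get("category", ""),
             "taxonomy": d.get("taxonomy", ""), "module": d.get("module", "")}
            for v, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["id", "kind", "category", "taxonomy", "module"])

    def write_graphml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        g = self.graph.copy()
        g.graph.update({k: str(v) for k, v in self.provenance.items()})
        nx.write_graphml(g, path)

    def write_tables(self, edges_path, nodes_path) -> None:
        Path(edges_path).parent.mkdir(parents=True, exist_ok=True)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)
        self.node_table().to_csv(nodes_path, sep="\t", index=False)


def _check_symmetric(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} matrix is not square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError(f"{name} matrix is not symmetric")


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    q: pd.DataFrame,
    node_meta: pd.DataFrame | None = None,
    rho_min: float = 0.5,
    alpha: float = 0.001,
    positive_only: bool = True,
    include_env: bool = True,
    drop_isolated: bool = True,
) -> CoNetwork:
    """Assemble the co-occurrence graph from correlation/significance matrices.

    ``node_meta`` is indexed by node id with optional columns ``kind``
    (default 'asv'), ``category``, ``taxonomy``. An edge is retained iff
    rho > rho_min (or |rho| > rho_min when ``positive_only`` is off) and
    both p and q are < alpha, all strict. Environment-environment edges
    are kept but flagged ``env_env``. Isolated nodes are dropped from the
    exported graph by default.
    """
    for name, df in (("rho", rho), ("p", p), ("q", q)):
        _check_symmetric(df, name)
    ids = list(rho.index)
    meta = node_meta if node_meta is not None else pd.DataFrame(index=pd.Index(ids))
    kind = {v: (meta.loc[v, "kind"] if "kind" in meta.columns and v in meta.index else "asv")
            for v in ids}
    if not include_env:
        ids = [v for v in ids if kind[v] != "environment"]

    g = nx.Graph()
    for v in ids:
        attrs = {"kind": kind[v]}
        if v in meta.index:
            for c in ("category", "taxonomy"):
                if c in meta.columns:
                    attrs[c] = meta.loc[v, c]
        g.add_node(v, **attrs)

    r_arr = rho.loc[ids, ids].to_numpy(dtype=float)
    p_arr = p.loc[ids, ids].to_numpy(dtype=float)
    q_arr = q.loc[ids, ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        strength = r_arr if positive_only else np.abs(r_arr)
        keep = (strength > rho_min) & (p_arr < alpha) & (q_arr < alpha)
    keep &= ~np.isnan(r_arr)
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu[keep[iu, ju]], ju[keep[iu, ju]]):
        u, v = ids[i], ids[j]
        g.add_edge(
            u, v,
            rho=float(r_arr[i, j]), p=float(p_arr[i, j]), q=float(q_arr[i, j]),
            env_env=(kind[u] == "environment" and kind[v] == "environment"),
        )
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    prov = {
        "rho_min": rho_min,
        "alpha": alpha,
        "positive_only": positive_only,
        "include_env": include_env,
        "n_candidates": len(rho),
    }
    return CoNetwork(g, prov)
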