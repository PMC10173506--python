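"""End-to-end orchestration: simulate/load -> filter -> classify -> network
-> topology -> roles -> module patterns, with a JSON run manifest.

The study design builds four co-occurrence networks from the same filtered
ASV pool — one per niche category (generalist, common, specialist) plus a
total network — each including the environmental covariates as nodes.
`run_all` executes every stage in dependency order, writes all stage
outputs as TSV/GraphML under the output directory, and records per-stage
counts (ASVs surviving filters, category tallies, nodes, edges, modules,
hubs) in a manifest so each filtering step is auditable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tables import FeatureTable, SampleMetadata
from .niche import niche_profiles, category_summary, CATEGORIES
from .network import (
    network_input_filter,
    spearman_all_pairs,
    qvalues_matrix,
    build_network,
    CoNetwork,
)
from .topology import louvain, summarize_with_null
from .roles import node_role_table, compare_by_category
from .modules import (
    module_patterns,
    ward_cluster,
    linkage_to_newick,
    module_env_correlation,
    intermodule_edges,
    env_subnetwork,
    major_modules,
)
from .simulate import ScenarioConfig, generate

__all__ = ["RunConfig", "run_all", "report"]

NETWORKS = ("generalist", "common", "specialist", "total")


@dataclass
class RunConfig:
    """All stage parameters with the study's published values as defaults."""

    # input: either a simulation scenario or paths to TSV inputs
    scenario: ScenarioConfig | None = None
    feature_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    outdir: str = "nichewebs_out"
    seed: int = 1
    # stage parameters
    min_total_count: int = 4
    rarefy_depth: str | int = "min"
    min_mean_rel_abund: float = 2e-5
    min_prevalence: int = 25
    upper_b: float = 78.0
    lower_b: float = 22.0
    auto_thresholds: bool = True
    niche_use: str = "relative"
    min_max_rel_abund: float = 5e-4
    rho_min: float = 0.5
    alpha: float = 0.001
    positive_only: bool = True
    include_env: bool = True
    null_reps: int = 100
    resolution: float = 1.0
    major_min_fraction: float = 0.02
    major_min_size: int = 5
    write_outputs: bool = True

    def validate(self) -> None:
        if not self.lower_b < self.upper_b:
            raise ValueError("niche thresholds require lower_b < upper_b")
        if self.scenario is None and self.feature_table is None:
            raise ValueError("either a scenario or a feature_table path is required")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None:
            cfg.scenario = ScenarioConfig(**scenario)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class RunResult:
    """In-memory handles to every stage product plus the JSON manifest."""

    manifest: dict
    table: FeatureTable
    metadata: SampleMetadata
    profiles: pd.DataFrame
    networks: dict = field(default_factory=dict)      # name -> CoNetwork
    topologies: dict = field(default_factory=dict)    # name -> TopologySummary
    partitions: dict = field(default_factory=dict)    # name -> node -> module
    roles: pd.DataFrame | None = None
    patterns: pd.DataFrame | None = None
    ground_truth: object = None


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _build_one_network(table, meta_cov, ids, node_meta, cfg):
    X = pd.concat([table.relative_abundance().loc[ids], meta_cov.T]) \
        if cfg.include_env else table.relative_abundance().loc[ids]
    res = spearman_all_pairs(X)
    q = qvalues_matrix(res.p)
    return build_network(
        res.rho, res.p, q, node_meta,
        rho_min=cfg.rho_min, alpha=cfg.alpha,
        positive_only=cfg.positive_only, include_env=cfg.include_env,
    )


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage; identical config + seeds give identical outputs."""
    config.validate()
    outdir = Path(config.outdir)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outdir": str(outdir),
        "stages": {},
    }
    st = manifest["stages"]

    # -- stage: data ----------------------------------------------------
    truth = None
    if config.scenario is not None:
        table, metadata, truth = _stage("simulate")(generate)(config.scenario, seed=config.seed)
    else:
        table = _stage("load")(FeatureTable.read_tsv)(
            config.feature_table, taxonomy_path=config.taxonomy
        )
        metadata = (
            SampleMetadata.read_tsv(config.metadata) if config.metadata else
            SampleMetadata(pd.DataFrame(index=pd.Index(table.sample_ids, name="sample_id")))
        )
    st["input"] = {"n_asvs": table.n_asvs, "n_samples": table.n_samples}

    # -- stage: low-count filter + diversity ----------------------------
    table = _stage("filter_low_count")(table.filter_low_count)(config.min_total_count)
    st["filter_low_count"] = {"n_asvs": table.n_asvs, "min_total": config.min_total_count}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rare = _stage("rarefy")(table.rarefy)(config.rarefy_depth, seed=config.seed)
    div = rare.shannon()
    st["diversity"] = {
        "rarefaction_depth": int(rare.sample_totals().iloc[0]),
        "n_samples_retained": rare.n_samples,
        "shannon_mean": float(div.mean()),
        "shannon_sd": float(div.std(ddof=1)),
    }

    # -- stage: niche classification -------------------------------------
    profiles = _stage("niche")(niche_profiles)(
        table,
        use=config.niche_use,
        min_mean_rel_abund=config.min_mean_rel_abund,
        min_prevalence=config.min_prevalence,
        upper=config.upper_b,
        lower=config.lower_b,
        auto_thresholds=config.auto_thresholds,
    )
    summary = category_summary(profiles, table)
    st["niche"] = {
        "upper_b": float(profiles.attrs["upper"]),
        "lower_b": float(profiles.attrs["lower"]),
        "n_included": int(summary.attrs["n_included"]),
        "category_counts": {c: int(summary.loc[c, "n_asvs"]) for c in CATEGORIES},
    }

    # -- stage: networks --------------------------------------------------
    net_mask = network_input_filter(
        table, min_prevalence=config.min_prevalence, min_max_rel_abund=config.min_max_rel_abund
    )
    eligible = table.counts.index[net_mask & (profiles["category"] != "excluded")]
    st["network_input_filter"] = {"n_asvs": int(len(eligible))}
    meta_cov = metadata.covariates.loc[table.sample_ids] if len(metadata.covariates.columns) \
        else pd.DataFrame(index=pd.Index(table.sample_ids))

    tax_str = (
        table.taxonomy.apply(lambda r: ";".join(map(str, r)), axis=1)
        if table.taxonomy is not None
        else pd.Series("", index=table.counts.index)
    )
    networks, partitions, topologies = {}, {}, {}
    rng = np.random.default_rng(config.seed)
    for name in NETWORKS:
        ids = (
            eligible
            if name == "total"
            else eligible[profiles.loc[eligible, "category"] == name]
        )
        if len(ids) < 2:
            st.setdefault("networks", {})[name] = {"n_nodes": 0, "n_edges": 0, "skipped": True}
            continue
        node_meta = pd.DataFrame(
            {
                "kind": "asv",
                "category": profiles.loc[ids, "category"],
                "taxonomy": tax_str.loc[ids],
            },
            index=ids,
        )
        if config.include_env:
            env_meta = pd.DataFrame(
                {"kind": "environment", "category": "", "taxonomy": ""},
                index=meta_cov.columns,
            )
            node_meta = pd.concat([node_meta, env_meta])
        net = _stage(f"network[{name}]")(_build_one_network)(
            table, meta_cov, ids, node_meta, config
        )
        networks[name] = net
        sub_seed = int(rng.integers(2**31))
        if net.n_edges >= 1:
            part = louvain(net.graph, seed=sub_seed, resolution=config.resolution).partition
            partitions[name] = part
            for v, m in part.items():
                net.graph.nodes[v]["module"] = m
            topologies[name] = _stage(f"topology[{name}]")(summarize_with_null)(
                net.graph, reps=config.null_reps, seed=sub_seed,
                resolution=config.resolution, partition=part,
            )
        st.setdefault("networks", {})[name] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_env_nodes": len(net.env_nodes()),
            "n_modules": len(set(partitions.get(name, {}).values())),
        }
        if name in topologies:
            manifest.setdefault("topology", {})[name] = _jsonable(topologies[name].as_dict())

    # -- stage: node roles (total network) -------------------------------
    roles_df = None
    comparisons = None
    if "total" in partitions:
        roles_df = _stage("roles")(node_role_table)(
            networks["total"].graph, partitions["total"]
        )
        role_counts = roles_df["role"].value_counts().to_dict()
        hubs = roles_df[roles_df["role"].isin(["module_hub", "network_hub"])]
        st["roles"] = {
            "role_counts": {k: int(v) for k, v in role_counts.items()},
            "n_module_hubs": int((roles_df["role"] == "module_hub").sum()),
            "n_connectors": int((roles_df["role"] == "connector").sum()),
            "hub_share_pct": float(100.0 * len(hubs) / len(roles_df)) if len(roles_df) else 0.0,
        }
        cats_present = roles_df["category"].value_counts()
        if (cats_present >= 3).sum() >= 2:
            metrics = roles_df[
                ["zi", "pi", "degree", "betweenness", "closeness",
                 "neighborhood_connectivity", "avg_shortest_path"]
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comparisons = compare_by_category(metrics, roles_df["category"])

    # -- stage: module patterns (total network) ---------------------------
    patterns = None
    env_rho = env_p = None
    inter_counts = inter_pct = None
    newick = None
    if "total" in partitions:
        part = partitions["total"]
        patterns = _stage("module_patterns")(module_patterns)(
            table, part, graph=networks["total"].graph,
            min_fraction=config.major_min_fraction, min_size=config.major_min_size,
        )
        flags, coverage = major_modules(
            part, config.major_min_fraction, config.major_min_size
        )
        st["modules"] = {
            "n_modules": len(flags),
            "n_major": int(sum(flags.values())),
            "major_coverage": float(coverage),
        }
        if len(patterns) >= 2:
            Z = ward_cluster(patterns)
            newick = linkage_to_newick(Z, [f"M{m}" for m in patterns.index])
        if len(meta_cov.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                env_rho, env_p = module_env_correlation(patterns, metadata)
        inter_counts, _, inter_pct = intermodule_edges(networks["total"].graph, part)
        st["modules"]["intermodule_edge_total"] = int(
            np.triu(inter_counts.to_numpy()).sum()
        )

    # -- outputs ----------------------------------------------------------
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        table.write_tsv(outdir / "feature_table.tsv", outdir / "taxonomy.tsv")
        metadata.write_tsv(outdir / "metadata.tsv")
        if truth is not None:
            truth.write_tsv(outdir / "ground_truth.tsv")
        prof_out = profiles.copy()
        prof_out.index.name = "asv_id"
        prof_out.to_csv(outdir / "niche_profiles.tsv", sep="\t")
        div.to_csv(outdir / "shannon.tsv", sep="\t")
        topo_rows = []
        for name, topo in topologies.items():
            row = {"network": name}
            row.update(_jsonable(topo.as_dict()))
            topo_rows.append(row)
        if topo_rows:
            pd.DataFrame(topo_rows).to_csv(outdir / "topology.tsv", sep="\t", index=False)
        for name, net in networks.items():
            net.write_graphml(outdir / f"network_{name}.graphml")
            net.write_tables(outdir / f"edges_{name}.tsv", outdir / f"nodes_{name}.tsv")
        if roles_df is not None:
            out = roles_df.copy()
            out.index.name = "node_id"
            out.to_csv(outdir / "node_roles.tsv", sep="\t")
            pd.crosstab(roles_df["category"], roles_df["role"]).to_csv(
                outdir / "role_summary.tsv", sep="\t"
            )
        if comparisons is not None:
            comparisons.to_csv(outdir / "category_comparisons.tsv", sep="\t", index=False)
        if patterns is not None and len(patterns):
            out = patterns.copy()
            out.index = [f"M{m}" for m in out.index]
            out.index.name = "module"
            out.to_csv(outdir / "module_patterns.tsv", sep="\t")
        if env_rho is not None:
            env_rho.to_csv(outdir / "module_env_rho.tsv", sep="\t")
            env_p.to_csv(outdir / "module_env_p.tsv", sep="\t")
        if inter_counts is not None:
            inter_counts.to_csv(outdir / "intermodule_edges.tsv", sep="\t")
            inter_pct.to_csv(outdir / "intermodule_density_pct.tsv", sep="\t")
        if newick is not None:
            (outdir / "module_dendrogram.nwk").write_text(newick + "\n")
        if "total" in networks and networks["total"].env_nodes():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub, comp = env_subnetwork(networks["total"])
            CoNetwork(sub).write_graphml(outdir / "env_subnetwork.graphml")
            comp.to_csv(outdir / "env_subnetwork_composition.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)

    result = RunResult(
        manifest=_jsonable(manifest),
        table=table,
        metadata=metadata,
        profiles=profiles,
        networks=networks,
        topologies=topologies,
        partitions=partitions,
        roles=roles_df,
        patterns=patterns,
    )
    result.ground_truth = truth
    return result


def report(manifest: dict) -> str:
    """Human-readable run summary: category counts, one topology block per
    network, role counts, and major-module coverage."""
    st = manifest.get("stages", {})
    lines = [
        f"nichewebs {manifest.get('package_version', '?')} run "
        f"(seed {manifest.get('seed')}, config {manifest.get('config_hash', '')[:8]})",
        "",
    ]
    if "input" in st:
        lines.append(
            f"input: {st['input']['n_asvs']} ASVs x {st['input']['n_samples']} samples"
        )
    if "filter_low_count" in st:
        lines.append(
            f"after low-count filter (total >= {st['filter_low_count']['min_total']}): "
            f"{st['filter_low_count']['n_asvs']} ASVs"
        )
    if "niche" in st:
        n = st["niche"]
        lines.append(
            f"niche classification (B cutoffs {n['lower_b']:.1f}/{n['upper_b']:.1f}): "
            f"{n['n_included']} included"
        )
        for c in CATEGORIES:
            cnt = n["category_counts"].get(c, 0)
            flag = "  [empty]" if cnt == 0 else ""
            lines.append(f"  {c:<11} {cnt}{flag}")
    lines.append("")
    lines.append(f"{'network':<11} {'nodes':>6} {'edges':>7} {'C':>6} {'L':>6} {'SW':>7} {'Q':>6}")
    nets = st.get("networks", {})
    topo = manifest.get("topology", {})
    for name in NETWORKS:
        if name not in nets:
            continue
        row = nets[name]
        t = topo.get(name, {})

        def _fmt(x, w=6):
            return f"{x:>{w}.2f}" if isinstance(x, (int, float)) and x is not None else " " * (w - 1) + "-"

        lines.append(
            f"{name:<11} {row['n_nodes']:>6} {row['n_edges']:>7} "
            f"{_fmt(t.get('clustering'))} {_fmt(t.get('path_length'))} "
            f"{_fmt(t.get('small_world'), 7)} {_fmt(t.get('modularity'))}"
        )
    if "roles" in st:
        r = st["roles"]
        lines.append("")
        lines.append(
            f"roles: {r['n_module_hubs']} module hubs, {r['n_connectors']} connectors "
            f"({r['hub_share_pct']:.1f}% hubs of nodes)"
        )
    if "modules" in st:
        m = st["modules"]
        lines.append(
            f"modules: {m['n_major']} major of {m['n_modules']} "
            f"(coverage {100 * m['major_coverage']:.0f}% of nodes)"
        )
    return "\n".join(lines)
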