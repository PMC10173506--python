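"""Synthetic elevation-gradient communities with known ground truth.

The generator emulates a three-belt elevation survey (75 samples per belt
by default, 225 total) with ~15 environmental covariates that vary
linearly with elevation plus noise, a latent vegetation variable driven by
elevation and moisture and indicated by vascular-plant and cryptogam
cover, and an ASV pool split into habitat generalists, common taxa, and
specialists.

Expected abundance of ASV j in sample i is

    mu_ij ∝ exp( baseline_j  - (e_i - c_j)^2 / (2 w_j^2)  + lambda_j F_{m(j),i}
                 + cascade terms )

i.e. a log-linear model with a Gaussian niche response along elevation
(broad width for generalists, narrow for specialists), a shared per-module
latent factor F that plants co-occurrence blocks, and a causal cascade
vegetation -> generalists -> common taxa -> specialists. Counts are drawn
from a negative binomial at a lognormal sequencing depth; compositional
normalization makes relative abundances sum to one in expectation.

Every random draw flows from a single seed, so a fixed configuration
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata

__all__ = ["ScenarioConfig", "GroundTruth", "generate", "planted_partition_graph"]


# covariate = intercept + slope * z(elevation) + Normal(0, sd), clipped to [lo, hi].
# Directions follow the field pattern the design emulates: moisture, vascular
# cover, C/N and litter decrease with elevation; temperature, cryptogam and
# rock cover, respiration increase; pH is flat.
DEFAULT_COVARIATES: dict[str, tuple[float, float, float, float, float]] = {
    # name: (intercept, slope, noise sd, lo, hi)
    "soil_temperature": (13.6, 2.2, 0.9, -5.0, 40.0),
    "moisture": (38.0, -12.0, 5.0, 0.0, 100.0),
    "pH": (5.1, 0.0, 0.3, 2.0, 10.0),
    "EC": (60.0, -8.0, 10.0, 0.0, np.inf),
    "C": (8.0, -2.0, 1.5, 0.0, np.inf),
    "N": (0.6, -0.12, 0.1, 0.0, np.inf),
    "CN_ratio": (13.1, -2.0, 1.5, 1.0, np.inf),
    "litter_depth": (3.0, -1.2, 0.8, 0.0, np.inf),
    "rock_cover": (25.0, 15.0, 8.0, 0.0, 100.0),
    "dry_wet_ratio": (0.55, 0.10, 0.05, 0.05, 1.0),
    "respiration": (2.0, 0.5, 0.4, 0.0, np.inf),
}


@dataclass
class ScenarioConfig:
    """Defaults define the study conditions the analysis pipeline assumes."""

    n_samples: int = 225
    # (name, mean elevation m, sd m) per belt; samples split as evenly as possible
    strata: tuple = (("low", 162.0, 43.0), ("mid", 251.0, 21.0), ("high", 302.0, 39.0))
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    # latent vegetation = veg_elev*(-z_elev) + veg_moist*z_moisture + noise
    veg_elev: float = 0.8
    veg_moist: float = 0.3
    veg_noise: float = 0.3
    # indicators of the vegetation latent
    vascular_intercept: float = 45.0
    vascular_loading: float = 22.0
    vascular_noise: float = 6.0
    cryptogam_intercept: float = 30.0
    cryptogam_loading: float = -12.0
    cryptogam_noise: float = 6.0
    # ASV pool
    n_generalist: int = 40
    n_common: int = 130
    n_specialist: int = 50
    niche_width: dict = field(
        default_factory=lambda: {"generalist": 1000.0, "common": 60.0, "specialist": 14.0}
    )
    baseline_log_mean: dict = field(
        default_factory=lambda: {"generalist": 4.4, "common": 2.8, "specialist": 4.2}
    )
    baseline_log_sd: float = 0.4
    module_loading: dict = field(
        default_factory=lambda: {"generalist": 0.2, "common": 1.1, "specialist": 1.1}
    )
    # causal cascade strengths (log scale per latent sd)
    beta_veg_generalist: float = 0.3
    beta_generalist_common: float = 0.3
    beta_common_specialist: float = 0.3
    # planted modules per category
    modules_per_category: dict = field(
        default_factory=lambda: {"generalist": 1, "common": 2, "specialist": 3}
    )
    common_centers: tuple = (215.0, 270.0)
    center_jitter: float = 8.0
    # sequencing depth and overdispersion
    depth_mean: float = 20000.0
    depth_log_sd: float = 0.25
    nb_size: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for cat in ("generalist", "common", "specialist"):
            n = getattr(self, f"n_{cat}")
            if n < 0:
                raise ValueError(f"n_{cat} must be >= 0")
            if self.niche_width[cat] <= 0:
                raise ValueError("niche widths must be positive")
        if self.depth_mean <= 0 or self.nb_size <= 0:
            raise ValueError("depth_mean and nb_size must be positive")

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth for recovery tests: per-ASV labels and per-sample latents."""

    asv: pd.DataFrame          # category, module, center, width, baseline
    sample_latents: pd.DataFrame  # vegetation / generalist / common latents
    coefficients: dict

    def write_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out = self.asv.copy()
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")


_PHYLA = (
    "Proteobacteria", "Acidobacteriota", "Verrucomicrobiota", "Chloroflexi",
    "Actinobacteriota", "Planctomycetota", "Bacteroidota",
)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate(
    config: ScenarioConfig | None = None,
    seed: int | None = None,
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic community; ``seed`` overrides ``config.seed``."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # --- samples, elevation, covariates --------------------------------
    n = cfg.n_samples
    n_strata = len(cfg.strata)
    base, extra = divmod(n, n_strata)
    strata_labels, elev = [], []
    for k, (name, mu, sd) in enumerate(cfg.strata):
        size = base + (1 if k < extra else 0)
        strata_labels += [name] * size
        elev.append(rng.normal(mu, sd, size))
    elev = np.concatenate(elev)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    z_elev = _zscore(elev)

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["elevation"] = elev
    meta["stratum"] = strata_labels
    for name, (b0, b1, sd, lo, hi) in cfg.covariates.items():
        meta[name] = np.clip(b0 + b1 * z_elev + rng.normal(0, sd, n), lo, hi)

    z_moist = _zscore(meta["moisture"].to_numpy()) if "moisture" in meta else -z_elev
    veg = _zscore(
        cfg.veg_elev * (-z_elev) + cfg.veg_moist * z_moist + rng.normal(0, cfg.veg_noise, n)
    )
    meta["vascular_plant_cover"] = np.clip(
        cfg.vascular_intercept + cfg.vascular_loading * veg
        + rng.normal(0, cfg.vascular_noise, n), 0, 100,
    )
    meta["cryptogam_cover"] = np.clip(
        cfg.cryptogam_intercept + cfg.cryptogam_loading * veg
        + rng.normal(0, cfg.cryptogam_noise, n), 0, 100,
    )
    meta["altitude"] = elev + rng.normal(0, 2.0, n)

    # --- ASV pool ------------------------------------------------------
    cats = (
        ["generalist"] * cfg.n_generalist
        + ["common"] * cfg.n_common
        + ["specialist"] * cfg.n_specialist
    )
    n_asv = len(cats)
    if n_asv == 0:
        raise ValueError("no ASVs configured")
    asv_ids = [f"ASV{j + 1:04d}" for j in range(n_asv)]

    stratum_means = {name: mu for name, mu, _ in cfg.strata}
    spec_centers = [stratum_means[name] for name, _, _ in cfg.strata]
    centers_by_cat = {
        "generalist": [float(np.mean(elev))],
        "common": list(cfg.common_centers),
        "specialist": spec_centers,
    }

    module_id = np.zeros(n_asv, dtype=int)
    centers = np.zeros(n_asv)
    widths = np.zeros(n_asv)
    next_module = 0
    module_of: dict[str, list[int]] = {}
    for cat in ("generalist", "common", "specialist"):
        idx = [j for j, c in enumerate(cats) if c == cat]
        if not idx:
            continue
        k = max(1, int(cfg.modules_per_category.get(cat, 1)))
        mods = list(range(next_module, next_module + k))
        module_of[cat] = mods
        next_module += k
        cat_centers = centers_by_cat[cat]
        for pos, j in enumerate(idx):
            m = mods[pos % k]
            module_id[j] = m
            centers[j] = cat_centers[(m - mods[0]) % len(cat_centers)] + rng.normal(
                0, cfg.center_jitter
            )
            widths[j] = cfg.niche_width[cat]

    baseline = np.array(
        [rng.normal(cfg.baseline_log_mean[c], cfg.baseline_log_sd) for c in cats]
    )
    loading = np.array([cfg.module_loading[c] for c in cats])

    # per-module latent factors over samples
    factors = rng.normal(0, 1, (next_module, n))

    eta = np.empty((n_asv, n))
    cat_arr = np.array(cats)
    for j in range(n_asv):
        eta[j] = (
            baseline[j]
            - (elev - centers[j]) ** 2 / (2.0 * widths[j] ** 2)
            + loading[j] * factors[module_id[j]]
        )
    gen_mask = cat_arr == "generalist"
    com_mask = cat_arr == "common"
    spe_mask = cat_arr == "specialist"
    eta[gen_mask] += cfg.beta_veg_generalist * veg
    g_lat = _zscore(eta[gen_mask].mean(axis=0)) if gen_mask.any() else np.zeros(n)
    eta[com_mask] += cfg.beta_generalist_common * g_lat
    c_lat = _zscore(eta[com_mask].mean(axis=0)) if com_mask.any() else np.zeros(n)
    eta[spe_mask] += cfg.beta_common_specialist * c_lat

    # --- counts ----------------------------------------------------------
    w = np.exp(eta)
    p = w / w.sum(axis=0, keepdims=True)
    depth = rng.lognormal(np.log(cfg.depth_mean), cfg.depth_log_sd, n)
    mu = p * depth[None, :]
    nb_p = cfg.nb_size / (cfg.nb_size + mu)
    counts = rng.negative_binomial(cfg.nb_size, nb_p)

    taxonomy = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": [(_PHYLA * (n_asv // len(_PHYLA) + 1))[j] for j in range(n_asv)],
            "class": [f"Class_{module_id[j]}" for j in range(n_asv)],
            "order": [f"Order_{module_id[j]}" for j in range(n_asv)],
            "family": [f"Family_{j % 17}" for j in range(n_asv)],
            "genus": [f"Genus_{j % 53}" for j in range(n_asv)],
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    table = FeatureTable(
        pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id"), columns=sample_ids),
        taxonomy,
    )
    truth_asv = pd.DataFrame(
        {
            "category": cats,
            "module": module_id,
            "center": centers,
            "width": widths,
            "baseline": baseline,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    latents = pd.DataFrame(
        {"vegetation": veg, "generalist_latent": g_lat, "common_latent": c_lat},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    coefs = {
        "beta_veg_generalist": cfg.beta_veg_generalist,
        "beta_generalist_common": cfg.beta_generalist_common,
        "beta_common_specialist": cfg.beta_common_specialist,
        "module_loading": dict(cfg.module_loading),
    }
    return table, SampleMetadata(meta), GroundTruth(truth_asv, latents, coefs)


def planted_partition_graph(
    n_nodes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed=None,
) -> tuple[nx.Graph, dict]:
    """Planted-block random graph with known assignment (fixture for
    module-recovery tests). Requires 0 <= p_out < p_in <= 1 ... equality
    of p_in and 1 allowed; block sizes as equal as possible."""
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    base, extra = divmod(n_nodes, n_modules)
    sizes = [base + (1 if k < extra else 0) for k in range(n_modules)]
    probs = [[p_in if a == b else p_out for b in range(n_modules)] for a in range(n_modules)]
    g = nx.stochastic_block_model(sizes, probs, seed=seed)
    blocks = {v: g.nodes[v]["block"] for v in g.nodes}
    return nx.Graph(g), blocks
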