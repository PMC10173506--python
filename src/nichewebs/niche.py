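"""Levins' niche breadth and habitat generalist/specialist classification.

For ASV j observed with abundance P_ij in sample i (shares normalized so
that sum_i P_ij = 1), Levins' niche breadth is

    B_j = 1 / sum_i P_ij**2

B equals 1 for an ASV confined to a single sample and N for one spread
perfectly evenly over N samples. ASVs with broad breadth are habitat
generalists, those with narrow breadth habitat specialists, and the rest
common taxa. Classification uses either fixed B cutoffs (defaults 78/22,
appropriate for 225-sample surveys) or data-driven cutoffs: the Tukey
upper fence Q3 + 1.5*IQR for generalists and the lower quartile Q1 for
specialists.

Rare ASVs are excluded before classification: mean relative abundance
>= 2e-5 and prevalence >= 25 samples (about 10% of a 225-sample design)
are required, since extremely rare ASVs masquerade as specialists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "levins_b",
    "niche_filter",
    "classify",
    "suggest_thresholds",
    "niche_profiles",
    "category_summary",
]

CATEGORIES = ("generalist", "common", "specialist")


def levins_b(abund) -> float:
    """Levins' niche breadth of one ASV from its per-sample abundances."""
    x = np.asarray(abund, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("niche breadth undefined for an all-zero abundance vector")
    p = x / total
    return 1.0 / float(np.sum(p**2))


def _profile_matrix(table: FeatureTable, use: str) -> pd.DataFrame:
    if use == "relative":
        return table.relative_abundance()
    if use == "counts":
        return table.counts.astype(float)
    raise ValueError(f"use must be 'relative' or 'counts', got {use!r}")


def niche_filter(
    table: FeatureTable,
    min_mean_rel_abund: float = 2e-5,
    min_prevalence: int = 25,
) -> pd.Series:
    """Boolean inclusion mask per ASV (both boundaries inclusive)."""
    rel = table.relative_abundance()
    mean_rel = rel.mean(axis=1)
    prev = table.prevalence()
    return (mean_rel >= min_mean_rel_abund) & (prev >= min_prevalence)


def classify(b, upper: float = 78.0, lower: float = 22.0):
    """Map B values to categories: generalist (B > upper), specialist
    (B < lower), common otherwise. Both cutoffs land in 'common'."""
    if not lower < upper:
        raise ValueError("require lower < upper")
    b_arr = np.asarray(b, dtype=float)
    cats = np.where(b_arr > upper, "generalist", np.where(b_arr < lower, "specialist", "common"))
    if np.isscalar(b) or b_arr.ndim == 0:
        return str(cats)
    return pd.Series(cats, index=b.index if isinstance(b, pd.Series) else None)


def suggest_thresholds(b_values) -> tuple[float, float]:
    """Data-driven cutoffs: (Q3 + 1.5*IQR, Q1), linear-interpolation quantiles.

    The upper fence marks the outlier region of the B distribution
    (generalists); the lower quartile marks specialists.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 B values to suggest thresholds")
    q1, q3 = np.quantile(b, [0.25, 0.75])  # default 'linear' == R type 7
    iqr = q3 - q1
    upper = q3 + 1.5 * iqr
    if iqr == 0:
        warnings.warn("degenerate B distribution: all quartiles equal")
    return float(upper), float(q1)


def niche_profiles(
    table: FeatureTable,
    use: str = "relative",
    min_mean_rel_abund: float = 2e-5,
    min_prevalence: int = 25,
    upper: float = 78.0,
    lower: float = 22.0,
    auto_thresholds: bool = False,
) -> pd.DataFrame:
    """Per-ASV niche profile: B, prevalence, mean relative abundance, category.

    ``use`` selects whether the shares P_ij come from per-sample relative
    abundances (default, removes sequencing-depth artifacts) or raw counts.
    ASVs failing the inclusion filters get category ``excluded`` (their B
    is still reported). When ``auto_thresholds`` is set, cutoffs come from
    :func:`suggest_thresholds` on the included ASVs' B values.
    """
    rel = table.relative_abundance()
    mat = _profile_matrix(table, use)
    vals = mat.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    b = np.full(len(totals), np.nan)
    nz = totals > 0
    shares = vals[nz] / totals[nz, None]
    b[nz] = 1.0 / np.sum(shares**2, axis=1)

    prof = pd.DataFrame(
        {
            "B": b,
            "prevalence": table.prevalence(),
            "mean_rel_abund": rel.mean(axis=1),
        },
        index=table.counts.index,
    )
    included = niche_filter(table, min_mean_rel_abund, min_prevalence)
    if auto_thresholds:
        upper, lower = suggest_thresholds(prof.loc[included, "B"].to_numpy())
    cats = classify(prof["B"].fillna(0.0), upper=upper, lower=lower)
    cats[~included] = "excluded"
    prof["category"] = cats
    prof.attrs["upper"] = upper
    prof.attrs["lower"] = lower
    return prof


def category_summary(profiles: pd.DataFrame, table: FeatureTable) -> pd.DataFrame:
    """Per-category ASV counts and mean +/- sd of per-sample abundance share.

    The share of a category in a sample is the summed relative abundance of
    its ASVs there; the table reports the across-sample mean and sd.
    """
    rel = table.relative_abundance()
    rows = []
    for cat in CATEGORIES:
        ids = profiles.index[profiles["category"] == cat]
        share = rel.loc[ids].sum(axis=0)
        rows.append(
            {
                "category": cat,
                "n_asvs": len(ids),
                "mean_share": float(share.mean()),
                "sd_share": float(share.std(ddof=1)) if table.n_samples > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["n_included"] = int((profiles["category"] != "excluded").sum())
    return out
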