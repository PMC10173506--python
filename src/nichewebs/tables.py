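"""Feature tables, sample metadata, and basic community transforms.

The central container is :class:`FeatureTable`, an ASV-by-sample matrix of
sequence counts with optional taxonomy, read from and written to plain TSV.
On top of it sit the routine community-ecology transforms the rest of the
package relies on: low-count filtering, per-sample relative abundance,
rarefaction (subsampling without replacement to a common depth), and the
Shannon diversity index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "read_feature_table",
    "read_metadata",
    "shannon",
]

#: canonical 7-rank taxonomy column order
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

VALID_STRATA = ("low", "mid", "high")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class FeatureTable:
    """ASV x sample count matrix with optional per-ASV taxonomy.

    Parameters
    ----------
    counts
        DataFrame with ASV ids as the index and sample ids as columns,
        non-negative integer entries.
    taxonomy
        Optional DataFrame indexed by ASV id with rank columns
        (domain ... genus/species). Must cover every ASV in ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.size == 0 and len(self.counts.columns) == 0:
            # empty ASV axis is allowed (filters may remove everything),
            # but there must be a sample axis to reason about
            pass
        _check_unique(self.counts.index, "ASV")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(vals < 0):
                bad = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative count at ASV {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "asv_id"
        self.counts.columns.name = None
        if self.taxonomy is not None:
            missing = self.counts.index.difference(self.taxonomy.index)
            if len(missing):
                raise ValueError(f"taxonomy missing for ASVs: {missing[:5].tolist()}")
            self.taxonomy = self.taxonomy.loc[self.counts.index]

    # -- basic accessors -------------------------------------------------
    @property
    def asv_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def asv_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def prevalence(self) -> pd.Series:
        """Number of samples in which each ASV has a nonzero count."""
        return (self.counts > 0).sum(axis=1)

    def subset(self, asv_ids) -> "FeatureTable":
        tax = self.taxonomy.loc[asv_ids] if self.taxonomy is not None else None
        return FeatureTable(self.counts.loc[asv_ids], tax)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def read_tsv(
        cls,
        path,
        orientation: str = "asv_rows",
        taxonomy_path=None,
    ) -> "FeatureTable":
        """Read a TSV feature table.

        ``orientation`` declares whether rows are ASVs (``asv_rows``) or
        samples (``sample_rows``). The first column holds row ids.
        """
        if orientation not in ("asv_rows", "sample_rows"):
            raise ValueError(f"unknown orientation {orientation!r}")
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        num = pd.DataFrame(index=raw.index)
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"malformed numeric cell at row {row!r}, column {col!r} in {path}"
                )
            num[col] = converted
        if orientation == "sample_rows":
            num = num.T
        tax = None
        if taxonomy_path is not None:
            tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
        return cls(num, tax)

    def write_tsv(self, path, taxonomy_path=None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(path, sep="\t")
        if taxonomy_path is not None and self.taxonomy is not None:
            tx = self.taxonomy.copy()
            tx.index.name = tx.index.name or "asv_id"
            tx.to_csv(taxonomy_path, sep="\t")

    # -- transforms ------------------------------------------------------
    def filter_low_count(self, min_total: int = 4) -> "FeatureTable":
        """Drop ASVs whose summed count across samples is below ``min_total``.

        The default of 4 removes singletons, doubletons, and tripletons,
        the usual guard against MiSeq sequencing-error ASVs.
        """
        if min_total < 1:
            raise ValueError("min_total must be >= 1")
        keep = self.asv_totals() >= min_total
        return self.subset(self.counts.index[keep])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; zero-total samples stay zero (with a warning)."""
        totals = self.sample_totals()
        zero = totals[totals == 0].index.tolist()
        if zero:
            warnings.warn(f"samples with zero total counts left as zeros: {zero}")
        safe = totals.replace(0, 1)
        return self.counts / safe

    def rarefy(self, depth="min", seed=None) -> "FeatureTable":
        """Subsample each sample without replacement to a common ``depth``.

        ``depth="min"`` uses the smallest sample total. Samples whose total
        is below an explicit depth are dropped with a warning (upsampling
        without replacement is undefined).
        """
        totals = self.sample_totals()
        if depth == "min":
            depth = int(totals.min())
        depth = int(depth)
        if depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        keep = totals[totals >= depth].index
        dropped = totals.index.difference(keep).tolist()
        if dropped:
            warnings.warn(f"samples below depth {depth} dropped: {dropped}")
        rng = np.random.default_rng(seed)
        out = {}
        for s in keep:
            col = self.counts[s].to_numpy()
            if col.sum() == depth:
                out[s] = col
            else:
                out[s] = rng.multivariate_hypergeometric(col, depth)
        rare = pd.DataFrame(out, index=self.counts.index)
        return FeatureTable(rare, self.taxonomy)

    def shannon(self) -> pd.Series:
        return shannon(self)


def shannon(table: FeatureTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (natural log)."""
    totals = table.sample_totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"cannot compute Shannon index for zero-count samples: {zero}")
    p = table.counts / totals
    vals = p.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(vals > 0, vals * np.log(vals), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=table.counts.columns, name="shannon")


def read_feature_table(path, orientation="asv_rows", taxonomy_path=None) -> FeatureTable:
    return FeatureTable.read_tsv(path, orientation=orientation, taxonomy_path=taxonomy_path)


@dataclass
class SampleMetadata:
    """Per-sample environmental and vegetation covariates.

    ``data`` is indexed by sample id. A ``stratum`` column, when present,
    must take values in {low, mid, high} (the three elevation belts).
    All other columns are treated as numeric covariates.
    """

    data: pd.DataFrame
    stratum_col: str = field(default="stratum")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if self.stratum_col in self.data.columns:
            bad = set(self.data[self.stratum_col].unique()) - set(VALID_STRATA)
            if bad:
                raise ValueError(f"invalid stratum values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def covariates(self) -> pd.DataFrame:
        """Numeric covariate columns only (stratum excluded)."""
        num = self.data.select_dtypes(include=[np.number])
        return num

    @property
    def stratum(self) -> pd.Series | None:
        if self.stratum_col in self.data.columns:
            return self.data[self.stratum_col]
        return None

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write_tsv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        out = self.data.copy()
        out.index.name = out.index.name or "sample_id"
        out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata.read_tsv(path)
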