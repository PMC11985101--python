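"""ASV abundance tables: I/O, normalisation, filtering, and diversity.

The central container is :class:`AbundanceTable`, a thin wrapper around a
pandas DataFrame of non-negative counts with ASVs as rows and samples as
columns, carrying a per-ASV domain tag (bacteria / fungi) and an optional
per-sample ecosystem label. Operations follow common amplicon practice:
total-sum scaling to relative abundance, a mean-abundance + prevalence
inclusion filter, and Shannon diversity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

TAXONOMIC_RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]

#: Default inclusion thresholds: mean relative abundance > 0.1% and
#: non-zero counts in at least 3 samples ("present in more than two").
DEFAULT_MIN_REL_ABUND = 0.001
DEFAULT_MIN_PREVALENCE = 3


class TableError(ValueError):
    """Raised for invalid abundance-table inputs."""


@dataclass
class AbundanceTable:
    """ASV x sample count (or proportion) matrix with metadata.

    Parameters
    ----------
    counts
        Non-negative matrix, rows indexed by ASV id, columns by sample id.
    domain
        Per-ASV domain tag, "bacteria" or "fungi"; defaults to "bacteria"
        for every ASV when omitted.
    ecosystem
        Optional per-sample ecosystem label.
    """

    counts: pd.DataFrame
    domain: pd.Series | None = None
    ecosystem: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise TableError("duplicate asv_id in table index")
        if counts.columns.has_duplicates:
            raise TableError("duplicate sample_id in table columns")
        vals = counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise TableError("abundance table contains non-finite values")
        if (vals < 0).any():
            raise TableError("abundance table contains negative values")
        counts.index.name = "asv_id"
        if self.domain is None:
            self.domain = pd.Series("bacteria", index=counts.index, name="domain")
        else:
            self.domain = self.domain.reindex(counts.index)
            if self.domain.isna().any():
                missing = list(self.domain.index[self.domain.isna()])[:5]
                raise TableError(f"domain tag missing for ASVs: {missing}")
        if self.ecosystem is not None:
            self.ecosystem = self.ecosystem.reindex(counts.columns)

    # -- basic accessors -------------------------------------------------
    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_asvs(self, asv_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.loc[asv_ids],
            domain=self.domain.loc[asv_ids],
            ecosystem=self.ecosystem,
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write counts as TSV: first column ``asv_id``, header = sample ids."""
        out = self.counts.copy()
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        domain: pd.Series | None = None,
        ecosystem: pd.Series | None = None,
    ) -> "AbundanceTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, domain=domain, ecosystem=ecosystem)


@dataclass
class TaxonomyMap:
    """ASV id -> six-rank lineage (kingdom..genus).

    Missing ranks are stored as the explicit string ``"unclassified"``.
    """

    lineages: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TAXONOMIC_RANKS))

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise TableError("duplicate asv_id in taxonomy map")
        for rank in TAXONOMIC_RANKS:
            if rank not in self.lineages.columns:
                self.lineages[rank] = "unclassified"
        self.lineages = self.lineages[TAXONOMIC_RANKS].fillna("unclassified")

    def rank(self, asv_id: str, rank: str = "phylum") -> str:
        if asv_id in self.lineages.index:
            return str(self.lineages.at[asv_id, rank])
        return "unclassified"

    def to_tsv(self, path: str | Path) -> None:
        out = self.lineages.copy()
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: divide each sample column by its total.

    Every column of the result sums to 1 (within 1e-9). A sample with an
    all-zero column cannot be normalised and raises naming that sample.
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise TableError(f"all-zero sample column(s): {list(zero.index)}")
    props = table.counts.div(totals, axis=1)
    return AbundanceTable(props, domain=table.domain, ecosystem=table.ecosystem)


def filter_asvs(
    table: AbundanceTable,
    min_rel_abund: float = DEFAULT_MIN_REL_ABUND,
    min_prevalence: int = DEFAULT_MIN_PREVALENCE,
    abundance_rule: Literal["mean", "any_sample"] = "mean",
) -> AbundanceTable:
    """Apply the community inclusion filter and return the count sub-table.

    An ASV is retained when its relative abundance exceeds ``min_rel_abund``
    (by default the mean across the samples; ``abundance_rule="any_sample"``
    requires only a single sample to exceed it) AND it has a non-zero raw
    count in at least ``min_prevalence`` samples. Thresholds of (0, 0) are
    the identity. Raises if nothing survives.
    """
    if not 0 <= min_rel_abund <= 1:
        raise TableError(f"min_rel_abund must be in [0,1], got {min_rel_abund}")
    if min_prevalence < 0:
        raise TableError(f"min_prevalence must be >= 0, got {min_prevalence}")
    if abundance_rule not in ("mean", "any_sample"):
        raise TableError(f"unknown abundance_rule {abundance_rule!r}")

    if min_rel_abund > 0:
        rel = relative_abundance(table).counts
        if abundance_rule == "mean":
            abund_ok = rel.mean(axis=1) > min_rel_abund
        else:
            abund_ok = (rel > min_rel_abund).any(axis=1)
    else:
        abund_ok = pd.Series(True, index=table.asv_ids)
    prevalence = (table.counts > 0).sum(axis=1)
    prev_ok = prevalence >= min_prevalence
    keep = abund_ok & prev_ok
    n_kept = int(keep.sum())
    logger.info(
        "filter_asvs: retained %d / %d ASVs (removed %d) at min_rel_abund=%g, min_prevalence=%d",
        n_kept, table.n_asvs, table.n_asvs - n_kept, min_rel_abund, min_prevalence,
    )
    if n_kept == 0:
        raise TableError(
            "inclusion filter removed every ASV; review min_rel_abund "
            f"({min_rel_abund}) and min_prevalence ({min_prevalence})"
        )
    return table.subset_asvs(table.asv_ids[keep])


def shannon_diversity(
    table: AbundanceTable,
    per: Literal["sample", "ecosystem"] = "sample",
) -> pd.Series:
    """Shannon index H' = -sum p_i ln p_i over ASV proportions.

    ``per="sample"`` returns one H' per sample; ``per="ecosystem"`` averages
    per-sample H' within each ecosystem label (which must be present).
    """
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise TableError(f"cannot compute diversity for empty sample(s): {empty}")
    props = table.counts.to_numpy() / totals.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(props > 0, props * np.log(props), 0.0)
    h = pd.Series(-terms.sum(axis=0), index=table.sample_ids, name="shannon")
    if per == "sample":
        return h
    if per == "ecosystem":
        if table.ecosystem is None or table.ecosystem.isna().all():
            raise TableError("ecosystem labels required for per-ecosystem diversity")
        return h.groupby(table.ecosystem).mean().rename("shannon")
    raise TableError(f"unknown per={per!r}")


class AbundanceFilter(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer applying the ASV inclusion filter.

    Parameters mirror :func:`filter_asvs`. After :meth:`fit`, the retained
    ASV ids are available as ``retained_ids_`` and the tallies as
    ``n_retained_`` / ``n_removed_``; :meth:`transform` returns the filtered
    count table (AbundanceTable in, AbundanceTable out; a bare DataFrame is
    wrapped on the fly).
    """

    def __init__(
        self,
        min_rel_abund: float = DEFAULT_MIN_REL_ABUND,
        min_prevalence: int = DEFAULT_MIN_PREVALENCE,
        abundance_rule: str = "mean",
    ):
        self.min_rel_abund = min_rel_abund
        self.min_prevalence = min_prevalence
        self.abundance_rule = abundance_rule

    @staticmethod
    def _as_table(X) -> AbundanceTable:
        return X if isinstance(X, AbundanceTable) else AbundanceTable(pd.DataFrame(X))

    def fit(self, X, y=None):
        table = self._as_table(X)
        filtered = filter_asvs(
            table,
            min_rel_abund=self.min_rel_abund,
            min_prevalence=self.min_prevalence,
            abundance_rule=self.abundance_rule,
        )
        self.retained_ids_ = filtered.asv_ids
        self.n_retained_ = len(self.retained_ids_)
        self.n_removed_ = table.n_asvs - self.n_retained_
        return self

    def transform(self, X) -> AbundanceTable:
        table = self._as_table(X)
        keep = table.asv_ids.intersection(self.retained_ids_)
        return table.subset_asvs(keep)

    def fit_transform(self, X, y=None, **fit_params) -> AbundanceTable:
        return self.fit(X, y).transform(X)


def read_ecosystem_map(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, ecosystem) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("ecosystem")
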