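"""OTU count tables: I/O, validation, rarefaction, filtering, summaries.

The universal input of every pipeline stage is an :class:`OtuTable`: a
non-negative integer count matrix (samples x taxa) with optional sample
collection dates and optional taxonomic lineages.  On disk the table uses
the "classic" tab-separated layout: taxa as rows, samples as columns,
first column taxon ids, optional trailing ``taxonomy`` column holding a
semicolon-separated lineage (domain ... genus/species).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rarecohort.errors import DataError

log = logging.getLogger(__name__)

#: Canonical rank names for lineage positions 0..6.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

TAXONOMY_COLUMN = "taxonomy"


@dataclass(frozen=True)
class OtuTable:
    """An OTU count matrix with optional dates and taxonomy.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = samples, columns = taxa.
    sample_dates
        Optional mapping sample_id -> :class:`datetime.date`; if given it
        must cover every sample.
    taxonomy
        Optional mapping taxon_id -> ordered lineage tuple (domain first).
    """

    counts: pd.DataFrame
    sample_dates: dict[str, datetime.date] | None = None
    taxonomy: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise DataError("counts must be finite integers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise DataError("counts must be non-negative")
        if self.sample_dates is not None:
            missing = set(c.index) - set(self.sample_dates)
            if missing:
                raise DataError(f"samples without a date: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; raises on a zero-total sample."""
        totals = self.sample_totals
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise DataError(f"samples with zero total reads: {bad}")
        return self.counts.div(totals, axis=0)

    def subset_taxa(self, taxon_ids) -> "OtuTable":
        taxon_ids = list(taxon_ids)
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return OtuTable(self.counts[taxon_ids], self.sample_dates, tax)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        dates = None
        if self.sample_dates is not None:
            dates = {s: self.sample_dates[s] for s in sample_ids}
        return OtuTable(self.counts.loc[sample_ids], dates, self.taxonomy)


# -- I/O -----------------------------------------------------------------


def read_otu_table(path, metadata_path=None) -> OtuTable:
    """Read a classic tab-separated OTU table (taxa rows x sample columns).

    The first column holds taxon ids; an optional trailing ``taxonomy``
    column holds semicolon-separated lineages.  ``metadata_path``, if
    given, is a TSV with columns ``sample_id`` and ``date`` (ISO 8601).
    Unparseable counts are an error, never silently zeroed.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate taxon ids in {path}: {dups}")
    taxonomy = None
    if raw.columns.size and raw.columns[-1].strip().lower() == TAXONOMY_COLUMN:
        lineages = raw.iloc[:, -1]
        raw = raw.iloc[:, :-1]
        taxonomy = {
            str(t): tuple(part.strip() for part in str(lin).split(";") if part.strip())
            for t, lin in lineages.items()
        }
    try:
        counts = raw.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-integer count in {path}: {exc}") from exc
    counts = counts.T
    counts.index.name = None
    counts.columns.name = None
    table = OtuTable(counts, taxonomy=taxonomy)

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        required = {"sample_id", "date"}
        if not required.issubset(meta.columns):
            raise DataError(f"metadata must have columns {sorted(required)}")
        dates = {
            str(r.sample_id): datetime.date.fromisoformat(str(r.date))
            for r in meta.itertuples()
        }
        if set(dates) != set(table.sample_ids):
            raise DataError(
                "metadata sample ids do not match the table: "
                f"table-only={sorted(set(table.sample_ids) - set(dates))}, "
                f"metadata-only={sorted(set(dates) - set(table.sample_ids))}"
            )
        table = OtuTable(table.counts, sample_dates=dates, taxonomy=taxonomy)
    return table


def write_otu_table(table: OtuTable, path, metadata_path=None) -> None:
    """Write ``table`` in the same classic TSV dialect read_otu_table reads."""
    out = table.counts.T.copy()
    out.index.name = "taxon_id"
    if table.taxonomy is not None:
        out[TAXONOMY_COLUMN] = [
            ";".join(table.taxonomy.get(t, ())) for t in out.index
        ]
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        if table.sample_dates is None:
            raise DataError("table has no sample dates to write")
        meta = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "date": [table.sample_dates[s].isoformat() for s in table.sample_ids],
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


# -- transforms ----------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample is drawn from a multivariate hypergeometric
    distribution over its own reads, so richness loss reflects sampling
    alone.  Samples with fewer than ``depth`` reads are dropped with a
    warning.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise DataError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        log.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep:
        raise DataError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    rows = []
    for s in keep:
        row = table.counts.loc[s].to_numpy()
        rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(rows, index=keep, columns=table.taxon_ids, dtype=np.int64)
    dates = None
    if table.sample_dates is not None:
        dates = {s: table.sample_dates[s] for s in keep}
    return OtuTable(counts, dates, table.taxonomy)


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop taxa whose total count across the whole table equals one.

    Matches the convention of excluding OTUs represented by a single read
    in the pooled dataset; taxa with zero or >= 2 reads are retained.
    """
    totals = table.taxon_totals
    keep = totals.index[totals != 1]
    return table.subset_taxa(keep)


def summarize_taxa(table: OtuTable) -> pd.DataFrame:
    """Per-taxon abundance/occurrence summaries.

    Returns a DataFrame indexed by taxon_id with columns ``total_count``,
    ``mean_rel_abund`` (mean over samples of per-sample proportions, the
    metacommunity abundance estimate p_i), ``occurrence`` (number of
    samples with a positive count) and ``occurrence_freq``.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise DataError("cannot summarize an empty table")
    rel = table.relative_abundance()
    occurrence = (table.counts > 0).sum(axis=0)
    out = pd.DataFrame(
        {
            "total_count": table.taxon_totals,
            "mean_rel_abund": rel.mean(axis=0),
            "occurrence": occurrence,
            "occurrence_freq": occurrence / table.n_samples,
        }
    )
    # rename_axis (not .name=) so the Index shared with counts.columns
    # is left untouched
    return out.sort_index().rename_axis("taxon_id")


# -- taxonomic composition ----------------------------------------------


def _rank_value(lineage: tuple[str, ...], rank: str) -> str:
    """Value of ``rank`` in ``lineage``, 'unclassified_<parent>' if absent.

    ``rank='phylum'`` splits Proteobacteria into its classes, mirroring the
    common phylum/proteobacterial-class presentation of community bar
    plots.
    """
    idx = {"phylum": 1, "class": 2, "family": 4}[rank]

    def level(i: int) -> str | None:
        if i < len(lineage) and lineage[i] and not lineage[i].lower().startswith(
            "unclassified"
        ):
            return lineage[i]
        return None

    if rank == "phylum":
        phylum = level(1)
        if phylum is None:
            parent = level(0) or "root"
            return f"unclassified_{parent}"
        if phylum.lower() == "proteobacteria":
            cls = level(2)
            return cls if cls is not None else f"unclassified_{phylum}"
        return phylum
    value = level(idx)
    if value is not None:
        return value
    for i in range(idx - 1, -1, -1):
        parent = level(i)
        if parent is not None:
            return f"unclassified_{parent}"
    return "unclassified_root"


@dataclass(frozen=True)
class CompositionTable:
    """Relative abundance of each taxonomic rank value per (cohort, sample).

    ``data`` is wide: rows are a MultiIndex (cohort, sample_id), columns
    are rank values, entries are relative abundances on the whole-table
    scale (a cohort's row sums to that cohort's share of the sample).
    """

    rank: str
    data: pd.DataFrame

    def for_cohort(self, cohort: str) -> "CompositionTable":
        sub = self.data.loc[[cohort]]
        return CompositionTable(self.rank, sub)

    @property
    def cohorts(self) -> list[str]:
        return list(self.data.index.get_level_values(0).unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.get_level_values(1).unique())


def aggregate_composition(table: OtuTable, partition, rank: str) -> CompositionTable:
    """Aggregate relative abundances at a taxonomic rank, per cohort.

    ``rank`` is ``'phylum'`` (with Proteobacteria split to class) or
    ``'family'``.  Values are fractions of the whole-sample read total, so
    a cohort's values in a sample sum to the cohort's relative abundance
    there.
    """
    if table.taxonomy is None:
        raise DataError("aggregate_composition requires taxonomy")
    if rank not in ("phylum", "family", "class"):
        raise DataError(f"unsupported rank {rank!r}")
    rel = table.relative_abundance()
    labels = partition.labels
    groups: dict[tuple[str, str], dict[str, float]] = {}
    rank_values = sorted(
        {
            _rank_value(table.taxonomy.get(t, ()), rank)
            for t in table.taxon_ids
        }
    )
    frames = []
    for cohort in sorted(labels.unique()):
        taxa = labels.index[labels == cohort]
        sub = rel[taxa]
        value_of = [
            _rank_value(table.taxonomy.get(t, ()), rank) for t in taxa
        ]
        agg = sub.T.groupby(pd.Index(value_of, name=rank)).sum().T
        agg = agg.reindex(columns=rank_values, fill_value=0.0)
        agg.index = pd.MultiIndex.from_product(
            [[cohort], agg.index], names=["cohort", "sample_id"]
        )
        frames.append(agg)
    return CompositionTable(rank, pd.concat(frames))


def compare_compositions(a: CompositionTable, b: CompositionTable) -> pd.DataFrame:
    """Welch two-sample t-test per rank value between two compositions.

    Both tables must share the rank and sample set (typically two cohorts
    of the same samples).  P-values are reported without multiple-testing
    correction; the ``corrected`` attribute on the result flags this.
    """
    if a.rank != b.rank:
        raise DataError(f"rank mismatch: {a.rank!r} vs {b.rank!r}")
    if set(a.sample_ids) != set(b.sample_ids):
        raise DataError("compositions cover different sample sets")
    if len(a.sample_ids) < 2:
        raise DataError("need at least 2 samples for a t-test")
    values = sorted(set(a.data.columns) | set(b.data.columns))
    rows = []
    for v in values:
        xa = (
            a.data[v].to_numpy() if v in a.data.columns
            else np.zeros(len(a.sample_ids))
        )
        xb = (
            b.data[v].to_numpy() if v in b.data.columns
            else np.zeros(len(b.sample_ids))
        )
        if np.allclose(xa.var(), 0) and np.allclose(xb.var(), 0):
            if np.isclose(xa.mean(), xb.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(xa.mean() - xb.mean()), 0.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {"rank_value": v, "mean_a": xa.mean(), "mean_b": xb.mean(),
             "t": float(t), "p": float(p)}
        )
    out = pd.DataFrame(rows).set_index("rank_value")
    out.attrs["corrected"] = False
    return out
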