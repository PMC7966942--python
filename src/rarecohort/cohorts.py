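"""Rarity cohorts: classification, threshold grids, conditional rarity.

Taxa are split into four cohorts under explicit thresholds.  A taxon is
*rare* when its pooled read total is below a fraction of all reads
(default <1%).  Rare taxa occurring in fewer than ``transient_max_occ``
samples are *transient-rare*; rare taxa occurring in more than
``persistent_min_occ`` samples are *persistent-rare*; the remainder are
*intermediate-rare*.  Everything non-rare is *common*.  All inequalities
are strict, matching the "<1%", "<4 occurrences", ">8 occurrences"
convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rarecohort.errors import ConfigError, DataError

TRANSIENT_RARE = "transient_rare"
PERSISTENT_RARE = "persistent_rare"
INTERMEDIATE_RARE = "intermediate_rare"
COMMON = "common"
COHORT_LABELS = (TRANSIENT_RARE, PERSISTENT_RARE, INTERMEDIATE_RARE, COMMON)


@dataclass(frozen=True)
class CohortThresholds:
    """Thresholds defining the rarity cohorts.

    ``rare_max_rel_abund`` is a fraction of the grand read total (strict
    upper bound); ``transient_max_occ`` and ``persistent_min_occ`` are
    occurrence counts (strict bounds, exclusive).
    """

    rare_max_rel_abund: float = 0.01
    transient_max_occ: int = 4
    persistent_min_occ: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.rare_max_rel_abund < 1):
            raise ConfigError(
                f"rare_max_rel_abund must be in (0,1), got {self.rare_max_rel_abund}"
            )
        if not (0 < self.transient_max_occ <= self.persistent_min_occ):
            raise ConfigError(
                "need 0 < transient_max_occ <= persistent_min_occ, got "
                f"{self.transient_max_occ}, {self.persistent_min_occ}"
            )

    def occurrence_fractions(self, n_samples: int) -> tuple[float, float]:
        """The thresholds as fractions of the sample count (for logging)."""
        return (self.transient_max_occ / n_samples,
                self.persistent_min_occ / n_samples)


@dataclass(frozen=True)
class CohortPartition:
    """Assignment of every taxon to one cohort, plus per-cohort summary."""

    labels: pd.Series  # taxon_id -> cohort label
    thresholds: CohortThresholds
    summary: pd.DataFrame  # cohort -> n_otus, pct_otus, pct_reads

    def taxa(self, cohort: str) -> list[str]:
        return list(self.labels.index[self.labels == cohort])

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in COHORT_LABELS}


def classify_taxa(summaries: pd.DataFrame,
                  thresholds: CohortThresholds) -> CohortPartition:
    """Partition taxa into the four rarity cohorts.

    ``summaries`` is the frame produced by
    :func:`rarecohort.core_table.summarize_taxa`.  Rarity is judged on the
    pooled reads fraction: a taxon is rare when
    ``total_count < rare_max_rel_abund * grand_total``.
    """
    if summaries.empty:
        raise DataError("no taxa to classify")
    grand_total = summaries["total_count"].sum()
    if grand_total <= 0:
        raise DataError("table has zero total reads")
    cutoff = thresholds.rare_max_rel_abund * grand_total
    rare = summaries["total_count"] < cutoff
    occ = summaries["occurrence"]
    labels = pd.Series(COMMON, index=summaries.index, name="cohort")
    labels[rare] = INTERMEDIATE_RARE
    labels[rare & (occ < thresholds.transient_max_occ)] = TRANSIENT_RARE
    labels[rare & (occ > thresholds.persistent_min_occ)] = PERSISTENT_RARE
    labels = labels.sort_index()
    partition = CohortPartition(labels, thresholds, pd.DataFrame())
    summary = cohort_summary(partition, summaries)
    return CohortPartition(labels, thresholds, summary)


def cohort_summary(partition: CohortPartition,
                   summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort OTU count, % of OTUs, and % of total reads."""
    if set(partition.labels.index) != set(summaries.index):
        raise DataError("partition and summaries cover different taxa")
    total_otus = len(summaries)
    total_reads = summaries["total_count"].sum()
    rows = []
    for cohort in COHORT_LABELS:
        taxa = partition.labels.index[partition.labels == cohort]
        reads = summaries.loc[taxa, "total_count"].sum()
        rows.append(
            {
                "cohort": cohort,
                "n_otus": len(taxa),
                "pct_otus": 100.0 * len(taxa) / total_otus,
                "pct_reads": 100.0 * reads / total_reads,
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


# -- threshold sensitivity grid -----------------------------------------

#: 12 rarity-abundance thresholds spanning 0.05%..4.00% and 5 occurrence
#: thresholds spanning 2..6 -> the 60-combination sensitivity grid.
DEFAULT_ABUND_THRESHOLDS = (
    0.0005, 0.00075, 0.001, 0.0025, 0.005, 0.0075,
    0.01, 0.015, 0.02, 0.025, 0.03, 0.04,
)
DEFAULT_OCC_THRESHOLDS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ThresholdGrid:
    """Cartesian product of rarity-abundance and occurrence thresholds."""

    abund_values: tuple[float, ...]
    occ_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.abund_values or not self.occ_values:
            raise ConfigError("threshold grid lists must be nonempty")
        for a in self.abund_values:
            if not (0 < a < 1):
                raise ConfigError(f"abundance threshold out of (0,1): {a}")
        for o in self.occ_values:
            if o < 1:
                raise ConfigError(f"occurrence threshold must be >= 1: {o}")

    @property
    def combinations(self) -> list[tuple[float, int]]:
        """Abundance-major lexicographic enumeration of the grid."""
        return list(itertools.product(self.abund_values, self.occ_values))

    def __len__(self) -> int:
        return len(self.abund_values) * len(self.occ_values)


def threshold_grid(abund_values, occ_values) -> ThresholdGrid:
    return ThresholdGrid(tuple(abund_values), tuple(occ_values))


def default_grid() -> ThresholdGrid:
    """The study-design sensitivity grid: 12 abundances x 5 occurrences."""
    return ThresholdGrid(DEFAULT_ABUND_THRESHOLDS, DEFAULT_OCC_THRESHOLDS)


# -- conditionally rare taxa --------------------------------------------


def flag_conditionally_rare(table, bimodality_cutoff: float = 0.9,
                            rarity_rel_abund: float = 0.01) -> set[str]:
    """Flag taxa that are rare most of the time but occasionally bloom.

    A taxon is conditionally rare when the coefficient of bimodality of
    its per-sample relative abundances, b = (skewness^2 + 1) / kurtosis
    (kurtosis non-excess), exceeds ``bimodality_cutoff`` AND the taxon is
    below ``rarity_rel_abund`` in at least one sample and above it in at
    least one other.  Zero-variance (including all-zero) taxa are never
    flagged.
    """
    if table.n_samples < 4:
        raise DataError("conditional rarity needs >= 4 samples (kurtosis)")
    rel = table.relative_abundance()
    flagged: set[str] = set()
    for taxon in table.taxon_ids:
        x = rel[taxon].to_numpy()
        if np.ptp(x) == 0:
            continue
        if not ((x < rarity_rel_abund).any() and (x > rarity_rel_abund).any()):
            continue
        skew = stats.skew(x, bias=True)
        kurt = stats.kurtosis(x, fisher=False, bias=True)
        if kurt > 0 and (skew**2 + 1) / kurt > bimodality_cutoff:
            flagged.add(taxon)
    return flagged
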