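"""Abundance-based beta-null deviation.

How different would samples look if every taxon were ecologically
equivalent?  The null model redraws each sample's reads (sample totals
fixed) with replacement from the regional pool, with probabilities
proportional to pooled taxon totals.  The *null deviation* of a sample
pair is its observed Bray-Curtis distance minus the mean distance over
null iterations: values near zero indicate neutral (equivalent-taxa)
assembly, while systematic taxon-sample associations push deviations away
from zero.  Deviations are aggregated per sample and compared between the
transient-rare and common cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from rarecohort import cohorts as _cohorts
from rarecohort.core_table import OtuTable
from rarecohort.errors import ConfigError, DataError


@dataclass(frozen=True)
class NullModelConfig:
    iterations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


def null_community(table: OtuTable, seed: int) -> OtuTable:
    """One randomized table under the ecological-equivalence null.

    Each sample's total is redrawn with replacement from the regional pool
    (pooled taxon totals); sample totals and the taxon identity set are
    preserved exactly.
    """
    rng = np.random.default_rng(seed)
    return _null_draw(table.counts.to_numpy(), rng, table)


def _null_draw(counts: np.ndarray, rng, table: OtuTable) -> OtuTable:
    pooled = counts.sum(axis=0).astype(float)
    grand = pooled.sum()
    if grand <= 0:
        raise DataError("cannot randomize an all-zero table")
    probs = pooled / grand
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise DataError("every sample needs a positive total")
    rows = rng.multinomial(totals, probs)
    out = pd.DataFrame(rows, index=table.counts.index,
                       columns=table.counts.columns, dtype=np.int64)
    return OtuTable(out, table.sample_dates, table.taxonomy)


def _null_mean_distances(counts: np.ndarray, iterations: int,
                         rng) -> np.ndarray:
    """Mean pairwise Bray-Curtis over null iterations (condensed form)."""
    pooled = counts.sum(axis=0).astype(float)
    probs = pooled / pooled.sum()
    totals = counts.sum(axis=1)
    acc = None
    for _ in range(iterations):
        null = rng.multinomial(totals, probs).astype(float)
        d = pdist(null, metric="braycurtis")
        acc = d if acc is None else acc + d
    return acc / iterations


def table_null_deviation(table: OtuTable,
                         config: NullModelConfig) -> pd.DataFrame:
    """Per-pair and per-sample null deviations for one (sub-)table.

    Returns a frame with columns sample_a, sample_b, observed, mean_null,
    deviation; the per-sample means are in ``attrs['per_sample']``.
    """
    if table.n_samples < 3:
        raise DataError("need >= 3 samples")
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise DataError("every sample needs a positive total")
    rng = np.random.default_rng(config.seed)
    observed = pdist(counts.astype(float), metric="braycurtis")
    mean_null = _null_mean_distances(counts, config.iterations, rng)
    deviation = observed - mean_null
    ids = table.sample_ids
    pairs = list(itertools.combinations(range(len(ids)), 2))
    out = pd.DataFrame(
        {
            "sample_a": [ids[i] for i, _ in pairs],
            "sample_b": [ids[j] for _, j in pairs],
            "observed": observed,
            "mean_null": mean_null,
            "deviation": deviation,
        }
    )
    per_sample = pd.Series(
        {
            s: out.loc[(out.sample_a == s) | (out.sample_b == s),
                       "deviation"].mean()
            for s in ids
        },
        name="mean_deviation",
    )
    out.attrs["per_sample"] = per_sample
    return out


@dataclass(frozen=True)
class NullDeviationResult:
    per_pair: pd.DataFrame     # cohort, sample_a, sample_b, observed, mean_null, deviation
    per_sample: pd.DataFrame   # cohort, sample_id, mean_deviation
    comparison: dict           # Mann-Whitney U and Welch t between cohorts
    not_computable: list[str]
    config: NullModelConfig


def beta_null_deviation(table: OtuTable, partition,
                        config: NullModelConfig,
                        cohorts=(_cohorts.TRANSIENT_RARE,
                                 _cohorts.COMMON)) -> NullDeviationResult:
    """Beta-null deviations per cohort plus a two-cohort comparison.

    The table is restricted to each cohort in turn; cohorts with fewer
    than 3 taxa are reported as not computable.  Per-sample deviations of
    the two cohorts are compared by a two-sided Mann-Whitney U (primary,
    robust at n=12) and a Welch t-test (reported alongside).
    """
    pair_frames = []
    sample_frames = []
    not_computable = []
    per_cohort_samples: dict[str, pd.Series] = {}
    rng_seed = np.random.default_rng(config.seed)
    for cohort in cohorts:
        taxa = partition.taxa(cohort)
        if len(taxa) < 3:
            not_computable.append(cohort)
            continue
        sub = table.subset_taxa(taxa)
        sub_cfg = NullModelConfig(
            iterations=config.iterations,
            seed=int(rng_seed.integers(2**31 - 1)),
        )
        pairs = table_null_deviation(sub, sub_cfg)
        per_sample = pairs.attrs["per_sample"]
        per_cohort_samples[cohort] = per_sample
        pairs = pairs.copy()
        pairs.attrs = {}  # concat chokes comparing Series-valued attrs
        pairs.insert(0, "cohort", cohort)
        pair_frames.append(pairs)
        sample_frames.append(
            pd.DataFrame(
                {
                    "cohort": cohort,
                    "sample_id": per_sample.index,
                    "mean_deviation": per_sample.to_numpy(),
                }
            )
        )
    comparison: dict = {}
    if len(per_cohort_samples) == 2:
        a, b = (per_cohort_samples[c].to_numpy() for c in cohorts)
        u, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
        t, t_p = stats.ttest_ind(a, b, equal_var=False)
        comparison = {
            "cohorts": list(cohorts),
            "mannwhitney_u": float(u),
            "mannwhitney_p": float(u_p),
            "welch_t": float(t),
            "welch_p": float(t_p),
        }
    return NullDeviationResult(
        per_pair=pd.concat(pair_frames, ignore_index=True)
        if pair_frames else pd.DataFrame(),
        per_sample=pd.concat(sample_frames, ignore_index=True)
        if sample_frames else pd.DataFrame(),
        comparison=comparison,
        not_computable=not_computable,
        config=config,
    )
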