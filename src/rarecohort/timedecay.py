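"""Time-decay of community similarity.

For every sample pair, similarity = 1 - Bray-Curtis and lag = days between
collection dates.  The time-decay exponent w is the OLS slope of
log10(similarity) on log10(lag): similarity ~ lag^w, with w < 0 when the
community drifts.  Because the n(n-1)/2 pairwise points are not
independent, significance comes from permuting the date assignment across
samples (Mantel-style) and comparing |slope|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarecohort.betadiv import bray_curtis
from rarecohort.core_table import OtuTable
from rarecohort.errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeDecayFit:
    slope: float
    intercept: float
    p_value: float
    pairs: pd.DataFrame  # sample_a, sample_b, lag_days, similarity
    n_pairs: int
    n_excluded: int
    permutations: int
    seed: int


def _fit_slope(lags: np.ndarray, sims: np.ndarray) -> tuple[float, float]:
    keep = sims > 0
    if keep.sum() < 2:
        raise DataError("fewer than 2 pairs with positive similarity")
    slope, intercept = np.polyfit(np.log10(lags[keep]), np.log10(sims[keep]), 1)
    return float(slope), float(intercept)


def time_decay(table: OtuTable, permutations: int = 999,
               seed: int = 0) -> TimeDecayFit:
    """Fit the log-log time-decay regression with a date-permutation test."""
    if table.sample_dates is None:
        raise DataError("time decay requires sample dates")
    ids = table.sample_ids
    dates = [table.sample_dates[s] for s in ids]
    if len(set(dates)) < 4:
        raise DataError("need >= 4 distinct sample dates")
    dist = bray_curtis(table)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    sims = 1.0 - np.asarray(dist.data)[iu]
    day_num = np.array([d.toordinal() for d in dates], dtype=float)

    def lags_for(day_values: np.ndarray) -> np.ndarray:
        return np.abs(day_values[iu[0]] - day_values[iu[1]])

    lags = lags_for(day_num)
    if np.any(lags == 0):
        raise DataError("sample pairs with identical dates give zero lag")
    n_excluded = int((sims <= 0).sum())
    if n_excluded:
        log.warning("excluding %d pair(s) with zero similarity", n_excluded)
    if n_excluded == len(sims):
        raise DataError("all pairwise similarities are zero")
    slope, intercept = _fit_slope(lags, sims)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm_lags = lags_for(rng.permutation(day_num))
        s_perm, _ = _fit_slope(perm_lags, sims)
        if abs(s_perm) >= abs(slope) - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    pairs = pd.DataFrame(
        {
            "sample_a": [ids[i] for i in iu[0]],
            "sample_b": [ids[j] for j in iu[1]],
            "lag_days": lags,
            "similarity": sims,
        }
    )
    return TimeDecayFit(
        slope=slope, intercept=intercept, p_value=float(p), pairs=pairs,
        n_pairs=len(sims), n_excluded=n_excluded,
        permutations=permutations, seed=seed,
    )
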