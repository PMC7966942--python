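"""Bray-Curtis distances, principal coordinates, PERMANOVA and PERMDISP.

The location test (PERMANOVA) asks whether two assemblages differ in
composition; the dispersion test (PERMDISP) asks whether one varies more
over time than the other.  Both permute group labels and report
p = (exceedances + 1) / (permutations + 1); ``permutations=None``
enumerates every label permutation exhaustively (feasible for toy
problems), in which case p is the exact fraction of permutations —
including the identity — whose statistic reaches the observed one.

The statistics are computed directly from the distance matrix (PERMANOVA)
or from a full principal-coordinates embedding with negative eigenvalues
retained (PERMDISP, Anderson's correction: squared distances to the group
centroid subtract the contribution of the imaginary axes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from rarecohort import cohorts as _cohorts
from rarecohort.core_table import OtuTable
from rarecohort.errors import DataError


def bray_curtis(table, relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``table`` is an :class:`OtuTable` or a samples-x-taxa DataFrame.  With
    ``relative=True`` (default) rows are converted to proportions first,
    so samples with unequal totals (e.g. cohort sub-tables) remain
    comparable.
    """
    if isinstance(table, OtuTable):
        df = table.counts
    else:
        df = table
    totals = df.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise DataError(f"zero-total samples: {bad}")
    mat = df.div(totals, axis=0) if relative else df.astype(float)
    condensed = pdist(mat.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in df.index])


@dataclass(frozen=True)
class PcoaResult:
    """Classical scaling of a distance matrix.

    ``coordinates`` are scaled eigenvectors (columns ordered by descending
    eigenvalue); axes with negative eigenvalues are imaginary — their
    coordinates are stored as sqrt(-lambda)-scaled real numbers and
    flagged in ``negative_axes``.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    negative_axes: np.ndarray
    ids: tuple[str, ...]


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates via double-centering and eigendecomposition."""
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise DataError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        negative_axes=eigvals < 0,
        ids=tuple(dist.ids),
    )


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    permutations: int
    seed: int | None
    method: str


def _group_index(groups) -> tuple[np.ndarray, list]:
    labels = np.asarray(list(groups))
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise DataError("need at least 2 groups")
    codes = np.array([uniq.index(g) for g in labels])
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise DataError("every group needs at least 2 members")
    return codes, uniq


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def _permutation_p(stat_fn, codes: np.ndarray, permutations, seed):
    """Shared permutation machinery; stat_fn(codes) -> statistic."""
    observed = stat_fn(codes)
    if permutations is None:
        count = 0
        total = 0
        for perm in itertools.permutations(codes):
            total += 1
            if stat_fn(np.array(perm)) >= observed - 1e-12:
                count += 1
        return observed, count / total, total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if stat_fn(rng.permutation(codes)) >= observed - 1e-12:
            exceed += 1
    return observed, (exceed + 1) / (permutations + 1), permutations


def permanova(dist: DistanceMatrix, groups, permutations: int | None = 999,
              seed: int | None = 0) -> PermTestResult:
    """Permutational multivariate analysis of variance (location test).

    The pseudo-F is the distance-based decomposition of total versus
    within-group sums of squared dissimilarities.
    """
    codes, uniq = _group_index(groups)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    k = len(uniq)
    stat, p, used = _permutation_p(
        lambda c: _pseudo_f(d2, c, k), codes, permutations, seed
    )
    return PermTestResult(statistic=float(stat), p_value=float(p),
                          permutations=used, seed=seed, method="permanova")


def _dispersion_distances(coords, neg, codes, k):
    """Distance of every item to its group centroid, imaginary-corrected."""
    sq = np.empty(coords.shape[0])
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        centroid = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - centroid) ** 2
        sq[idx] = diff2[:, ~neg].sum(axis=1) - diff2[:, neg].sum(axis=1)
    return np.sqrt(np.clip(sq, 0.0, None))


def _dispersion_f(coords, neg, codes, k) -> float:
    z = _dispersion_distances(coords, neg, codes, k)
    n = len(z)
    means = np.array([z[codes == g].mean() for g in range(k)])
    sizes = np.bincount(codes, minlength=k)
    grand = z.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum((z - means[codes]) ** 2))
    if ss_within == 0.0:
        return 0.0 if ss_between == 0.0 else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permdisp(dist: DistanceMatrix, groups, permutations: int | None = 999,
             seed: int | None = 0) -> PermTestResult:
    """Permutation test of multivariate dispersion homogeneity.

    Items are embedded by PCoA (all axes, negative eigenvalues retained);
    the statistic is the one-way F on distances to group centroids.
    Labels are permuted and centroids recomputed for each permutation.
    """
    codes, uniq = _group_index(groups)
    emb = pcoa(dist)
    k = len(uniq)
    stat, p, used = _permutation_p(
        lambda c: _dispersion_f(emb.coordinates, emb.negative_axes, c, k),
        codes, permutations, seed,
    )
    return PermTestResult(statistic=float(stat), p_value=float(p),
                          permutations=used, seed=seed, method="permdisp")


def cohort_assemblage_tests(table, partition,
                            cohorts=(_cohorts.TRANSIENT_RARE, _cohorts.COMMON),
                            permutations: int = 999, seed: int = 0) -> dict:
    """PERMANOVA + PERMDISP between two cohort assemblages.

    The two cohort sub-tables of the same samples are stacked as 2n items
    labeled by cohort; each row is converted to within-cohort proportions
    before the Bray-Curtis computation.  Both tests share one permutation
    stream per the given seed.
    """
    frames = []
    labels = []
    ids = []
    for cohort in cohorts:
        taxa = partition.taxa(cohort)
        if len(taxa) < 1:
            raise DataError(f"cohort {cohort!r} is empty")
        sub = table.counts[taxa]
        totals = sub.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise DataError(f"cohort {cohort!r} absent from samples {bad}")
        sub = sub.div(totals, axis=0)
        sub.columns = [str(c) for c in sub.columns]
        frames.append(sub)
        labels.extend([cohort] * len(sub))
        ids.extend(f"{s}|{cohort}" for s in sub.index)
    stacked = pd.concat(frames, axis=0).fillna(0.0)
    stacked.index = ids
    dist = bray_curtis(stacked, relative=False)
    return {
        "permanova": permanova(dist, labels, permutations, seed),
        "permdisp": permdisp(dist, labels, permutations, seed),
    }
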