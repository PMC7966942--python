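"""Sloan neutral community model fitting.

The Sloan model treats a local community of N individuals as continuously
receiving immigrants from a source metacommunity.  For a taxon with
metacommunity relative abundance p, neutral drift plus immigration make
its local relative abundance Beta-distributed with parameters
(Nm*p, Nm*(1-p)), where Nm is the product of community size and
immigration rate — the model's single free parameter.  The probability of
*detecting* the taxon in a sample (occurrence frequency) is the
probability that its abundance exceeds the detection limit d:

    freq(p) = 1 - I_d(Nm*p, Nm*(1-p))

with I the regularized incomplete beta function.  Nm is estimated by
nonlinear least squares of observed occurrence frequencies on mean
relative abundances; the quality of fit is the generalized
R^2 = 1 - SS_err/SS_total.  A 95% Wilson score envelope around the
prediction partitions taxa into above / within / below, and the *within*
fraction ("neutrality fraction") measures how much of the assemblage is
consistent with purely neutral dynamics.  A dispersal-unlimited binomial
sampling model (no drift, Nm -> infinity) serves as the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rarecohort.errors import DataError, NumericalError

log = logging.getLogger(__name__)

ABOVE, WITHIN, BELOW = "above", "within", "below"


def ncm_predict(p, nm: float, n_reads: int, d: float):
    """Predicted occurrence frequency under the neutral model.

    ``1 - BetaCDF(d; Nm*p, Nm*(1-p))``; vectorized over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DataError("ncm_predict requires 0 < p < 1")
    if nm <= 0:
        raise DataError("Nm must be positive")
    if not (0 < d < 1):
        raise DataError("detection limit d must be in (0,1)")
    out = stats.beta.sf(d, nm * p, nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class NcmFit:
    """A fitted neutral community model with per-taxon records.

    ``taxa`` has columns p, obs_freq, pred_freq and (once the envelope is
    computed) lower, upper, position.  ``excluded`` lists taxa with
    p in {0, 1} that could not enter the fit.
    """

    nm: float
    m: float
    n_reads: int
    d: float
    r_squared: float
    binomial_r_squared: float | None
    n_samples: int
    converged: bool
    uninformative: bool
    taxa: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    envelope_alpha: float | None = None


def _sum_sq(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sum((obs - pred) ** 2))


def fit_ncm(summaries: pd.DataFrame, n_reads: int, n_samples: int,
            d: float | None = None, log_bounds=(-2.0, 7.0),
            n_grid: int = 200) -> NcmFit:
    """Estimate Nm by bounded 1-D least squares on log10(Nm).

    ``summaries`` is the per-taxon frame from ``summarize_taxa``.  Taxa
    with mean relative abundance 0 or 1 are excluded (degenerate beta) and
    listed on the result.  A coarse log-spaced scan over
    ``[10^log_bounds[0], 10^log_bounds[1]]`` is refined by bounded scalar
    minimization; convergence requires an interior minimum.

    The default detection limit is d = ln(2)/N rather than the naive one
    read (1/N): when a sample of N reads is drawn multinomially from a
    local community at relative abundance x, the detection probability
    1-(1-x)^N is the CDF of an exponential threshold with mean 1/N and
    median ln(2)/N, so the median-matched threshold makes the beta
    tail-probability prediction agree with actual detection (and removes
    an upward bias in fitted Nm).  Pass ``d=1/N`` for the naive limit.
    """
    if d is None:
        d = np.log(2.0) / n_reads
    p_all = summaries["mean_rel_abund"]
    ok = (p_all > 0) & (p_all < 1)
    excluded = list(summaries.index[~ok])
    sub = summaries[ok]
    if len(sub) < 10:
        raise DataError(f"need >= 10 taxa with 0 < p < 1, got {len(sub)}")
    p = sub["mean_rel_abund"].to_numpy()
    obs = sub["occurrence_freq"].to_numpy()

    def sse(log_nm: float) -> float:
        return _sum_sq(obs, ncm_predict(p, 10.0**log_nm, n_reads, d))

    grid = np.linspace(log_bounds[0], log_bounds[1], n_grid)
    vals = np.array([sse(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise NumericalError("Nm optimization failed to converge")
    log_nm = float(res.x)
    converged = log_bounds[0] + 1e-6 < log_nm < log_bounds[1] - 1e-6
    if not converged:
        log.warning("fitted Nm sits at the search boundary (10^%.2f)", log_nm)
    nm = 10.0**log_nm
    pred = ncm_predict(p, nm, n_reads, d)
    ss_err = _sum_sq(obs, pred)
    ss_tot = _sum_sq(obs, np.full_like(obs, obs.mean()))
    uninformative = ss_tot == 0.0
    r2 = -np.inf if uninformative else 1.0 - ss_err / ss_tot
    taxa = pd.DataFrame(
        {"p": p, "obs_freq": obs, "pred_freq": pred}, index=sub.index
    )
    return NcmFit(
        nm=nm, m=nm / n_reads, n_reads=n_reads, d=d,
        r_squared=float(r2), binomial_r_squared=None,
        n_samples=n_samples, converged=converged,
        uninformative=uninformative, taxa=taxa, excluded=excluded,
    )


# -- Wilson envelope -----------------------------------------------------


def wilson_interval(p_hat, n: int, alpha: float = 0.05):
    """Wilson score interval for a binomial proportion.

    center = (p̂ + z²/2n) / (1 + z²/n),
    half-width = z * sqrt(p̂(1-p̂)/n + z²/4n²) / (1 + z²/n).
    """
    if n < 1:
        raise DataError("Wilson interval needs n >= 1")
    if not (0 < alpha < 1):
        raise DataError("alpha must be in (0,1)")
    p_hat = np.asarray(p_hat, dtype=float)
    z = stats.norm.isf(alpha / 2.0)
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2.0 * n)) / denom
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z**2 / (4.0 * n**2)) / denom
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    # at the boundaries the interval endpoints are exactly 0 / 1; enforce
    # this against float rounding so boundary observations compare "within"
    lower = np.where(p_hat == 0.0, 0.0, lower)
    upper = np.where(p_hat == 1.0, 1.0, upper)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def ncm_envelope(fit: NcmFit, alpha: float = 0.05,
                 n_samples: int | None = None) -> pd.DataFrame:
    """Attach the Wilson envelope around the predicted frequencies.

    The trial count defaults to the fit's sample count — the denominator
    of the observed occurrence frequencies.
    """
    n = fit.n_samples if n_samples is None else n_samples
    lower, upper = wilson_interval(fit.taxa["pred_freq"].to_numpy(), n, alpha)
    fit.taxa["lower"] = lower
    fit.taxa["upper"] = upper
    fit.envelope_alpha = alpha
    return fit.taxa[["lower", "upper"]]


def partition_by_envelope(fit: NcmFit) -> dict[str, int]:
    """Label each taxon above / within / below the envelope (closed bounds)."""
    if "lower" not in fit.taxa.columns:
        raise DataError("compute ncm_envelope before partitioning")
    obs = fit.taxa["obs_freq"]
    position = pd.Series(WITHIN, index=fit.taxa.index, name="position")
    position[obs > fit.taxa["upper"]] = ABOVE
    position[obs < fit.taxa["lower"]] = BELOW
    fit.taxa["position"] = position
    return {k: int((position == k).sum()) for k in (ABOVE, WITHIN, BELOW)}


@dataclass(frozen=True)
class NeutralityCurve:
    """Neutrality fraction by abundance bin and by cohort."""

    bins: pd.DataFrame       # bin_low, bin_high, n_taxa, frac_within
    cohort_fractions: pd.DataFrame  # per cohort: n, frac_within, abund-weighted


def neutrality_curve(fit: NcmFit, partition=None,
                     n_bins: int = 10) -> NeutralityCurve:
    """Fraction of taxa inside the envelope, on log-spaced abundance bins.

    Per-cohort fractions are reported under two weightings: by OTU count
    and by summed relative abundance of the within-taxa (both appear in
    standard presentations of the neutrality fraction).  Empty bins are
    omitted rather than reported as zero.
    """
    if n_bins < 2:
        raise DataError("need at least 2 bins")
    if "position" not in fit.taxa.columns:
        raise DataError("compute partition_by_envelope first")
    p = fit.taxa["p"].to_numpy()
    within = (fit.taxa["position"] == WITHIN).to_numpy()
    edges = np.geomspace(p.min(), p.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.digitize(p, edges) - 1
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_taxa": int(mask.sum()),
                "frac_within": float(within[mask].mean()),
            }
        )
    bins = pd.DataFrame(rows)
    cohort_rows = []
    if partition is not None:
        labels = partition.labels.reindex(fit.taxa.index)
        for cohort in sorted(labels.dropna().unique()):
            mask = (labels == cohort).to_numpy()
            if not mask.any():
                continue
            p_c = p[mask]
            w_c = within[mask]
            cohort_rows.append(
                {
                    "cohort": cohort,
                    "n_taxa": int(mask.sum()),
                    "frac_within": float(w_c.mean()),
                    "within_rel_abund_share": float(
                        p_c[w_c].sum() / p_c.sum()
                    ) if p_c.sum() > 0 else np.nan,
                }
            )
    cohort_fractions = pd.DataFrame(
        cohort_rows,
        columns=["cohort", "n_taxa", "frac_within", "within_rel_abund_share"],
    )
    return NeutralityCurve(bins=bins, cohort_fractions=cohort_fractions)


# -- binomial comparison model ------------------------------------------


@dataclass(frozen=True)
class BinomialFit:
    """Dispersal-unlimited random-sampling model (no drift, no parameter)."""

    predicted: pd.Series
    r_squared: float
    n_reads: int
    d: float


def binomial_predict(p, n_reads: int, d: float):
    """Detection probability under pure random sampling of N reads.

    ``1 - BinomCDF(ceil(N*d) - 1; N, p)``; with d = 1/N this is
    ``1 - (1-p)^N``.
    """
    p = np.asarray(p, dtype=float)
    k = int(np.ceil(n_reads * d))
    out = stats.binom.sf(k - 1, n_reads, p)
    return float(out) if out.ndim == 0 else out


def fit_binomial_model(summaries: pd.DataFrame, n_reads: int,
                       d: float | None = None) -> BinomialFit:
    """Evaluate the no-drift binomial model and its generalized R^2.

    The default detection limit matches :func:`fit_ncm` (d = ln(2)/N);
    any d <= 1/N keeps the detection rule "at least one read".
    """
    if d is None:
        d = np.log(2.0) / n_reads
    p_all = summaries["mean_rel_abund"]
    ok = (p_all > 0) & (p_all < 1)
    sub = summaries[ok]
    p = sub["mean_rel_abund"].to_numpy()
    obs = sub["occurrence_freq"].to_numpy()
    pred = binomial_predict(p, n_reads, d)
    ss_err = _sum_sq(obs, pred)
    ss_tot = _sum_sq(obs, np.full_like(obs, obs.mean()))
    r2 = -np.inf if ss_tot == 0 else 1.0 - ss_err / ss_tot
    return BinomialFit(
        predicted=pd.Series(pred, index=sub.index, name="pred_freq_binomial"),
        r_squared=float(r2), n_reads=n_reads, d=d,
    )
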