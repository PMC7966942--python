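"""Synthetic OTU tables with known assembly processes.

Every analysis stage in this package is validated against communities
whose generating process is known exactly:

* **Neutral**: a log-series metacommunity p is sampled once; each local
  sample draws its relative abundances from a Dirichlet with
  concentration Nm*p — so each taxon's marginal is Beta(Nm*p_i,
  Nm*(1-p_i)), exactly the distribution the Sloan model fits — and then
  counts from a multinomial of the sampling depth.  The generator is the
  exact generative dual of the fitted model, which turns parameter
  recovery into a sharp test.
* **Niche**: expected local abundance is the metacommunity abundance
  filtered by a Gaussian response to a per-sample environment value,
  exp(-(e_j - u_i)^2 / (2 sigma^2)); small sigma means strong filtering.
* **Time series**: the metacommunity log-abundances perform an AR(1)
  drift between bimonthly sampling dates, so community similarity decays
  with lag while the within-date sampling stays neutral.

Defaults emulate the study design the package targets: 12 bimonthly
samples over two years at a depth of 2,988 reads each, with a log-series
metacommunity dominated by rare taxa.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rarecohort.core_table import OtuTable
from rarecohort.errors import ConfigError, DataError


def _bimonthly_dates(n: int, start=datetime.date(2005, 5, 1)) -> list[datetime.date]:
    """n dates spaced two calendar months apart (12 -> two years)."""
    out = []
    year, month = start.year, start.month
    for _ in range(n):
        out.append(datetime.date(year, month, start.day))
        month += 2
        if month > 12:
            month -= 12
            year += 1
    return out


@dataclass(frozen=True)
class NeutralSimParams:
    """Dirichlet-multinomial neutral community parameters.

    The metacommunity is either an explicit relative-abundance vector
    ``p`` or ``n_taxa`` draws from a log-series with Fisher's alpha and an
    implied metacommunity size ``meta_size`` (series parameter
    x = meta_size / (meta_size + alpha)).
    """

    n_taxa: int = 2000
    alpha: float = 50.0
    meta_size: float = 1e6
    p: np.ndarray | None = None
    nm: float = 300.0
    depth: int = 2988
    n_samples: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p is None and self.n_taxa < 2:
            raise ConfigError("need at least 2 taxa")
        if self.alpha <= 0 or self.meta_size <= 0:
            raise ConfigError("alpha and meta_size must be positive")
        if self.nm <= 0:
            raise ConfigError("Nm must be positive")
        if self.depth < 1 or self.n_samples < 1:
            raise ConfigError("depth and n_samples must be >= 1")
        if self.p is not None:
            p = np.asarray(self.p, dtype=float)
            if p.ndim != 1 or p.size < 2:
                raise ConfigError("explicit p must be a vector of >= 2 taxa")
            if np.any(p <= 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ConfigError("explicit p must be positive and sum to 1")


@dataclass(frozen=True)
class NicheSimParams:
    """Gaussian environmental-filtering alternative.

    The default environment alternates between two conditions (-1, +1)
    across consecutive samples — a seasonal-style fluctuation matching a
    bimonthly sampling design — so that strong filtering (small sigma)
    creates abundant specialists whose occurrence is capped at half the
    samples, the niche signature no neutral parameterization can absorb.
    Pass ``env=np.linspace(...)`` for a monotone gradient instead.
    """

    n_taxa: int = 2000
    alpha: float = 50.0
    meta_size: float = 1e6
    p: np.ndarray | None = None
    sigma: float = 0.5
    env: np.ndarray | None = None       # default: alternating two conditions
    optima: np.ndarray | None = None    # default: uniform over the env range
    depth: int = 2988
    n_samples: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("niche breadth sigma must be positive")
        if self.depth < 1 or self.n_samples < 1:
            raise ConfigError("depth and n_samples must be >= 1")


@dataclass(frozen=True)
class TimeSeriesSimParams:
    """Neutral parameters plus AR(1) metacommunity drift and dates."""

    neutral: NeutralSimParams = field(default_factory=NeutralSimParams)
    rho: float = 0.85
    innovation_sd: float = 0.4
    start_date: datetime.date = datetime.date(2005, 5, 1)

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ConfigError("drift coefficient rho must be in [0,1)")
        if self.innovation_sd < 0:
            raise ConfigError("innovation_sd must be >= 0")


def simulate_metacommunity(params: NeutralSimParams,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Metacommunity relative abundances: explicit p or log-series draws."""
    if params.p is not None:
        return np.asarray(params.p, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = params.meta_size / (params.meta_size + params.alpha)
    draws = stats.logser.rvs(x, size=params.n_taxa, random_state=rng)
    return draws / draws.sum()


def _dirichlet_sample(p: np.ndarray, nm: float, depth: int,
                      rng: np.random.Generator) -> np.ndarray:
    conc = nm * p
    if conc.min() <= 0:
        raise DataError(
            "Nm*p underflows to 0 for the rarest taxon; raise Nm, reduce "
            "n_taxa, or supply a less skewed metacommunity"
        )
    g = rng.gamma(conc)
    total = g.sum()
    if total == 0:  # all gamma draws underflowed (conc uniformly tiny)
        raise DataError("Dirichlet draw underflowed; Nm*p too small")
    return rng.multinomial(depth, g / total)


def _table(counts_rows, n_taxa: int, n_samples: int,
           dates=None) -> OtuTable:
    counts = pd.DataFrame(
        np.asarray(counts_rows, dtype=np.int64),
        index=[f"S{i+1:02d}" for i in range(n_samples)],
        columns=[f"OTU{j+1:04d}" for j in range(n_taxa)],
    )
    sample_dates = None
    if dates is not None:
        sample_dates = dict(zip(counts.index, dates))
    return OtuTable(counts, sample_dates=sample_dates)


def simulate_neutral(params: NeutralSimParams, dated: bool = False) -> OtuTable:
    """Dispersal-limited neutral community table (Dirichlet-multinomial)."""
    rng = np.random.default_rng(params.seed)
    p = simulate_metacommunity(params, rng)
    rows = [
        _dirichlet_sample(p, params.nm, params.depth, rng)
        for _ in range(params.n_samples)
    ]
    dates = _bimonthly_dates(params.n_samples) if dated else None
    return _table(rows, p.size, params.n_samples, dates)


def simulate_niche(params: NicheSimParams) -> OtuTable:
    """Niche-structured community along an environmental gradient."""
    rng = np.random.default_rng(params.seed)
    base = NeutralSimParams(
        n_taxa=params.n_taxa, alpha=params.alpha, meta_size=params.meta_size,
        p=params.p, depth=params.depth, n_samples=params.n_samples,
        seed=params.seed,
    )
    p = simulate_metacommunity(base, rng)
    env = (
        np.asarray(params.env, dtype=float)
        if params.env is not None
        else np.array([(-1.0) ** j for j in range(params.n_samples)])
    )
    if env.size != params.n_samples:
        raise ConfigError("env must have one value per sample")
    optima = (
        np.asarray(params.optima, dtype=float)
        if params.optima is not None
        else rng.uniform(env.min(), env.max(), size=p.size)
    )
    if optima.size != p.size:
        raise ConfigError("optima must have one value per taxon")
    rows = []
    for e in env:
        w = p * np.exp(-((e - optima) ** 2) / (2.0 * params.sigma**2))
        total = w.sum()
        if total <= 0:
            raise DataError("all taxa filtered out at env value %r" % e)
        rows.append(rng.multinomial(params.depth, w / total))
    return _table(rows, p.size, params.n_samples)


def simulate_timeseries(params: TimeSeriesSimParams) -> OtuTable:
    """Neutral sampling from a metacommunity drifting by AR(1) on logs."""
    base = params.neutral
    rng = np.random.default_rng(base.seed)
    p0 = simulate_metacommunity(base, rng)
    n_taxa = p0.size
    dates = _bimonthly_dates(base.n_samples, params.start_date)
    z = np.zeros(n_taxa)
    rows = []
    for _ in range(base.n_samples):
        z = params.rho * z + rng.normal(0.0, params.innovation_sd, size=n_taxa)
        p_t = p0 * np.exp(z)
        p_t = p_t / p_t.sum()
        rows.append(_dirichlet_sample(p_t, base.nm, base.depth, rng))
    return _table(rows, n_taxa, base.n_samples, dates)


def example_table(seed: int = 20110) -> OtuTable:
    """The standard small fixture: 12 dated samples x 300 taxa, neutral
    drifting series at depth 2,988.  Regenerated bit-identically from the
    seed; shared across the test suite and the documentation examples."""
    params = TimeSeriesSimParams(
        neutral=NeutralSimParams(n_taxa=300, nm=300.0, depth=2988,
                                 n_samples=12, seed=seed),
    )
    return simulate_timeseries(params)
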