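"""From posterior parameter samples to posterior molecule numbers.

Given MCMC draws of (nu, f, sigma_e0, sigma_e1, sigma_e2), a single
fluorescence value y maps to a posterior over the molecule number x as
a mixture over the draws of

    N(x; (y - f)/nu, (sigma_e0^2 + y sigma_e1^2 + (y sigma_e2)^2) / nu^2)

(the observation model solved for x, with nu*x approximated by y inside
the variance).  For a population mean over N cells the per-cell noise
averages out and the posterior reduces to a kernel-smoothed mixture of
ybar/nu over the nu draws, using a log-normal kernel with log-scale
standard deviation sigma_K = 0.1.

Replicates are combined post hoc: the per-replicate posteriors are
represented by log-normal kernel density estimates, their product is
divided by prior^(N-1) (the replicates share one prior), and the
resulting target is sampled with a random-walk Metropolis algorithm in
log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import PriorSpec, SHARED_NAMES

__all__ = [
    "NumberPosterior",
    "number_posterior_single",
    "population_mean_posterior",
    "combine_replicates",
    "SIGMA_K",
]

#: log-normal kernel scale used for posterior KDEs (log-space sd 0.1)
SIGMA_K = 0.1


@dataclass(frozen=True)
class NumberPosterior:
    """Density over molecule number on a grid, normalised to 1."""

    grid: np.ndarray
    density: np.ndarray
    mode: float
    mass_below_zero: float = 0.0

    def __post_init__(self) -> None:
        total = np.trapezoid(self.density, self.grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {total}, not 1")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval from the gridded CDF."""
        cdf = np.concatenate(
            [[0.0], np.cumsum(np.diff(self.grid)
                              * 0.5 * (self.density[1:] + self.density[:-1]))]
        )
        cdf /= cdf[-1]
        a = (1.0 - level) / 2.0
        return (
            float(np.interp(a, cdf, self.grid)),
            float(np.interp(1.0 - a, cdf, self.grid)),
        )

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


def _normalise(grid: np.ndarray, density: np.ndarray) -> NumberPosterior:
    total = np.trapezoid(density, grid)
    if total <= 0:
        raise ValueError("degenerate (zero-mass) posterior on the grid")
    density = density / total
    mode = float(grid[np.argmax(density)])
    below = float(
        np.trapezoid(np.where(grid < 0, density, 0.0), grid)
    )
    return NumberPosterior(grid=grid, density=density, mode=mode,
                           mass_below_zero=below)


def _columns(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return samples.samples  # PosteriorSamples


def number_posterior_single(
    y: float,
    samples,
    f: float | np.ndarray = 0.0,
    grid_size: int = 1024,
) -> NumberPosterior:
    """Posterior over x for one fluorescence value y.

    ``samples`` is a DataFrame with columns nu, sigma_e0, sigma_e1,
    sigma_e2 (or a PosteriorSamples).  ``f`` is the residual
    autofluorescence (scalar or per-draw).  The grid spans the mixture's
    +/- 6 sigma range; negative x is retained (the noise model permits
    it) and reported as ``mass_below_zero``.
    """
    if not np.isfinite(y):
        raise ValueError("y must be finite")
    df = _columns(samples)
    nu = df["nu"].to_numpy(dtype=float)
    if nu.size < 1:
        raise ValueError("need at least one posterior draw")
    f = np.broadcast_to(np.asarray(f, dtype=float), nu.shape)
    var_y = (
        df["sigma_e0"].to_numpy() ** 2
        + y * df["sigma_e1"].to_numpy() ** 2
        + (y * df["sigma_e2"].to_numpy()) ** 2
    )
    mu = (y - f) / nu
    sd = np.sqrt(var_y) / nu
    sd = np.maximum(sd, 1e-12 * max(abs(y), 1.0))  # sigmas -> 0 limit
    lo = float(np.min(mu - 6 * sd))
    hi = float(np.max(mu + 6 * sd))
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[None, :] - mu[:, None]) / sd[:, None]
    dens = np.mean(
        np.exp(-0.5 * z**2) / (math.sqrt(2 * math.pi) * sd[:, None]), axis=0
    )
    return _normalise(grid, dens)


def population_mean_posterior(
    mean_y: float,
    mean_f: float,
    n_cells: int,
    samples,
    sigma_k: float = SIGMA_K,
    grid_size: int = 1024,
) -> NumberPosterior:
    """Posterior over the population-mean molecule number xbar.

    For large N the per-cell measurement noise averages out and
    P(xbar | theta) collapses onto ybar/nu; the posterior is that point
    mass smoothed with a log-normal kernel (log-sd ``sigma_k``) and
    mixed over the nu draws.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    df = _columns(samples)
    nu = df["nu"].to_numpy(dtype=float)
    centers = (mean_y - mean_f) / nu
    if np.any(centers <= 0):
        raise ValueError("mean fluorescence must exceed mean autofluorescence")
    logc = np.log(centers)
    lo = float(np.exp(logc.min() - 6 * sigma_k))
    hi = float(np.exp(logc.max() + 6 * sigma_k))
    grid = np.geomspace(lo, hi, grid_size)
    z = (np.log(grid)[None, :] - logc[:, None]) / sigma_k
    dens = np.mean(
        np.exp(-0.5 * z**2) / (math.sqrt(2 * math.pi) * sigma_k * grid[None, :]),
        axis=0,
    )
    return _normalise(grid, dens)


# ---------------------------------------------------------------------------
# Post-hoc combination of replicates


def _kde_log_mixture(z: np.ndarray, log_samples: np.ndarray,
                     sigma_k: float) -> float:
    """log density of the KDE mixture expressed in log space.

    Each log-normal kernel is an isotropic normal in z = log theta; the
    per-dimension 1/theta Jacobians are accounted for once, globally, in
    the sampler's target.
    """
    d = log_samples.shape[1]
    sq = np.sum((z[None, :] - log_samples) ** 2, axis=1) / sigma_k**2
    log_kernels = -0.5 * sq - d * math.log(sigma_k) \
        - 0.5 * d * math.log(2 * math.pi)
    return float(logsumexp(log_kernels)) - math.log(log_samples.shape[0])


def combine_replicates(
    sample_sets: Sequence[pd.DataFrame],
    prior: PriorSpec | None = None,
    seed: int = 0,
    n_samples: int = 10000,
    sigma_k: float = SIGMA_K,
    columns: Sequence[str] | None = None,
    target_accept: float = 0.44,
) -> pd.DataFrame:
    """Sample the pooled posterior over replicates.

    Each replicate's posterior is a log-normal KDE of its draws; the
    pooled target is their product divided by prior^(N-1).  A log-space
    random-walk Metropolis sampler (scale tuned toward ``target_accept``
    during burn-in) draws ``n_samples`` from the product.  All combined
    parameters must be positive.  Raises if the supports are disjoint
    (the product vanishes everywhere visited).
    """
    if not sample_sets:
        raise ValueError("need at least one sample set")
    frames = [_columns(s) for s in sample_sets]
    if columns is None:
        columns = [
            c for c in frames[0].columns
            if c in SHARED_NAMES and all(c in f.columns for f in frames)
        ] or [c for c in frames[0].columns if c != "loglik"]
    mats = []
    for f in frames:
        vals = f[list(columns)].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError("combined parameters must be positive")
        mats.append(np.log(vals))
    n_sets = len(mats)
    d = len(columns)

    def log_prior_theta(z: np.ndarray) -> float:
        if prior is None:
            return 0.0
        total = 0.0
        for zi, name in zip(z, columns):
            total += prior[name].logpdf(math.exp(zi))
            if total == -math.inf:
                break
        return total

    def log_target(z: np.ndarray) -> float:
        # pooled target over theta is prod_i p_i(theta) / prior^(N-1);
        # re-expressed over z = log theta, the N kernel Jacobians and the
        # one change-of-variables Jacobian leave (N-1) factors of
        # exp(-sum z) alongside the (N-1) inverse prior powers
        lp = log_prior_theta(z)
        if not math.isfinite(lp):
            return -math.inf
        lt = -(n_sets - 1) * (lp + float(z.sum()))
        for m in mats:
            lt += _kde_log_mixture(z, m, sigma_k)
        return lt

    rng = np.random.default_rng(seed)
    # start between the replicate posteriors; per-dimension step sizes
    # follow the pooled spread, with one adaptive global factor
    z = np.mean([np.median(m, axis=0) for m in mats], axis=0)
    width = np.maximum(np.std(np.vstack(mats), axis=0), sigma_k)
    lt = log_target(z)
    if not math.isfinite(lt):
        raise ValueError("replicate posteriors have (near-)disjoint supports")
    scale = 1.0
    burn = max(n_samples // 5, 2000)
    draws = np.empty((n_samples, d))
    for it in range(burn + n_samples):
        cand = z + rng.normal(0.0, scale * width, size=d)
        lt_new = log_target(cand)
        if lt_new - lt >= 0 or math.log(rng.random()) < lt_new - lt:
            z, lt = cand, lt_new
            acc = 1.0
        else:
            acc = 0.0
        if it < burn:
            scale *= math.exp(0.5 / (1.0 + it) ** 0.6 * (acc - target_accept))
            if it == burn - 1:
                # a point many kernel widths from every sample of some
                # replicate means the KDE product has vanished there
                for m in mats:
                    dist = np.sqrt(
                        np.min(np.sum((z[None, :] - m) ** 2, axis=1))
                    )
                    if dist > 8.0 * sigma_k * math.sqrt(d):
                        raise ValueError(
                            "replicate posteriors have disjoint supports"
                        )
        else:
            draws[it - burn] = z
    return pd.DataFrame(np.exp(draws), columns=list(columns))
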