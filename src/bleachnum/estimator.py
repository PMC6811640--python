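"""Molecule numbers from photobleaching fluctuations.

The magnitude of stochastic fluctuations during photobleaching is set by
the number of molecules, not their total fluorescence.  For first-order
bleaching from x0 molecules with survival probability l = exp(-lam*t),

    E[X_t]   = x0 * l
    Var[X_t] = x0 * l * (1 - l)

so with fluorescence Y = nu * X (brightness nu per molecule) the initial
number can be estimated from any (y0, y_t) pair:

    xhat0 = E[Y_t] * (y0 - E[Y_t]) / Var[Y_t]

for every t > 0 — with exact moments this is an identity in x0, and with
negligible measurement noise it is the maximum-likelihood estimator.
Per cell, E[Y_t] comes from GP smoothing and Var[Y_t] from the squared
residuals, giving n_d - 1 estimates per cell; estimates are pooled over
all cells and the mode of their distribution (KDE in log10 space) is the
point estimate.

When molecules are heterogeneous — brightness nu_i and survival l_i
drawn from a joint distribution P(nu, l) — and measurement noise has
variance sigma_e^2, the estimator is biased:

    xhat0 = x0 / (1 + eps),
    eps = (sigma_e^2/x0 + Cov[nu, nu*l] - Var[nu*l])
          / (E[nu*l] * (E[nu] - E[nu*l]))

so large measurement noise causes underestimation and heterogeneity in
nu*l (absent noise) overestimation.  ``predicted_bias`` and
``accuracy_margins`` evaluate this theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .preprocess import CellTrace, qc_filter
from .smoothing import SmoothedTrace, smooth_trace

__all__ = [
    "PairEstimate",
    "PooledEstimate",
    "BiasInputs",
    "pair_estimate",
    "estimate_cell",
    "pool_and_mode",
    "predicted_bias",
    "accuracy_margins",
    "molecules_from_concentration",
    "mature_fraction",
    "mle_x0",
    "FluctuationModel",
    "FluctuationResults",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class PairEstimate:
    """One (y0, y_t) pair's estimate of the initial molecule number."""

    cell_id: str
    t: float
    xhat0: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("pair estimates require t > 0")
        if not np.isfinite(self.xhat0):
            raise ValueError("xhat0 must be finite")


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled pair estimates, their log10 KDE, and the mode."""

    estimates: tuple[PairEstimate, ...]
    mode: float
    log10_grid: np.ndarray
    density: np.ndarray
    n_positive: int
    n_negative: int


def pair_estimate(y0: float, mean_t: float, var_t: float) -> float:
    """xhat0 = mean_t * (y0 - mean_t) / var_t for a single pair.

    May be negative when mean_t > y0 (callers flag rather than drop).
    Raises if var_t <= 0; such pairs are skipped upstream with a log entry.
    """
    if var_t <= 0:
        raise ValueError("pair estimate needs a positive variance")
    return mean_t * (y0 - mean_t) / var_t


def estimate_cell(
    trace: CellTrace,
    smoothed: SmoothedTrace,
    y0_convention: str = "smoothed",
    drop_first: int = 0,
    skipped: list | None = None,
) -> list[PairEstimate]:
    """All pair estimates for one cell: one per positive time point.

    ``y0_convention`` chooses the first-frame fluorescence: "smoothed"
    (GP mean at t=0; default — the raw frame would inject its own noise
    into every pair) or "raw".  ``drop_first`` excludes the first k
    frames before pairing (the early frames can fluctuate anomalously).
    Pairs with non-positive variance are skipped and recorded.
    """
    if len(smoothed.times) != len(trace.times) or not np.allclose(
        smoothed.times, trace.times
    ):
        raise ValueError("smoothed trace is not aligned with the raw trace")
    if y0_convention not in ("smoothed", "raw"):
        raise ValueError("y0_convention must be 'smoothed' or 'raw'")
    k = int(drop_first)
    times = trace.times[k:]
    means = smoothed.mean[k:]
    var = smoothed.var[k:]
    if times.size < 2:
        return []
    y0 = means[0] if y0_convention == "smoothed" else trace.values[k]
    out: list[PairEstimate] = []
    for t, m, v in zip(times[1:], means[1:], var[1:]):
        if v <= 0 or not np.isfinite(v):
            if skipped is not None:
                skipped.append((trace.cell_id, float(t), "non-positive variance"))
            continue
        xh = pair_estimate(y0, m, v)
        if not np.isfinite(xh):
            if skipped is not None:
                skipped.append((trace.cell_id, float(t), "non-finite estimate"))
            continue
        out.append(PairEstimate(trace.cell_id, float(t - times[0]), xh))
    return out


def pool_and_mode(
    estimates: Sequence[PairEstimate],
    min_positive: int = 30,
    grid_size: int = 512,
) -> PooledEstimate:
    """Pool pair estimates and take the mode of their distribution.

    The density is a Gaussian KDE (Silverman bandwidth) over log10 of the
    positive estimates on a ``grid_size``-point grid spanning the sample
    range; the mode is the argmax.  Negative estimates are excluded from
    the KDE but counted in the diagnostics.
    """
    vals = np.array([e.xhat0 for e in estimates], dtype=float)
    pos = vals[vals > 0]
    n_neg = int((vals <= 0).sum())
    if pos.size < min_positive:
        raise ValueError(
            f"only {pos.size} positive estimates; need at least {min_positive}"
        )
    logs = np.log10(pos)
    lo, hi = logs.min(), logs.max()
    if hi - lo < 1e-12:  # point mass: KDE degenerate, mode is the value
        grid = np.full(grid_size, lo)
        dens = np.zeros(grid_size)
        dens[grid_size // 2] = 1.0
        mode = float(10**lo)
    else:
        kde = stats.gaussian_kde(logs, bw_method="silverman")
        grid = np.linspace(lo, hi, grid_size)
        dens = kde(grid)
        mode = float(10 ** grid[np.argmax(dens)])
    return PooledEstimate(
        estimates=tuple(estimates),
        mode=mode,
        log10_grid=grid,
        density=dens,
        n_positive=int(pos.size),
        n_negative=n_neg,
    )


def ensemble_pair_estimate(
    nu: np.ndarray, ell: np.ndarray, sigma_e2: float = 0.0
) -> float:
    """The pair estimator evaluated on a fully specified ensemble.

    Given each molecule's brightness nu_i and survival probability l_i
    (and measurement-noise variance sigma_e^2 inflating the observed
    variance), the exact conditional moments give

        xhat0 = (sum nu_i l_i)(sum nu_j - nu_j l_j)
                / (sigma_e^2 + sum nu_i^2 l_i (1 - l_i))

    which is what the pair estimator converges to for that ensemble;
    averaging over ensemble draws probes the heterogeneity bias law.
    """
    nu = np.asarray(nu, dtype=float)
    ell = np.asarray(ell, dtype=float)
    num = np.sum(nu * ell) * np.sum(nu - nu * ell)
    den = sigma_e2 + np.sum(nu**2 * ell * (1.0 - ell))
    if den <= 0:
        raise ValueError("zero variance: no bleaching and no noise")
    return float(num / den)


# ---------------------------------------------------------------------------
# Bias and accuracy theory for heterogeneous molecules


@dataclass(frozen=True)
class BiasInputs:
    """Moments of the joint (nu, l) distribution plus noise and x0."""

    E_nu: float
    E_nul: float
    Var_nul: float
    Cov_nu_nul: float
    E_l: float
    Var_l: float
    sigma_e2: float  # measurement-noise variance sigma_e^2
    x0: float

    def __post_init__(self) -> None:
        if self.E_nu <= 0:
            raise ValueError("E[nu] must be positive")
        if not 0 < self.E_l < 1:
            raise ValueError("E[l] must lie in (0, 1)")
        if min(self.Var_nul, self.Var_l, self.sigma_e2) < 0:
            raise ValueError("variances must be non-negative")

    @classmethod
    def from_independent(
        cls, nu_dist, ell_dist, sigma_e2: float, x0: float
    ) -> "BiasInputs":
        """Moments for independent nu and l (floats act as point masses).

        With independence, E[nu*l] = E[nu]E[l],
        Var[nu*l] = E[nu^2]E[l^2] - E[nu]^2 E[l]^2 and
        Cov[nu, nu*l] = (E[nu^2] - E[nu]^2) E[l].
        """

        def m12(d):
            if np.isscalar(d) or isinstance(d, (int, float)):
                return float(d), float(d) ** 2
            return float(d.moment(1)), float(d.moment(2))

        e_nu, e_nu2 = m12(nu_dist)
        e_l, e_l2 = m12(ell_dist)
        return cls(
            E_nu=e_nu,
            E_nul=e_nu * e_l,
            Var_nul=max(e_nu2 * e_l2 - (e_nu * e_l) ** 2, 0.0),
            Cov_nu_nul=(e_nu2 - e_nu**2) * e_l,
            E_l=e_l,
            Var_l=max(e_l2 - e_l**2, 0.0),
            sigma_e2=sigma_e2,
            x0=x0,
        )


def predicted_bias(b: BiasInputs) -> tuple[float, float]:
    """Relative bias eps and the implied estimate x0 / (1 + eps).

    eps > 0 (underestimation) when sigma_e^2/x0 + Cov[nu,nu*l] exceeds
    Var[nu*l]; eps < 0 (overestimation) in the opposite regime.
    """
    denom = b.E_nul * (b.E_nu - b.E_nul)
    if denom == 0:
        raise ValueError("E[nu] equals E[nu*l]: no bleaching, bias undefined")
    eps = (b.sigma_e2 / b.x0 + b.Cov_nu_nul - b.Var_nul) / denom
    return eps, b.x0 / (1.0 + eps)


def accuracy_margins(b: BiasInputs) -> dict[str, dict[str, float]]:
    """Left/right sides (and ratios) of the small-bias conditions.

    "general": |sigma_e^2/x0 + Cov - Var| << E[nu*l](E[nu] - E[nu*l]);
    "homogeneous_nu": sigma_e^2/(E[nu]^2 x0) << E[l] - E[l]^2 + Var[l];
    "homogeneous_l": same LHS << (E[l] - E[l]^2)(1 - Var[nu]/E[nu]^2),
    which fails outright once Var[nu] > E[nu]^2.  Margins are easiest to
    satisfy midway through bleaching (E[l] = 1/2).
    """
    lhs_gen = abs(b.sigma_e2 / b.x0 + b.Cov_nu_nul - b.Var_nul)
    rhs_gen = b.E_nul * (b.E_nu - b.E_nul)
    lhs_h = b.sigma_e2 / (b.E_nu**2 * b.x0)
    rhs_hnu = b.E_l - b.E_l**2 + b.Var_l
    # Var[nu] recovered from Cov[nu, nu*l] = Var[nu] * E[l] when l independent
    var_nu = b.Cov_nu_nul / b.E_l
    rhs_hl = (b.E_l - b.E_l**2) * (1.0 - var_nu / b.E_nu**2)

    def entry(lhs, rhs):
        return {"lhs": lhs, "rhs": rhs, "ratio": lhs / rhs if rhs != 0 else np.inf}

    return {
        "general": entry(lhs_gen, rhs_gen),
        "homogeneous_nu": entry(lhs_h, rhs_hnu),
        "homogeneous_l": entry(lhs_h, rhs_hl),
    }


# ---------------------------------------------------------------------------
# Reference calculations


def molecules_from_concentration(conc_nM: float, volume_fl: float) -> float:
    """Molecule count from a concentration in nM and a volume in fl."""
    if conc_nM < 0 or volume_fl < 0:
        raise ValueError("concentration and volume must be non-negative")
    return conc_nM * 1e-9 * volume_fl * 1e-15 * AVOGADRO


def mature_fraction(maturation_time_min: float, doubling_time_min: float) -> float:
    """Steady-state fluorescent fraction for a fluorophore that matures
    with time constant tau_m while being diluted by growth with doubling
    time tau_d: (1/tau_m) / (1/tau_m + 1/tau_d)."""
    if maturation_time_min <= 0 or doubling_time_min <= 0:
        raise ValueError("times must be positive")
    km = 1.0 / maturation_time_min
    kd = 1.0 / doubling_time_min
    return km / (km + kd)


# ---------------------------------------------------------------------------
# Maximum-likelihood oracle: the estimator as the peak of an explicit
# likelihood, evaluated by numerical integration rather than algebra.


def _log_likelihood_x0(
    x0: float, y0: float, mu_y: float, var_y: float, eps_rel: float
) -> float:
    """log L(x0) for noiseless data (y0, mu_y, var_y).

    The likelihood marginalises nu, mu_x, sigma_x^2 and l with the model
    constraints imposed as narrow Gaussians of relative width ``eps_rel``
    (delta functions in the limit).  After reducing the mu_x, sigma_x^2
    and l integrals the remaining nu integral is evaluated by
    Gauss-Hermite quadrature around nu = y0/x0, where the y0-constraint
    localises it.  A flat prior on nu is used, so the peak over x0 is the
    fluctuation estimator's value.
    """
    eps1 = eps_rel * y0
    eps2 = eps_rel * var_y
    nu0 = y0 / x0
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    nu = nu0 + (eps1 / x0) * nodes
    valid = nu > 0
    nu = nu[valid]
    w = weights[valid]
    # remaining constraint after the exact reductions: the variance relation
    g = var_y / nu**2 - (mu_y / nu) * (1.0 - mu_y / (nu * x0))
    log_terms = (
        np.log(w)
        - 3.0 * np.log(nu)
        - np.log(x0)
        - 0.5 * (g / eps2) ** 2
        - np.log(eps2)
    )
    return float(logsumexp(log_terms)) - np.log(x0)  # d(nu) Jacobian eps1/x0 const


def mle_x0(
    y0: float, mu_y: float, var_y: float, eps_rel: float = 1e-7
) -> float:
    """Numerically maximise the explicit likelihood over x0.

    Serves as an independent check that the pair estimator is the
    maximum-likelihood point: the returned value should match
    ``pair_estimate(y0, mu_y, var_y)`` without ever evaluating it.
    """
    if not (0 < mu_y < y0):
        raise ValueError("requires 0 < mu_y < y0 (some bleaching, none total)")
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    # coarse bracket by log-grid scan, then Brent refinement
    grid = np.geomspace(1e-2 * y0**2 / var_y, 1e2 * y0**2 / var_y, 400)
    ll = np.array([_log_likelihood_x0(x, y0, mu_y, var_y, eps_rel) for x in grid])
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -_log_likelihood_x0(x, y0, mu_y, var_y, eps_rel),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * grid[i]},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Model / Results interface


class FluctuationModel:
    """Photobleaching fluctuation analysis of a cohort of cell traces.

    Parameters
    ----------
    traces : sequence of CellTrace
        Corrected single-cell bleaching traces (same time grid not
        required, but each must be uniformly sampled).
    y0_convention : {"smoothed", "raw"}
        Source of the t=0 fluorescence in each pair.
    drop_first : int
        Number of initial frames to exclude per cell before pairing.
    qc_threshold : float
        Sudden-drop rejection threshold in robust frame-to-frame scales
        (``inf`` disables QC).
    gp_restarts : int
        Marginal-likelihood optimiser restarts per cell.
    min_positive : int
        Minimum pooled positive estimates required for a mode.
    """

    def __init__(
        self,
        traces: Sequence[CellTrace],
        *,
        y0_convention: str = "smoothed",
        drop_first: int = 0,
        qc_threshold: float = 5.0,
        gp_restarts: int = 5,
        min_positive: int = 30,
        seed: int = 0,
    ) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.y0_convention = y0_convention
        self.drop_first = int(drop_first)
        self.qc_threshold = float(qc_threshold)
        self.gp_restarts = int(gp_restarts)
        self.min_positive = int(min_positive)
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "FluctuationModel":
        """Build from a long-format frame (cell_id, time_s, fluorescence)."""
        from .io import traces_from_frame

        return cls(traces_from_frame(df), **kwargs)

    def fit(self) -> "FluctuationResults":
        kept, rejected = qc_filter(self.traces, self.qc_threshold)
        if not kept:
            raise ValueError("QC rejected every trace")
        estimates: list[PairEstimate] = []
        skipped: list[tuple[str, float, str]] = []
        hypers: dict[str, object] = {}
        smoothed: dict[str, SmoothedTrace] = {}
        for i, tr in enumerate(kept):
            sm, hp = smooth_trace(tr, n_restarts=self.gp_restarts,
                                  seed=self.seed + i)
            hypers[tr.cell_id] = hp
            smoothed[tr.cell_id] = sm
            estimates.extend(
                estimate_cell(tr, sm, self.y0_convention, self.drop_first, skipped)
            )
        pooled = pool_and_mode(estimates, min_positive=self.min_positive)
        return FluctuationResults(
            model=self,
            pooled=pooled,
            hyperparams=hypers,
            smoothed=smoothed,
            qc_rejected=rejected,
            skipped_pairs=skipped,
        )


@dataclass
class FluctuationResults:
    """Fitted fluctuation-analysis results.

    ``mode`` is the point estimate of the number of molecules per cell;
    ``pooled`` carries every pair estimate and the KDE over log10 counts.
    """

    model: FluctuationModel
    pooled: PooledEstimate
    hyperparams: dict
    smoothed: dict
    qc_rejected: dict[str, str] = field(default_factory=dict)
    skipped_pairs: list = field(default_factory=list)

    @property
    def mode(self) -> float:
        return self.pooled.mode

    @property
    def n_estimates(self) -> int:
        return len(self.pooled.estimates)

    def estimates_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.cell_id, e.t, e.xhat0) for e in self.pooled.estimates],
            columns=["cell_id", "t", "xhat0"],
        )

    def credible_interval(self, level: float = 0.9) -> tuple[float, float]:
        """Central interval of the pooled positive estimates (log10 scale)."""
        vals = np.array([e.xhat0 for e in self.pooled.estimates])
        pos = vals[vals > 0]
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(pos, [a, 1.0 - a]))

    def summary(self) -> str:
        lo, hi = self.credible_interval()
        lines = [
            "Photobleaching fluctuation analysis",
            "===================================",
            f"cells analysed:        {len(self.smoothed)}",
            f"cells rejected (QC):   {len(self.qc_rejected)}",
            f"pair estimates:        {self.n_estimates}"
            f" ({self.pooled.n_negative} negative, excluded from KDE)",
            f"skipped pairs:         {len(self.skipped_pairs)}",
            f"mode (molecules/cell): {self.mode:.4g}",
            f"central 90% of pooled estimates: [{lo:.4g}, {hi:.4g}]",
            f"y0 convention:         {self.model.y0_convention}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the pooled KDE over log10 molecule numbers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.pooled.log10_grid, self.pooled.density)
        ax.axvline(np.log10(self.mode), ls="--", color="k")
        ax.set_xlabel("log10 molecules per cell")
        ax.set_ylabel("density")
        return ax
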