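"""Posterior sampling for the explicit bleaching + noise model.

The parameter space splits into heterogeneous per-cell blocks
(lam1, lam2, f, y0, alpha — with y0 = nu * x0, the noise-free initial
fluorescence, sampled instead of x0 so that the expected trace depends
only on per-cell parameters) and a homogeneous block shared by all
cells (nu, sigma_e0, sigma_e1, sigma_e2).  Scale parameters (y0, nu and
the sigmas) carry scale-free 1/x priors; the remaining heterogeneous
parameters carry flat priors; all priors are proper with finite bounds.

Sampling is Metropolis-within-Gibbs: each cell's block is updated
against that cell's likelihood alone (the per-cell conditional
independence of the Kalman likelihood), then the shared block against
the full-data likelihood.  lam1, lam2, f and alpha use Gaussian
random-walk proposals; y0, nu and the sigmas use log-normal random
walks (with the Hastings asymmetry correction).  Proposal scales adapt
by a Robbins-Monro rule toward a target acceptance rate and freeze
after burn-in.  Mixing is accelerated by adaptive parallel tempering:
several chains target prior * likelihood^beta, adjacent chains propose
state swaps, and the temperature ladder adapts toward a target swap
rate; only the beta = 1 chain contributes samples.

Chains start from a nested optimisation: bi-exponential fits seed each
cell, a bounded global optimiser refines each cell independently,
medians seed the shared block, and block-coordinate ascent polishes the
joint optimum; half the chains start there, half from random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .kalman import filter_loglik
from .preprocess import CellTrace, fit_biexponential
from .simulate import NoiseParams

__all__ = [
    "PriorEntry",
    "PriorSpec",
    "ParameterVector",
    "PosteriorSamples",
    "default_priors",
    "log_prior",
    "make_cell_loglik",
    "initialize",
    "gibbs_step",
    "temper_and_swap",
    "run_inference",
    "BleachingModel",
    "BleachingResults",
]

HET_NAMES = ("lam1", "lam2", "f", "y0", "alpha")
SHARED_NAMES = ("nu", "sigma_e0", "sigma_e1", "sigma_e2")

#: parameters proposed on the log scale (log-normal random walk)
LOG_PROPOSAL = {"y0", "nu", "sigma_e0", "sigma_e1", "sigma_e2"}

#: base proposal widths, multiplied by the adaptive block scale
BASE_WIDTH = {
    "lam1": 2e-4,
    "lam2": 1e-3,
    "f": 20.0,
    "y0": 0.10,  # log scale
    "alpha": 0.05,
    "nu": 0.05,
    "sigma_e0": 0.05,
    "sigma_e1": 0.05,
    "sigma_e2": 0.05,
}


@dataclass(frozen=True)
class PriorEntry:
    """One parameter's prior: kind in {"log", "flat", "fixed"}.

    "log" is the scale-free 1/x density truncated to [lo, hi];
    "flat" is uniform on [lo, hi]; "fixed" pins the parameter at
    ``value`` and removes it from sampling.
    """

    kind: str
    lo: float = 0.0
    hi: float = 0.0
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("log", "flat", "fixed"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None:
                raise ValueError("fixed prior needs a value")
            return
        if not self.lo < self.hi:
            raise ValueError("prior bounds must satisfy lo < hi")
        if self.kind == "log" and self.lo <= 0:
            raise ValueError("scale-free prior needs positive bounds")

    def logpdf(self, x: float) -> float:
        if self.kind == "fixed":
            return 0.0
        if not self.lo <= x <= self.hi:
            return -math.inf
        if self.kind == "log":
            return -math.log(x)
        return 0.0  # flat; normalisation constants dropped

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "log":
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        return float(rng.uniform(self.lo, self.hi))


PriorSpec = dict  # name -> PriorEntry


def default_priors() -> PriorSpec:
    """Proper, physically bounded defaults (all overridable)."""
    return {
        "lam1": PriorEntry("flat", 1e-6, 1.0),
        "lam2": PriorEntry("flat", 1e-6, 1.0),
        "f": PriorEntry("flat", -1e4, 1e4),
        "y0": PriorEntry("log", 1.0, 1e12),
        "alpha": PriorEntry("flat", 0.0, 1.0),
        "nu": PriorEntry("log", 1e-3, 1e3),
        "sigma_e0": PriorEntry("log", 1e-2, 1e6),
        "sigma_e1": PriorEntry("log", 1e-4, 1e3),
        "sigma_e2": PriorEntry("log", 1e-8, 10.0),
    }


@dataclass
class ParameterVector:
    """Per-cell heterogeneous blocks plus the shared homogeneous block."""

    het: np.ndarray  # (n_cells, 5) columns in HET_NAMES order
    shared: np.ndarray  # (4,) in SHARED_NAMES order

    def __post_init__(self) -> None:
        self.het = np.atleast_2d(np.asarray(self.het, dtype=float))
        self.shared = np.asarray(self.shared, dtype=float).reshape(4)

    @property
    def n_cells(self) -> int:
        return self.het.shape[0]

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.het.copy(), self.shared.copy())

    def as_series(self) -> dict[str, float]:
        out = {n: self.shared[j] for j, n in enumerate(SHARED_NAMES)}
        for m in range(self.n_cells):
            for j, n in enumerate(HET_NAMES):
                out[f"cell{m}_{n}"] = self.het[m, j]
        return out


@dataclass
class PosteriorSamples:
    """Thinned cold-chain draws plus run provenance and diagnostics."""

    samples: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def log_prior(p: ParameterVector, spec: PriorSpec) -> float:
    """Joint log prior; -inf outside any bound."""
    total = 0.0
    for j, name in enumerate(SHARED_NAMES):
        total += spec[name].logpdf(p.shared[j])
        if total == -math.inf:
            return total
    for m in range(p.n_cells):
        for j, name in enumerate(HET_NAMES):
            total += spec[name].logpdf(p.het[m, j])
            if total == -math.inf:
                return total
    return total


def _block_log_prior(values: np.ndarray, names: Sequence[str],
                     spec: PriorSpec) -> float:
    total = 0.0
    for v, name in zip(values, names):
        total += spec[name].logpdf(v)
        if total == -math.inf:
            break
    return total


# ---------------------------------------------------------------------------
# Likelihood plumbing


def make_cell_loglik(
    traces: Sequence[CellTrace],
    noise_model: str = "quadratic",
    drop_first: int = 0,
    clip: bool = True,
) -> tuple[Callable, int]:
    """Build ``cell_ll(het_row, shared, m) -> float`` over the traces.

    Data are frozen into arrays up front; ``drop_first`` discards the
    first k frames of every trace (the early frames can show anomalous
    fluctuations).  Returns (function, n_cells).
    """
    quadratic = noise_model == "quadratic"
    data = []
    for tr in traces:
        y = np.asarray(tr.values, dtype=float)[drop_first:]
        t = np.asarray(tr.times, dtype=float)[drop_first:]
        if y.size < 2:
            raise ValueError(f"trace {tr.cell_id} too short after frame drop")
        data.append((y, tuple(np.diff(t))))

    def cell_ll(het_row, shared, m: int) -> float:
        lam1, lam2, f, y0, alpha = het_row
        nu, s0, s1, s2 = shared
        if nu <= 0 or y0 <= 0:
            return -math.inf
        y, dts = data[m]
        return filter_loglik(
            y - f, dts, lam1, lam2, y0 / nu, alpha, nu,
            s0 * s0, s1 * s1, s2 * s2, quadratic, clip,
        )

    return cell_ll, len(data)


def _total_loglik(p: ParameterVector, cell_ll: Callable) -> np.ndarray:
    return np.array(
        [cell_ll(p.het[m], p.shared, m) for m in range(p.n_cells)]
    )


# ---------------------------------------------------------------------------
# Nested-optimisation initialisation


def _free(names: Sequence[str], spec: PriorSpec) -> list[str]:
    return [n for n in names if spec[n].kind != "fixed"]


def _to_opt(x: float, name: str) -> float:
    return math.log(x) if name in LOG_PROPOSAL else x


def _from_opt(z: float, name: str) -> float:
    return math.exp(z) if name in LOG_PROPOSAL else z


def _opt_bounds(name: str, spec: PriorSpec) -> tuple[float, float]:
    e = spec[name]
    if name in LOG_PROPOSAL:
        return math.log(e.lo), math.log(e.hi)
    return e.lo, e.hi


def _clip_to_prior(value: float, name: str, spec: PriorSpec) -> float:
    e = spec[name]
    if e.kind == "fixed":
        return float(e.value)
    margin = 1e-9 * (e.hi - e.lo)
    return float(np.clip(value, e.lo + margin, e.hi - margin))


def step1_biexp_starts(
    traces: Sequence[CellTrace], spec: PriorSpec, seed: int = 0
) -> np.ndarray:
    """Step 1: seed each cell's block from a bi-exponential fit."""
    het = np.empty((len(traces), 5))
    for m, tr in enumerate(traces):
        fit = fit_biexponential(tr, seed=seed + m)
        dt = tr.dt
        lam_slow, lam_fast = fit.rates(dt)
        amp = fit.a1 + fit.a2
        alpha = fit.a2 / amp if amp > 0 else 0.5
        raw = {
            "lam1": lam_slow,
            "lam2": lam_fast,
            "f": fit.a0,
            "y0": max(amp, 1.0),
            "alpha": alpha,
        }
        het[m] = [_clip_to_prior(raw[n], n, spec) for n in HET_NAMES]
    return het


def _optimize_cell(
    het_row: np.ndarray,
    shared: np.ndarray,
    m: int,
    cell_ll: Callable,
    spec: PriorSpec,
    rng: np.random.Generator,
    de_evals: int,
    optimize_shared: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: bounded global optimisation of one cell's full likelihood."""
    het_free = _free(HET_NAMES, spec)
    shared_free = _free(SHARED_NAMES, spec) if optimize_shared else []
    names = het_free + shared_free
    bounds = [_opt_bounds(n, spec) for n in names]

    def unpack(z):
        hr = het_row.copy()
        sh = shared.copy()
        for zi, n in zip(z, names):
            v = _from_opt(zi, n)
            if n in HET_NAMES:
                hr[HET_NAMES.index(n)] = v
            else:
                sh[SHARED_NAMES.index(n)] = v
        return hr, sh

    def neg(z):
        hr, sh = unpack(z)
        ll = cell_ll(hr, sh, m)
        lp = _block_log_prior(hr, HET_NAMES, spec) + _block_log_prior(
            sh, SHARED_NAMES, spec
        )
        val = ll + lp
        return -val if math.isfinite(val) else 1e12

    popsize = 10
    maxiter = max(de_evals // (popsize * len(names)), 3)
    res = optimize.differential_evolution(
        neg, bounds, seed=int(rng.integers(2**31 - 1)),
        popsize=popsize, maxiter=maxiter, tol=1e-3, polish=False, init="sobol",
    )
    x0 = np.array([_to_opt(v, n) for v, n in zip(
        list(het_row[[HET_NAMES.index(n) for n in het_free]])
        + list(shared[[SHARED_NAMES.index(n) for n in shared_free]])
        if names else [], names)])
    if x0.size and neg(x0) < res.fun:
        return unpack(x0)
    return unpack(res.x)


def _coordinate_ascent(
    p: ParameterVector,
    cell_lls: np.ndarray,
    cell_ll: Callable,
    spec: PriorSpec,
    max_sweeps: int = 5,
    tol: float = 1e-3,
) -> tuple[ParameterVector, np.ndarray, list[float]]:
    """Step 4: alternate shared-block and per-cell optimisation (Powell).

    The objective (log posterior) is non-decreasing across sweeps by
    construction: candidate moves are only accepted on improvement.
    """
    p = p.copy()
    shared_free = _free(SHARED_NAMES, spec)
    het_free = _free(HET_NAMES, spec)

    def objective(lls):
        return float(lls.sum()) + log_prior(p, spec)

    history = [objective(cell_lls)]
    for _ in range(max_sweeps):
        # shared block, heterogeneous fixed
        if shared_free:
            idx = [SHARED_NAMES.index(n) for n in shared_free]
            bounds = [_opt_bounds(n, spec) for n in shared_free]
            z0 = [_to_opt(p.shared[i], n) for i, n in zip(idx, shared_free)]

            def neg_shared(z):
                sh = p.shared.copy()
                for zi, i, n in zip(z, idx, shared_free):
                    sh[i] = _from_opt(zi, n)
                lp = _block_log_prior(sh, SHARED_NAMES, spec)
                if lp == -math.inf:
                    return 1e12
                ll = sum(cell_ll(p.het[m], sh, m) for m in range(p.n_cells))
                return -(ll + lp) if math.isfinite(ll) else 1e12

            res = optimize.minimize(neg_shared, z0, method="Powell",
                                    bounds=bounds,
                                    options={"maxiter": 50, "xtol": 1e-4})
            if -res.fun + _het_prior_total(p, spec) > history[-1]:
                for zi, i, n in zip(res.x, idx, shared_free):
                    p.shared[i] = _from_opt(zi, n)
        # per-cell blocks, shared fixed
        if het_free:
            idx = [HET_NAMES.index(n) for n in het_free]
            bounds = [_opt_bounds(n, spec) for n in het_free]
            for m in range(p.n_cells):
                z0 = [_to_opt(p.het[m, i], n) for i, n in zip(idx, het_free)]

                def neg_het(z, m=m):
                    hr = p.het[m].copy()
                    for zi, i, n in zip(z, idx, het_free):
                        hr[i] = _from_opt(zi, n)
                    lp = _block_log_prior(hr, HET_NAMES, spec)
                    if lp == -math.inf:
                        return 1e12
                    ll = cell_ll(hr, p.shared, m)
                    return -(ll + lp) if math.isfinite(ll) else 1e12

                base = neg_het(z0)
                res = optimize.minimize(neg_het, z0, method="Powell",
                                        bounds=bounds,
                                        options={"maxiter": 50, "xtol": 1e-4})
                if res.fun < base:
                    for zi, i, n in zip(res.x, idx, het_free):
                        p.het[m, i] = _from_opt(zi, n)
        cell_lls = _total_loglik(p, cell_ll)
        history.append(objective(cell_lls))
        if history[-1] - history[-2] < tol:
            break
    return p, cell_lls, history


def _het_prior_total(p: ParameterVector, spec: PriorSpec) -> float:
    return sum(
        _block_log_prior(p.het[m], HET_NAMES, spec) for m in range(p.n_cells)
    )


def _random_vector(n_cells: int, spec: PriorSpec,
                   rng: np.random.Generator) -> ParameterVector:
    het = np.array(
        [[spec[n].sample(rng) for n in HET_NAMES] for _ in range(n_cells)]
    )
    shared = np.array([spec[n].sample(rng) for n in SHARED_NAMES])
    return ParameterVector(het, shared)


def initialize(
    traces: Sequence[CellTrace],
    cell_ll: Callable,
    spec: PriorSpec,
    n_chains: int,
    rng: np.random.Generator,
    de_evals: int = 2000,
    ascent_sweeps: int = 5,
) -> tuple[list[ParameterVector], dict]:
    """Nested-optimisation chain starts (Steps 1-5).

    Half the chains start at the block-coordinate optimum reached from
    the data-driven seed; the other half at optima reached from random
    prior draws.  Per-cell optimiser failures fall back to the Step-1
    values (logged in the returned info dict).
    """
    n_cells = len(traces)
    info: dict = {"fallback_cells": [], "ascent_history": None}

    # Step 1: bi-exponential seeds
    het = step1_biexp_starts(traces, spec, seed=int(rng.integers(2**31 - 1)))
    shared0 = np.array(
        [spec[n].value if spec[n].kind == "fixed"
         else math.sqrt(spec[n].lo * spec[n].hi) if spec[n].kind == "log"
         else 0.5 * (spec[n].lo + spec[n].hi)
         for n in SHARED_NAMES]
    )

    # Step 2: independent full fits per cell
    per_cell_shared = np.empty((n_cells, 4))
    for m in range(n_cells):
        try:
            hr, sh = _optimize_cell(het[m], shared0, m, cell_ll, spec, rng,
                                    de_evals, optimize_shared=True)
            het[m], per_cell_shared[m] = hr, sh
        except Exception:
            info["fallback_cells"].append(m)
            per_cell_shared[m] = shared0

    # Step 3: medians of the shared parameters
    shared = np.median(per_cell_shared, axis=0)
    p = ParameterVector(het, shared)
    cell_lls = _total_loglik(p, cell_ll)

    # Step 4: block-coordinate ascent
    p_opt, lls_opt, history = _coordinate_ascent(
        p, cell_lls, cell_ll, spec, max_sweeps=ascent_sweeps
    )
    info["ascent_history"] = history

    # Step 5: half the chains at the optimum, half from random restarts
    starts = [p_opt.copy() for _ in range(n_chains - n_chains // 2)]
    while len(starts) < n_chains:
        q = _random_vector(n_cells, spec, rng)
        q_lls = _total_loglik(q, cell_ll)
        if np.all(np.isfinite(q_lls)):
            q, _, _ = _coordinate_ascent(q, q_lls, cell_ll, spec, max_sweeps=1)
        starts.append(q)
    return starts, info


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs and parallel tempering


@dataclass
class ChainState:
    params: ParameterVector
    cell_lls: np.ndarray
    beta: float = 1.0

    @property
    def loglik(self) -> float:
        return float(self.cell_lls.sum())


def _propose_block(
    values: np.ndarray,
    names: Sequence[str],
    spec: PriorSpec,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Random-walk proposal; returns (candidate, log Hastings correction)."""
    out = values.copy()
    logq = 0.0
    for j, name in enumerate(names):
        if spec[name].kind == "fixed":
            continue
        w = scale * BASE_WIDTH[name]
        if name in LOG_PROPOSAL:
            step = rng.normal(0.0, w)
            out[j] = values[j] * math.exp(step)
            logq += step  # q(x|x') / q(x'|x) = x'/x
        else:
            out[j] = values[j] + rng.normal(0.0, w)
    return out, logq


def gibbs_step(
    chain: ChainState,
    cell_ll: Callable,
    spec: PriorSpec,
    scale_het: float,
    scale_shared: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One Metropolis-within-Gibbs sweep, in place.

    Per-cell blocks are updated one cell at a time — only that cell's
    likelihood is recomputed — then the shared block against the full
    data.  Returns (het acceptances, shared acceptances 0/1).
    """
    p = chain.params
    beta = chain.beta
    acc_het = 0
    for m in range(p.n_cells):
        cand, logq = _propose_block(p.het[m], HET_NAMES, spec, scale_het, rng)
        lp_new = _block_log_prior(cand, HET_NAMES, spec)
        if lp_new == -math.inf:
            continue
        lp_old = _block_log_prior(p.het[m], HET_NAMES, spec)
        ll_new = cell_ll(cand, p.shared, m)
        if not math.isfinite(ll_new):
            continue
        log_alpha = beta * (ll_new - chain.cell_lls[m]) + lp_new - lp_old + logq
        if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
            p.het[m] = cand
            chain.cell_lls[m] = ll_new
            acc_het += 1

    acc_shared = 0
    cand, logq = _propose_block(p.shared, SHARED_NAMES, spec, scale_shared, rng)
    lp_new = _block_log_prior(cand, SHARED_NAMES, spec)
    if lp_new > -math.inf:
        lp_old = _block_log_prior(p.shared, SHARED_NAMES, spec)
        lls_new = np.array(
            [cell_ll(p.het[m], cand, m) for m in range(p.n_cells)]
        )
        if np.all(np.isfinite(lls_new)):
            log_alpha = (
                beta * (lls_new.sum() - chain.cell_lls.sum())
                + lp_new - lp_old + logq
            )
            if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
                p.shared = cand
                chain.cell_lls = lls_new
                acc_shared = 1
    return acc_het, acc_shared


def temper_and_swap(
    chains: list[ChainState], rng: np.random.Generator
) -> np.ndarray:
    """Propose adjacent-pair state swaps; returns accept flags per pair.

    The tempered acceptance ratio for neighbouring inverse temperatures
    is exp[(beta_k - beta_{k+1}) (L_{k+1} - L_k)] with L the (untempered)
    log likelihood — the priors are common to all chains and cancel.
    """
    accepted = np.zeros(max(len(chains) - 1, 0), dtype=bool)
    for k in range(len(chains) - 1):
        a, b = chains[k], chains[k + 1]
        log_alpha = (a.beta - b.beta) * (b.loglik - a.loglik)
        if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
            a.params, b.params = b.params, a.params
            a.cell_lls, b.cell_lls = b.cell_lls, a.cell_lls
            accepted[k] = True
    return accepted


def _adapt_ladder(
    betas: np.ndarray, swap_acc: np.ndarray, gamma: float,
    target: float = 0.234
) -> np.ndarray:
    """Stochastic-approximation update of the temperature ladder.

    The ladder is parameterised by the log spacings of the temperatures
    T_k = 1/beta_k; each spacing grows when its pair swaps too often and
    shrinks when it swaps too rarely, driving all pairs to the target.
    """
    T = 1.0 / betas
    spacings = np.log(np.diff(T))
    spacings += gamma * (swap_acc.astype(float) - target)
    T_new = np.concatenate([[1.0], 1.0 + np.cumsum(np.exp(spacings))])
    return 1.0 / T_new


def run_inference(
    traces: Sequence[CellTrace],
    *,
    priors: PriorSpec | None = None,
    noise_model: str = "quadratic",
    drop_first: int = 0,
    n_chains: int = 10,
    n_iter: int = 4000,
    burn_in: float = 0.5,
    thin_to: int = 10000,
    seed: int = 0,
    init: str = "nested",
    de_evals: int = 2000,
    target_accept: float = 0.234,
    t_max: float = 200.0,
    likelihood_on: bool = True,
    clip: bool = True,
) -> PosteriorSamples:
    """Sample the joint posterior over all per-cell and shared parameters.

    ``init="nested"`` uses the optimisation cascade; ``init="prior"``
    draws every chain from the prior (useful for sampler checks).
    ``likelihood_on=False`` targets the prior alone.  Adaptation of
    proposal scales and of the temperature ladder is diminishing and
    frozen at the end of burn-in, so post-burn-in samples target the
    correct posterior.  Reproducible for a fixed seed.
    """
    spec = default_priors() if priors is None else {**default_priors(), **priors}
    rng = np.random.default_rng(seed)
    cell_ll_real, n_cells = make_cell_loglik(traces, noise_model, drop_first, clip)
    if likelihood_on:
        cell_ll = cell_ll_real
    else:
        def cell_ll(het_row, shared, m):  # prior-only target
            return 0.0

    if init == "nested" and likelihood_on:
        starts, init_info = initialize(
            traces, cell_ll, spec, n_chains, rng, de_evals=de_evals
        )
    elif init in ("prior", "nested"):
        starts = [_random_vector(n_cells, spec, rng) for _ in range(n_chains)]
        init_info = {"mode": "prior draws"}
    else:
        raise ValueError("init must be 'nested' or 'prior'")

    betas = (
        1.0 / np.geomspace(1.0, t_max, n_chains)
        if n_chains > 1
        else np.array([1.0])
    )
    chains = [
        ChainState(p, _total_loglik(p, cell_ll), beta=b)
        for p, b in zip(starts, betas)
    ]
    for c in chains:
        if not np.all(np.isfinite(c.cell_lls)):
            raise RuntimeError("non-finite likelihood at a chain start")

    burn = int(burn_in * n_iter)
    scale_het = np.ones(n_chains)
    scale_shared = np.ones(n_chains)
    swap_counts = np.zeros(max(n_chains - 1, 0))
    swap_trials = 0
    kept_rows: list[dict] = []
    keep_every = max((n_iter - burn) // max(thin_to, 1), 1)
    acc_het_total = np.zeros(n_chains)
    acc_shared_total = np.zeros(n_chains)
    nan_streak = 0

    for it in range(n_iter):
        for k, chain in enumerate(chains):
            a_h, a_s = gibbs_step(
                chain, cell_ll, spec, scale_het[k], scale_shared[k], rng
            )
            acc_het_total[k] += a_h
            acc_shared_total[k] += a_s
            if it < burn:  # Robbins-Monro, diminishing and frozen after burn-in
                gamma = 0.5 / (1.0 + it) ** 0.6
                scale_het[k] *= math.exp(
                    gamma * (a_h / max(chain.params.n_cells, 1) - target_accept)
                )
                scale_shared[k] *= math.exp(gamma * (a_s - target_accept))
        if n_chains > 1:
            acc = temper_and_swap(chains, rng)
            swap_counts += acc
            swap_trials += 1
            if it < burn and it > 10:
                gamma = 1.0 / (1.0 + it) ** 0.6
                betas = _adapt_ladder(betas, acc, gamma)
                for c, b in zip(chains, betas):
                    c.beta = b
        cold = chains[0]
        if not np.all(np.isfinite(cold.cell_lls)):
            nan_streak += 1
            if nan_streak > 50:
                raise RuntimeError(
                    "persistent non-finite likelihood; state: "
                    + str(cold.params.as_series())
                )
        else:
            nan_streak = 0
        if it >= burn and (it - burn) % keep_every == 0:
            row = cold.params.as_series()
            row["loglik"] = cold.loglik
            kept_rows.append(row)

    n_post = n_iter - burn
    diagnostics = {
        "accept_het": (acc_het_total / (n_iter * max(n_cells, 1))).tolist(),
        "accept_shared": (acc_shared_total / n_iter).tolist(),
        "swap_rates": (
            (swap_counts / max(swap_trials, 1)).tolist() if n_chains > 1 else []
        ),
        "betas": betas.tolist(),
        "scale_het": scale_het.tolist(),
        "scale_shared": scale_shared.tolist(),
        "init": init_info,
        "n_kept": len(kept_rows),
        "n_post_burn_in": n_post,
    }
    provenance = {
        "seed": seed,
        "n_chains": n_chains,
        "n_iter": n_iter,
        "burn_in": burn_in,
        "noise_model": noise_model,
        "drop_first": drop_first,
        "n_cells": n_cells,
    }
    return PosteriorSamples(
        samples=pd.DataFrame(kept_rows),
        diagnostics=diagnostics,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Model / Results interface


class BleachingModel:
    """Bayesian bleaching model: LNA dynamics + Kalman likelihood + MCMC.

    Parameters
    ----------
    traces : sequence of CellTrace
        Corrected traces (autofluorescence handled via the per-cell
        residual offset f, which is inferred).
    priors : dict, optional
        Overrides of :func:`default_priors` (name -> PriorEntry).
    noise_model : {"quadratic", "constant"}
    drop_first : int
        Frames to ignore at the start of every trace.
    """

    def __init__(
        self,
        traces: Sequence[CellTrace],
        *,
        priors: PriorSpec | None = None,
        noise_model: str = "quadratic",
        drop_first: int = 0,
    ) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.priors = priors
        self.noise_model = noise_model
        self.drop_first = drop_first

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "BleachingModel":
        from .io import traces_from_frame

        return cls(traces_from_frame(df), **kwargs)

    def fit(self, **kwargs) -> "BleachingResults":
        """Run the sampler; keyword arguments pass to :func:`run_inference`."""
        post = run_inference(
            self.traces,
            priors=self.priors,
            noise_model=self.noise_model,
            drop_first=self.drop_first,
            **kwargs,
        )
        return BleachingResults(model=self, posterior=post)


@dataclass
class BleachingResults:
    """Posterior samples with summaries and molecule-number conversion."""

    model: BleachingModel
    posterior: PosteriorSamples

    @property
    def samples(self) -> pd.DataFrame:
        return self.posterior.samples

    def credible_interval(self, name: str, level: float = 0.95
                          ) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        q = self.samples[name].quantile([a, 1.0 - a])
        return float(q.iloc[0]), float(q.iloc[1])

    def noise_params(self) -> NoiseParams:
        """Posterior-median homogeneous parameters."""
        med = self.samples[list(SHARED_NAMES)].median()
        return NoiseParams(
            nu=med["nu"], sigma_e0=med["sigma_e0"],
            sigma_e1=med["sigma_e1"], sigma_e2=med["sigma_e2"],
        )

    def number_posterior(self, y: float, grid_size: int = 1024):
        from .posterior import number_posterior_single

        return number_posterior_single(y, self.samples, grid_size=grid_size)

    def population_mean_posterior(self, mean_y: float, n_cells: int,
                                  mean_f: float = 0.0, grid_size: int = 1024):
        from .posterior import population_mean_posterior

        return population_mean_posterior(
            mean_y, mean_f, n_cells, self.samples, grid_size=grid_size
        )

    def summary(self) -> str:
        lines = [
            "Bleaching-model posterior (Kalman-filter likelihood)",
            "====================================================",
            f"cells: {self.posterior.provenance['n_cells']}   "
            f"chains: {self.posterior.provenance['n_chains']}   "
            f"kept draws: {len(self.samples)}",
            "",
            f"{'parameter':<12}{'median':>12}{'2.5%':>12}{'97.5%':>12}",
        ]
        for name in SHARED_NAMES:
            lo, hi = self.credible_interval(name)
            med = self.samples[name].median()
            lines.append(f"{name:<12}{med:>12.4g}{lo:>12.4g}{hi:>12.4g}")
        acc = self.posterior.diagnostics["accept_shared"]
        lines.append("")
        lines.append(f"cold-chain shared-block acceptance: {acc[0]:.2f}")
        if self.posterior.diagnostics["swap_rates"]:
            sr = np.mean(self.posterior.diagnostics["swap_rates"])
            lines.append(f"mean adjacent swap rate: {sr:.2f}")
        return "\n".join(lines)
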