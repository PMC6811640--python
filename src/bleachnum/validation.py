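"""Study-condition validation experiments with known ground truth.

Each function reproduces one quantitative check of the methodology on
synthetic data generated by :mod:`bleachnum.simulate`: the algebraic
identity and maximum-likelihood property of the pair estimator, the
heterogeneity/noise bias law, the equivalence of the Kalman filter with
its dense joint-Gaussian oracle and of the LNA closed forms with the
moment ODEs, order-of-magnitude recovery of absolute numbers across four
decades, and frequentist calibration of the Bayesian route's credible
intervals.  They are deliberately plain functions so that the same code
drives both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimator import (
    BiasInputs,
    FluctuationModel,
    mle_x0,
    molecules_from_concentration,
    pair_estimate,
    predicted_bias,
)
from .io import traces_from_frame
from .kalman import (
    GaussianState,
    ObservationModel,
    integrate_moment_odes,
    joint_gaussian_loglik,
    lna_propagate,
    loglikelihood,
)
from .mcmc import BleachingModel, PriorEntry
from .preprocess import CellTrace
from .simulate import (
    CellParams,
    NoiseParams,
    add_noise,
    default_times,
    simulate_cohort,
    simulate_pools,
)

__all__ = [
    "fus3_reference_count",
    "estimator_identity_max_rel_error",
    "mle_equivalence_rel_error",
    "bias_law_grid",
    "kalman_oracle_errors",
    "recovery_experiment",
    "mcmc_coverage",
]


def fus3_reference_count(
    cytoplasm_nM: float = 180.0,
    nucleus_factor: float = 3.0,
    cell_volume_fl: float = 42.0,
    nuclear_volume_fl: float = 3.0,
) -> float:
    """Fus3 copy number implied by its FCS concentration measurement.

    Cytoplasmic concentration over the cell volume net of the nucleus,
    plus the three-fold higher nuclear concentration over the nuclear
    volume.
    """
    cyto = molecules_from_concentration(
        cytoplasm_nM, cell_volume_fl - nuclear_volume_fl
    )
    nuc = molecules_from_concentration(
        nucleus_factor * cytoplasm_nM, nuclear_volume_fl
    )
    return cyto + nuc


def estimator_identity_max_rel_error() -> float:
    """Max relative error of the estimator identity on a parameter grid.

    With exact moments E[Y]=nu*x0*l and Var[Y]=nu^2*x0*l(1-l) the pair
    estimator must return x0 for every survival l, brightness nu and x0.
    """
    worst = 0.0
    for ell in np.arange(0.01, 0.995, 0.01):
        for nu in (0.1, 1.0, 100.0):
            for x0 in (1e2, 1e6):
                est = pair_estimate(
                    nu * x0, nu * x0 * ell, nu**2 * x0 * ell * (1 - ell)
                )
                worst = max(worst, abs(est - x0) / x0)
    return worst


def mle_equivalence_rel_error(
    y0: float = 2e4, mu_y: float = 1.2e4, var_y: float = 8e4
) -> float:
    """Relative distance between the likelihood peak and the estimator.

    The explicit likelihood (delta constraints marginalised numerically)
    is maximised over x0 and compared with the closed-form estimator on
    one worked instance.
    """
    direct = pair_estimate(y0, mu_y, var_y)
    numeric = mle_x0(y0, mu_y, var_y)
    return abs(numeric - direct) / direct


def bias_law_grid(
    n_reps: int = 1000,
    x0: int = 10_000,
    seed: int = 0,
    noise_levels: tuple = (0.0, 50.0, 200.0),
    cv_levels: tuple = (0.0, 0.25, 0.5),
) -> dict:
    """Monte-Carlo test of the heterogeneity/noise bias law on a grid.

    ``noise_levels`` are sigma_e^2 / x0 values; ``cv_levels`` are
    coefficients of variation of a Gamma brightness distribution with
    mean 20.  Survival is Beta(20, 20) (centred on one half).  For each
    grid cell the mean of the ensemble estimator over ``n_reps``
    replicate ensembles is compared with the predicted x0 / (1 + eps),
    and the sign of the empirical bias with the sign of eps.

    Returns the worst |empirical - predicted| / SE over the grid, the
    number of decidable cells whose sign matches, and the per-cell table.
    """
    rng = np.random.default_rng(seed)
    ell_dist = stats.beta(20.0, 20.0)
    rows = []
    worst_z = 0.0
    signs_ok = decidable = 0
    for cv in cv_levels:
        nu_dist = (
            20.0 if cv == 0.0
            else stats.gamma(1.0 / cv**2, scale=20.0 * cv**2)
        )
        for noise in noise_levels:
            sigma_e2 = noise * x0
            b = BiasInputs.from_independent(nu_dist, ell_dist, sigma_e2, x0)
            eps, implied = predicted_bias(b)
            nus = (
                np.full((n_reps, x0), 20.0) if cv == 0.0
                else nu_dist.rvs((n_reps, x0), random_state=rng)
            )
            ells = ell_dist.rvs((n_reps, x0), random_state=rng)
            num = (nus * ells).sum(axis=1) * (nus - nus * ells).sum(axis=1)
            den = sigma_e2 + (nus**2 * ells * (1 - ells)).sum(axis=1)
            draws = num / den
            se = draws.std(ddof=1) / np.sqrt(n_reps)
            z = abs(draws.mean() - implied) / se
            worst_z = max(worst_z, z)
            if abs(implied - x0) > 3 * se:
                decidable += 1
                if np.sign(draws.mean() - x0) == -np.sign(eps):
                    signs_ok += 1
            rows.append({
                "cv": cv, "noise": noise, "eps": eps,
                "implied": implied, "empirical": float(draws.mean()),
                "se": float(se), "z": float(z),
            })
    return {
        "max_z": float(worst_z),
        "signs_ok": signs_ok,
        "decidable": decidable,
        "cells": rows,
    }


def kalman_oracle_errors(n_instances: int = 50, seed: int = 0) -> dict:
    """Filter vs dense joint Gaussian, and closed forms vs moment ODEs.

    Random two-pool instances of 10 frames with constant noise and mean
    clipping disabled: the filter log likelihood must equal the dense
    multivariate-normal evaluation; the closed-form propagation must
    equal high-accuracy integration of the moment ODEs.
    """
    rng = np.random.default_rng(seed)
    t = default_times(10)
    filter_err = 0.0
    lna_err = 0.0
    for _ in range(n_instances):
        cell = CellParams(
            lambda1=rng.uniform(1e-4, 5e-3),
            lambda2=rng.uniform(5e-3, 2e-2),
            x0=int(rng.integers(100, 10_000)),
            alpha=rng.uniform(0.0, 1.0),
        )
        noise = NoiseParams(nu=rng.uniform(5, 30),
                            sigma_e0=rng.uniform(50, 200))
        y = add_noise(simulate_pools(cell, t, rng).total, cell, noise, rng)
        tr = CellTrace("c", t, y)
        obs = ObservationModel(noise, noise_model="constant")
        fl = loglikelihood(tr, cell, obs, clip=False).loglik
        dense = joint_gaussian_loglik(tr, cell, obs)
        filter_err = max(filter_err, abs(fl - dense))

        state = GaussianState(
            rng.uniform(10, 2000, 2), np.diag(rng.uniform(0, 100, 2))
        )
        dt = rng.uniform(1.0, 100.0)
        a = lna_propagate(state, cell, dt)
        b = integrate_moment_odes(state, cell, dt)
        lna_err = max(
            lna_err,
            float(np.max(np.abs(a.mu - b.mu))),
            float(np.max(np.abs(a.Sigma - b.Sigma))),
        )
    return {"filter_max_abs_error": filter_err, "lna_max_abs_error": lna_err}


def recovery_experiment(
    x0_values: tuple = (1e3, 1e4, 1e5, 1e6),
    n_cells: int = 150,
    seed: int = 0,
) -> dict:
    """Order-of-magnitude recovery of absolute numbers across decades.

    Simulates heterogeneous bi-exponential cohorts (45 frames, 10 s)
    with realistic camera noise at each x0, runs the full fluctuation
    pipeline, and reports the pooled mode and its log10 error.
    """
    out = {}
    for i, x0 in enumerate(x0_values):
        df, truth = simulate_cohort(n_cells, x0, seed=seed + i)
        traces = traces_from_frame(df)
        res = FluctuationModel(traces, seed=seed + i).fit()
        true_mean = float(np.mean(
            [c["x0"] for c in truth["cells"].values()]
        ))
        out[x0] = {
            "mode": res.mode,
            "truth": true_mean,
            "log10_error": float(np.log10(res.mode / true_mean)),
            "n_estimates": res.n_estimates,
        }
    return out


def _calibration_priors() -> dict:
    return {
        "lam1": PriorEntry("flat", 1e-4, 0.1),
        "lam2": PriorEntry("fixed", value=1e-3),
        "f": PriorEntry("fixed", value=0.0),
        "alpha": PriorEntry("fixed", value=0.0),
        "y0": PriorEntry("log", 1e2, 1e8),
        "nu": PriorEntry("log", 1.0, 1e3),
        "sigma_e0": PriorEntry("log", 1.0, 1e4),
        "sigma_e1": PriorEntry("fixed", value=1e-3),
        "sigma_e2": PriorEntry("fixed", value=1e-6),
    }


def mcmc_coverage(
    n_reps: int = 100,
    seed: int = 0,
    n_cells: int = 3,
    n_frames: int = 45,
    n_iter: int = 1200,
    n_chains: int = 2,
    level: float = 0.95,
) -> dict:
    """Frequentist coverage of the credible interval for the brightness.

    Repeatedly simulates well-specified single-pool cohorts (binomial
    bleaching, constant Gaussian noise, nu = 20), runs the reduced-scale
    sampler, and counts how often the central ``level`` interval for nu
    contains the truth.
    """
    nu_true = 20.0
    priors = _calibration_priors()
    times = default_times(n_frames)
    noise = NoiseParams(nu=nu_true, sigma_e0=136.6)
    covered = 0
    widths = []
    master = np.random.SeedSequence(seed)
    for rep_seq in master.spawn(n_reps):
        rng = np.random.default_rng(rep_seq)
        traces = []
        for i in range(n_cells):
            cell = CellParams(
                lambda1=rng.uniform(3e-3, 6e-3), lambda2=1e-3,
                x0=int(rng.uniform(1500, 3000)), alpha=0.0,
            )
            y = add_noise(
                simulate_pools(cell, times, rng).total, cell, noise, rng
            )
            traces.append(CellTrace(f"c{i}", times, y))
        res = BleachingModel(
            traces, priors=priors, noise_model="constant"
        ).fit(
            n_chains=n_chains, n_iter=n_iter,
            seed=int(rng.integers(2**31 - 1)),
            de_evals=200, t_max=10.0,
        )
        lo, hi = res.credible_interval("nu", level)
        covered += int(lo <= nu_true <= hi)
        widths.append(hi - lo)
    return {
        "covered": covered,
        "n_reps": n_reps,
        "coverage": covered / n_reps,
        "median_width": float(np.median(widths)),
    }
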