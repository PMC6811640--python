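"""Sampler correctness: priors, detailed balance, tempering, recovery."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from bleachnum.mcmc import (
    ChainState,
    ParameterVector,
    PriorEntry,
    _total_loglik,
    default_priors,
    gibbs_step,
    initialize,
    log_prior,
    make_cell_loglik,
    run_inference,
    step1_biexp_starts,
    temper_and_swap,
    BleachingModel,
)
from bleachnum.preprocess import CellTrace
from bleachnum.simulate import (
    CellParams,
    NoiseParams,
    add_noise,
    default_times,
    simulate_pools,
)


def make_traces(n_cells=2, n_frames=12, seed=0, x0=2000, sigma_e0=136.6):
    rng = np.random.default_rng(seed)
    times = default_times(n_frames)
    noise = NoiseParams(nu=20.0, sigma_e0=sigma_e0)
    traces, cells = [], []
    for i in range(n_cells):
        cell = CellParams(lambda1=rng.uniform(3e-3, 6e-3), lambda2=1e-3,
                          x0=x0, alpha=0.0)
        y = add_noise(simulate_pools(cell, times, rng).total, cell, noise, rng)
        traces.append(CellTrace(f"c{i}", times, y))
        cells.append(cell)
    return traces, cells, noise


def single_pool_priors():
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


def toy_chain(het, shared=None, beta=1.0, cell_ll=None):
    p = ParameterVector(np.atleast_2d(het),
                        shared if shared is not None else
                        np.array([20.0, 100.0, 1.0, 0.001]))
    lls = _total_loglik(p, cell_ll) if cell_ll else np.zeros(p.n_cells)
    return ChainState(p, lls, beta=beta)


class TestLogPrior:
    def test_scale_free_prior_halves_on_doubling(self):
        spec = default_priors()
        p1 = ParameterVector(
            np.array([[1e-3, 1e-2, 0.0, 1e4, 0.5]]),
            np.array([10.0, 100.0, 1.0, 0.001]),
        )
        p2 = p1.copy()
        p2.shared[0] *= 2.0  # nu
        assert log_prior(p1, spec) - log_prior(p2, spec) == pytest.approx(
            math.log(2.0)
        )

    def test_flat_parameter_move_leaves_prior_unchanged(self):
        spec = default_priors()
        p1 = ParameterVector(
            np.array([[1e-3, 1e-2, 0.0, 1e4, 0.5]]),
            np.array([10.0, 100.0, 1.0, 0.001]),
        )
        p2 = p1.copy()
        p2.het[0, 2] = 500.0  # f, flat prior
        assert log_prior(p1, spec) == log_prior(p2, spec)

    def test_proper_bounds(self):
        spec = default_priors()
        inside = ParameterVector(
            np.array([[1e-3, 1e-2, 0.0, 1e4, 0.5]]),
            np.array([1e-3 + 1e-9, 100.0, 1.0, 0.001]),
        )
        outside = inside.copy()
        outside.shared[0] = 1e-4  # below the nu bound
        assert np.isfinite(log_prior(inside, spec))
        assert log_prior(outside, spec) == -math.inf


class TestGibbsStep:
    def test_vanishing_proposal_scale_accepts_everything(self):
        traces, _, _ = make_traces(seed=1)
        cell_ll, _ = make_cell_loglik(traces, "constant")
        spec = single_pool_priors()
        chain = toy_chain(
            [[5e-3, 1e-3, 0.0, 4e4, 0.0], [5e-3, 1e-3, 0.0, 4e4, 0.0]],
            np.array([20.0, 136.6, 1e-3, 1e-6]),
            cell_ll=cell_ll,
        )
        rng = np.random.default_rng(0)
        acc_h = acc_s = 0
        for _ in range(50):
            h, s = gibbs_step(chain, cell_ll, spec, 1e-9, 1e-9, rng)
            acc_h += h
            acc_s += s
        assert acc_h == 100 and acc_s == 50

    def test_prior_target_accepts_in_bounds_moves(self):
        # flat priors with symmetric proposals, and 1/x priors with
        # log-normal proposals, both give unit Metropolis ratios
        spec = single_pool_priors()

        def flat_ll(het_row, shared, m):
            return 0.0

        chain = toy_chain([[5e-3, 1e-3, 0.0, 1e4, 0.0]],
                          np.array([20.0, 100.0, 1e-3, 1e-6]))
        rng = np.random.default_rng(1)
        accepted = sum(
            gibbs_step(chain, flat_ll, spec, 0.3, 0.3, rng)[0]
            for _ in range(200)
        )
        # the only rejections are bound violations
        assert accepted > 180

    def test_updating_one_cell_touches_only_its_likelihood(self):
        traces, _, _ = make_traces(n_cells=3, seed=2)
        cell_ll, _ = make_cell_loglik(traces, "constant")
        spec = single_pool_priors()
        chain = toy_chain(
            [[5e-3, 1e-3, 0.0, 4e4, 0.0]] * 3,
            np.array([20.0, 136.6, 1e-3, 1e-6]),
            cell_ll=cell_ll,
        )
        rng = np.random.default_rng(3)
        for _ in range(30):
            gibbs_step(chain, cell_ll, spec, 1.0, 1.0, rng)
        recomputed = _total_loglik(chain.params, cell_ll)
        np.testing.assert_allclose(chain.cell_lls, recomputed, atol=1e-12)

    def test_detailed_balance_on_gaussian_toy_target(self):
        # 2-parameter analytic target; frozen scales; chi^2 on a 10x10
        # equal-probability grid of thinned samples
        spec = single_pool_priors()
        spec["y0"] = PriorEntry("fixed", value=1e4)
        target_lam = stats.norm(5e-3, 1e-3)
        target_f = stats.norm(0.0, 50.0)
        spec["f"] = PriorEntry("flat", -1e4, 1e4)

        def toy_ll(het_row, shared, m):
            return float(target_lam.logpdf(het_row[0])
                         + target_f.logpdf(het_row[2]))

        chain = toy_chain([[5e-3, 1e-3, 0.0, 1e4, 0.0]])
        chain.cell_lls = np.array([toy_ll(chain.params.het[0], None, 0)])
        rng = np.random.default_rng(4)
        lam_s, f_s = [], []
        thin = 20
        for it in range(120_000):
            gibbs_step(chain, toy_ll, spec, 6.0, 1e-9, rng)
            if it % thin == 0 and it > 4000:
                lam_s.append(chain.params.het[0, 0])
                f_s.append(chain.params.het[0, 2])
        edges_lam = target_lam.ppf(np.linspace(0, 1, 11))
        edges_f = target_f.ppf(np.linspace(0, 1, 11))
        counts, _, _ = np.histogram2d(lam_s, f_s, bins=[edges_lam, edges_f])
        expected = len(lam_s) / 100.0
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2(99).sf(chi2)
        assert p > 0.01


class TestTempering:
    def test_identical_chains_always_swap(self):
        cell_ll = None
        a = toy_chain([[5e-3, 1e-3, 0.0, 1e4, 0.0]], beta=1.0)
        b = toy_chain([[5e-3, 1e-3, 0.0, 1e4, 0.0]], beta=0.5)
        a.cell_lls = np.array([-10.0])
        b.cell_lls = np.array([-10.0])
        rng = np.random.default_rng(5)
        accepted = [temper_and_swap([a, b], rng)[0] for _ in range(20)]
        assert all(accepted)

    def test_infinite_temperature_chain_samples_the_prior(self):
        # beta = 0 removes the likelihood: nu follows its 1/x prior
        traces, _, _ = make_traces(seed=6)
        cell_ll, _ = make_cell_loglik(traces, "constant")
        spec = single_pool_priors()
        chain = toy_chain(
            [[5e-3, 1e-3, 0.0, 4e4, 0.0], [5e-3, 1e-3, 0.0, 4e4, 0.0]],
            np.array([20.0, 136.6, 1e-3, 1e-6]),
            beta=0.0,
            cell_ll=cell_ll,
        )
        rng = np.random.default_rng(7)
        nus = []
        # large shared scale: with unit acceptance inside the bounds the
        # log-space walk decorrelates in a few steps
        for it in range(30_000):
            gibbs_step(chain, cell_ll, spec, 3.0, 60.0, rng)
            if it % 20 == 0 and it > 2000:
                nus.append(chain.params.shared[0])
        # 1/x prior on [1, 1e3] means log(nu) is uniform
        ks = stats.kstest(
            np.log(nus), stats.uniform(0.0, math.log(1e3)).cdf
        )
        assert ks.pvalue > 0.01

    def test_swaps_rescue_mixing_on_a_bimodal_target(self):
        spec = single_pool_priors()
        spec["y0"] = PriorEntry("fixed", value=1e4)
        spec["lam1"] = PriorEntry("fixed", value=5e-3)
        spec["f"] = PriorEntry("flat", -1e4, 1e4)

        def bimodal_ll(het_row, shared, m):
            f = het_row[2]
            return float(logsumexp([
                stats.norm(-300.0, 30.0).logpdf(f),
                stats.norm(300.0, 30.0).logpdf(f),
            ]))

        def run(n_chains):
            betas = np.geomspace(1.0, 1e-3, n_chains)
            chains = []
            for b in betas:
                c = toy_chain([[5e-3, 1e-3, -300.0, 1e4, 0.0]], beta=b)
                c.cell_lls = np.array([bimodal_ll(c.params.het[0], None, 0)])
                chains.append(c)
            rng = np.random.default_rng(8)
            signs = []
            for _ in range(4000):
                for c in chains:
                    gibbs_step(c, bimodal_ll, spec, 3.0, 1e-9, rng)
                if n_chains > 1:
                    temper_and_swap(chains, rng)
                signs.append(np.sign(chains[0].params.het[0, 2]))
            return int(np.abs(np.diff(signs)).sum() // 2)

        assert run(4) > 10 * max(run(1), 1)


class TestInitialize:
    def test_biexp_seeds_within_prior_bounds(self):
        traces, _, _ = make_traces(n_cells=3, n_frames=20, seed=9)
        spec = single_pool_priors()
        het = step1_biexp_starts(traces, spec)
        assert het.shape == (3, 5)
        assert np.all(het[:, 0] >= 1e-4) and np.all(het[:, 0] <= 0.1)
        assert np.all(het[:, 3] > 0)

    def test_ascent_is_monotone_and_beats_truth_on_easy_data(self):
        traces, cells, noise = make_traces(
            n_cells=2, n_frames=20, seed=10, sigma_e0=50.0
        )
        cell_ll, _ = make_cell_loglik(traces, "constant")
        spec = single_pool_priors()
        rng = np.random.default_rng(11)
        starts, info = initialize(traces, cell_ll, spec, 2, rng,
                                  de_evals=600, ascent_sweeps=3)
        hist = info["ascent_history"]
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))
        truth = ParameterVector(
            np.array([[c.lambda1, 1e-3, 0.0, noise.nu * c.x0, 0.0]
                      for c in cells]),
            np.array([noise.nu, noise.sigma_e0, 1e-3, 1e-6]),
        )
        ll_truth = _total_loglik(truth, cell_ll).sum() + log_prior(truth, spec)
        ll_opt = (_total_loglik(starts[0], cell_ll).sum()
                  + log_prior(starts[0], spec))
        assert ll_opt >= ll_truth - 1e-3

    def test_step3_median_of_symmetric_values_is_midpoint(self):
        vals = np.array([[1.0], [3.0], [5.0]])
        assert np.median(vals, axis=0)[0] == 3.0


class TestRunInference:
    def test_reproducible_under_seed(self):
        traces, _, _ = make_traces(seed=12)
        kwargs = dict(
            priors=single_pool_priors(), noise_model="constant",
            n_chains=2, n_iter=150, seed=5, init="prior", t_max=10.0,
        )
        a = run_inference(traces, **kwargs)
        b = run_inference(traces, **kwargs)
        assert a.samples.equals(b.samples)

    def test_prior_only_run_reproduces_priors(self):
        traces, _, _ = make_traces(seed=13)
        post = run_inference(
            traces, priors=single_pool_priors(), likelihood_on=False,
            init="prior", n_chains=2, n_iter=6000, seed=2, t_max=10.0,
        )
        nu = post.samples["nu"].to_numpy()[::3]
        ks = stats.kstest(np.log(nu), stats.uniform(0.0, math.log(1e3)).cdf)
        assert ks.pvalue > 0.01
        alpha_vals = post.samples["cell0_alpha"].unique()
        assert list(alpha_vals) == [0.0]  # fixed parameters stay fixed

    def test_single_cell_identifiable_y0_recovered(self):
        traces, cells, noise = make_traces(n_cells=1, n_frames=45, seed=14)
        true_y0 = noise.nu * cells[0].x0
        res = BleachingModel(
            traces, priors=single_pool_priors(), noise_model="constant"
        ).fit(n_chains=2, n_iter=1500, seed=3, de_evals=300, t_max=10.0)
        med = res.samples["cell0_y0"].median()
        assert abs(med - true_y0) / true_y0 < 0.10
        assert "nu" in res.summary()

    def test_diagnostics_and_provenance_recorded(self):
        traces, _, _ = make_traces(seed=15)
        post = run_inference(
            traces, priors=single_pool_priors(), noise_model="constant",
            n_chains=3, n_iter=120, seed=1, init="prior", t_max=20.0,
        )
        d = post.diagnostics
        assert len(d["betas"]) == 3
        assert d["betas"][0] == 1.0 and d["betas"][1] < 1.0
        assert len(d["swap_rates"]) == 2
        assert post.provenance["n_cells"] == 2
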