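"""Linear-noise model of two-pool bleaching and its Kalman likelihood.

Under the linear noise approximation the state of a cell — the numbers
(x1, x2) of unbleached molecules in two pools decaying at rates
(lambda1, lambda2) — is Gaussian with mean mu and covariance Sigma that
obey the moment ODEs

    d mu_i / dt     = -lambda_i * mu_i
    d Sigma_ii / dt = -2 lambda_i Sigma_ii + lambda_i mu_i
    d Sigma_12 / dt = -(lambda1 + lambda2) Sigma_12

whose solution over an interval t is closed form:

    mu_i(t)     = mu_i(0) exp(-lambda_i t)
    Sigma_ii(t) = Sigma_ii(0) e^{-2 lambda_i t}
                  + e^{-lambda_i t} (1 - e^{-lambda_i t}) mu_i(0)
    Sigma_12(t) = Sigma_12(0) e^{-(lambda1 + lambda2) t}

Within the filter the variance source term (lambda_i * mu_i, the shot
noise of bleaching events) is driven by the data-independent LNA mean
trajectory rather than the filtered mean: the process noise is then
state-independent and the filter is *exact* inference in one joint
Gaussian model — the same model ``joint_gaussian_loglik`` evaluates
densely — instead of an approximation whose implied joint density
depends on the data.  The filtered mean itself is of course
data-conditioned as usual.

A fluorescence frame observes y = U x + f + noise with U = [nu, nu] and
noise variance either constant (sigma_e0^2) or quadratic in the signal,
``sigma_e0^2 + nu*x*sigma_e1^2 + (nu*x*sigma_e2)^2``; the quadratic case
is handled by replacing the state-dependent variance with its
expectation under the one-step-ahead prediction.  The filter alternates
closed-form propagation and the linear-Gaussian update, accumulating the
log likelihood as the sum of one-step predictive log densities.  The
initial state is a delta at (x0*(1-alpha), x0*alpha) with zero
covariance, so the first predictive variance is the noise variance
alone.  Negative posterior mean components (possible with noisy data)
are clipped to zero.

``joint_gaussian_loglik`` evaluates the same constant-noise model as one
dense multivariate normal over the whole trace — an independent route
used to validate the filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from scipy.integrate import solve_ivp

from .preprocess import CellTrace
from .simulate import CellParams, NoiseParams

__all__ = [
    "GaussianState",
    "ObservationModel",
    "FilterResult",
    "lna_propagate",
    "moment_odes",
    "effective_noise_variance",
    "kalman_update",
    "loglikelihood",
    "filter_loglik",
    "joint_gaussian_loglik",
]


@dataclass
class GaussianState:
    """Gaussian state of the two pools: mean 2-vector and 2x2 covariance."""

    mu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.Sigma = np.asarray(self.Sigma, dtype=float).reshape(2, 2)

    def validate(self, tol: float = 1e-10) -> None:
        if not np.allclose(self.Sigma, self.Sigma.T, atol=tol):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma).min() < -tol:
            raise ValueError("Sigma must be positive semi-definite")


@dataclass(frozen=True)
class ObservationModel:
    """Fluorescence observation y = [nu nu] . x + f + noise.

    ``noise_model`` selects the constant-variance filter (sigma_e0 only)
    or the quadratic mean-dependent variance.
    """

    noise: NoiseParams
    f: float = 0.0
    noise_model: str = "quadratic"

    def __post_init__(self) -> None:
        if self.noise_model not in ("quadratic", "constant"):
            raise ValueError("noise_model must be 'quadratic' or 'constant'")


@dataclass
class FilterResult:
    """Filter output: total log likelihood plus per-step states."""

    loglik: float
    predicted: list[GaussianState]
    updated: list[GaussianState]
    predictive_mean: np.ndarray
    predictive_var: np.ndarray


def lna_propagate(
    state: GaussianState,
    cell: CellParams,
    dt: float,
    source_mean: np.ndarray | None = None,
) -> GaussianState:
    """Closed-form propagation of the Gaussian state over an interval dt.

    ``source_mean`` optionally supplies the mean trajectory driving the
    bleaching shot-noise term (the filter passes the data-independent
    prior mean there); by default the state's own mean is used, which
    matches the self-consistent moment ODEs.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    e1 = math.exp(-cell.lambda1 * dt)
    e2 = math.exp(-cell.lambda2 * dt)
    m1, m2 = state.mu
    q1, q2 = state.mu if source_mean is None else source_mean
    s = state.Sigma
    mu = np.array([m1 * e1, m2 * e2])
    Sigma = np.array(
        [
            [s[0, 0] * e1 * e1 + e1 * (1 - e1) * q1, s[0, 1] * e1 * e2],
            [s[0, 1] * e1 * e2, s[1, 1] * e2 * e2 + e2 * (1 - e2) * q2],
        ]
    )
    return GaussianState(mu, Sigma)


def moment_odes(
    mu: np.ndarray, Sigma: np.ndarray, cell: CellParams
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives of the mean and covariance for two-pool decay.

    These are the generic LNA moment equations dmu/dt = S^T h and
    dSigma/dt = J Sigma + Sigma J^T + S^T H S specialised to the two
    first-order bleaching reactions (S = -I, h = (l1*x1, l2*x2)).
    """
    lam = np.array([cell.lambda1, cell.lambda2])
    dmu = -lam * np.asarray(mu, dtype=float)
    J = np.diag(-lam)
    H = np.diag(lam * np.asarray(mu, dtype=float))
    S = -np.eye(2)
    dSigma = J @ Sigma + Sigma @ J.T + S.T @ H @ S
    return dmu, dSigma


def integrate_moment_odes(
    state: GaussianState, cell: CellParams, dt: float, rtol: float = 1e-12
) -> GaussianState:
    """Numerically integrate the moment ODEs (validation route for the
    closed-form propagation)."""

    def rhs(_t, z):
        mu = z[:2]
        Sigma = np.array([[z[2], z[3]], [z[3], z[4]]])
        dmu, dS = moment_odes(mu, Sigma, cell)
        return [dmu[0], dmu[1], dS[0, 0], dS[0, 1], dS[1, 1]]

    z0 = [state.mu[0], state.mu[1],
          state.Sigma[0, 0], state.Sigma[0, 1], state.Sigma[1, 1]]
    sol = solve_ivp(rhs, (0.0, dt), z0, rtol=rtol, atol=1e-12, method="DOP853")
    z = sol.y[:, -1]
    return GaussianState(np.array(z[:2]), np.array([[z[2], z[3]], [z[3], z[4]]]))


def effective_noise_variance(state: GaussianState, obs: ObservationModel) -> float:
    """Constant-variance stand-in for the state-dependent noise.

    The quadratic variance is averaged over the predicted state:
    E[sigma0^2 + U x sigma1^2 + (U x sigma2)^2]
      = sigma0^2 + U mu sigma1^2 + U (mu mu^T + Sigma) U^T sigma2^2.
    """
    n = obs.noise
    if obs.noise_model == "constant":
        return n.sigma_e0**2
    nu = n.nu
    mtot = float(state.mu.sum())
    stot = float(state.Sigma.sum())
    return (
        n.sigma_e0**2
        + nu * mtot * n.sigma_e1**2
        + nu**2 * (mtot**2 + stot) * n.sigma_e2**2
    )


def kalman_update(
    state: GaussianState,
    y: float,
    obs: ObservationModel,
    V: float,
    clip: bool = True,
) -> GaussianState:
    """Linear-Gaussian measurement update with scalar innovation.

    Sigma is updated in Joseph-stabilised form (algebraically equal to
    the textbook Sigma - K U Sigma).  Negative posterior mean components
    are clipped to zero when ``clip``; Sigma is left untouched.
    """
    if V <= 0:
        raise ValueError("observation-noise variance must be positive")
    nu = obs.noise.nu
    U = np.array([nu, nu])
    S = float(U @ state.Sigma @ U + V)
    innov = y - float(U @ state.mu)
    if not np.isfinite(innov):
        raise ValueError("non-finite innovation")
    K = state.Sigma @ U / S
    mu = state.mu + K * innov
    A = np.eye(2) - np.outer(K, U)
    Sigma = A @ state.Sigma @ A.T + V * np.outer(K, K)
    Sigma = 0.5 * (Sigma + Sigma.T)
    if clip:
        mu = np.maximum(mu, 0.0)
    return GaussianState(mu, Sigma)


def loglikelihood(
    trace: CellTrace,
    cell: CellParams,
    obs: ObservationModel,
    clip: bool = True,
) -> FilterResult:
    """Kalman-filter log likelihood of one cell's trace.

    The residual autofluorescence ``obs.f`` is subtracted from the data
    before filtering.  Per-step predicted and updated states are stored;
    use :func:`filter_loglik` when only the scalar is needed.
    """
    times = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float) - obs.f
    n1, n2 = cell.pool_counts
    state = GaussianState(np.array([float(n1), float(n2)]), np.zeros((2, 2)))
    prior_mean = state.mu.copy()  # data-independent trajectory for shot noise
    predicted, updated = [], []
    pm = np.empty(y.size)
    pv = np.empty(y.size)
    ll = 0.0
    nu = obs.noise.nu
    U = np.array([nu, nu])
    lam = np.array([cell.lambda1, cell.lambda2])
    for i, yi in enumerate(y):
        if i > 0:
            dt = times[i] - times[i - 1]
            state = lna_propagate(state, cell, dt, source_mean=prior_mean)
            prior_mean = prior_mean * np.exp(-lam * dt)
        predicted.append(state)
        V = effective_noise_variance(state, obs)
        S = float(U @ state.Sigma @ U + V)
        if S <= 0:
            raise ValueError("non-positive predictive variance (sigma_e0 = 0?)")
        mean = float(U @ state.mu)
        pm[i], pv[i] = mean, S
        ll += -0.5 * (math.log(2.0 * math.pi * S) + (yi - mean) ** 2 / S)
        state = kalman_update(state, yi, obs, V, clip=clip)
        updated.append(state)
    if not np.isfinite(ll):
        raise ValueError("non-finite log likelihood")
    return FilterResult(ll, predicted, updated, pm, pv)


def filter_loglik(
    y: np.ndarray,
    dts: np.ndarray,
    lam1: float,
    lam2: float,
    x0: float,
    alpha: float,
    nu: float,
    s0sq: float,
    s1sq: float,
    s2sq: float,
    quadratic: bool = True,
    clip: bool = True,
) -> float:
    """Scalar fast path of :func:`loglikelihood`.

    Same recursion with the 2x2 algebra unrolled to plain floats — the
    posterior sampler calls this millions of times, where array overhead
    at this size dominates the arithmetic.  ``y`` must already have the
    autofluorescence subtracted; ``dts`` are the inter-frame intervals.
    """
    m1 = x0 * (1.0 - alpha)
    m2 = x0 * alpha
    p1, p2 = m1, m2  # data-independent prior means driving the shot noise
    s11 = s12 = s22 = 0.0
    ll = 0.0
    log2pi = math.log(2.0 * math.pi)
    n = len(y)
    for i in range(n):
        if i > 0:
            dt = dts[i - 1]
            e1 = math.exp(-lam1 * dt)
            e2 = math.exp(-lam2 * dt)
            s11 = s11 * e1 * e1 + e1 * (1.0 - e1) * p1
            s22 = s22 * e2 * e2 + e2 * (1.0 - e2) * p2
            s12 = s12 * e1 * e2
            m1 *= e1
            m2 *= e2
            p1 *= e1
            p2 *= e2
        mtot = m1 + m2
        stot = s11 + 2.0 * s12 + s22
        if quadratic:
            V = s0sq + nu * mtot * s1sq + nu * nu * (mtot * mtot + stot) * s2sq
        else:
            V = s0sq
        S = nu * nu * stot + V
        if S <= 0.0 or not math.isfinite(S):
            return -math.inf
        r = y[i] - nu * mtot
        ll += -0.5 * (log2pi + math.log(S) + r * r / S)
        # gain K = Sigma U^T / S with U = [nu, nu]
        a1 = nu * (s11 + s12)
        a2 = nu * (s12 + s22)
        k1 = a1 / S
        k2 = a2 / S
        m1 += k1 * r
        m2 += k2 * r
        # Joseph form: (I - K U) Sigma (I - K U)^T + V K K^T
        b11 = 1.0 - k1 * nu
        b12 = -k1 * nu
        b21 = -k2 * nu
        b22 = 1.0 - k2 * nu
        c11 = b11 * s11 + b12 * s12
        c12 = b11 * s12 + b12 * s22
        c21 = b21 * s11 + b22 * s12
        c22 = b21 * s12 + b22 * s22
        s11 = c11 * b11 + c12 * b12 + V * k1 * k1
        s12 = c11 * b21 + c12 * b22 + V * k1 * k2
        s22 = c21 * b21 + c22 * b22 + V * k2 * k2
        if clip:
            if m1 < 0.0:
                m1 = 0.0
            if m2 < 0.0:
                m2 = 0.0
    if not math.isfinite(ll):
        return -math.inf
    return ll


def joint_gaussian_loglik(
    trace: CellTrace, cell: CellParams, obs: ObservationModel
) -> float:
    """Dense-covariance evaluation of the constant-noise model.

    Builds the joint normal of the whole observation vector directly —
    mean nu*(mu1(t)+mu2(t)), covariance from the closed-form pool
    variances with cross-time terms Cov[X_s, X_t] = e^{-lam(t-s)} Var[X_s]
    for s <= t — and evaluates one multivariate-normal density.  Agrees
    with the filter exactly when no mean clipping fires.
    """
    if obs.noise_model != "constant":
        raise ValueError("dense evaluation only defined for constant noise")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float) - obs.f
    nu = obs.noise.nu
    n1, n2 = cell.pool_counts
    mean = np.zeros(t.size)
    C = np.zeros((t.size, t.size))
    early = np.minimum.outer(np.arange(t.size), np.arange(t.size))
    for x0p, lam in ((n1, cell.lambda1), (n2, cell.lambda2)):
        ell = np.exp(-lam * t)
        mean += nu * x0p * ell
        var = x0p * ell * (1.0 - ell)
        # Cov[X_s, X_t] = e^{-lam (t - s)} Var[X_s], s <= t
        decay = np.exp(-lam * np.abs(t[:, None] - t[None, :]))
        C += nu**2 * decay * var[early]
    C += obs.noise.sigma_e0**2 * np.eye(t.size)
    return float(_sps.multivariate_normal(mean=mean, cov=C).logpdf(y))
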