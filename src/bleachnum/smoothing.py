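"""Gaussian-process smoothing of per-cell bleaching traces.

The fluctuation estimator needs E[Y_t], the underlying mean fluorescence
at each frame, which we obtain by GP regression with a squared-
exponential covariance ``k(t, t') = theta0 * exp(-theta1 (t-t')^2 / 2)``
plus i.i.d. observation noise theta2.  Hyperparameters are found by
maximising the marginal likelihood inside hard box bounds:

    1e3  < theta0 < 1e14   (signal variance, camera units^2)
    1e-8 < theta1 < 1      (inverse squared length-scale, 1/s^2)
    10   < theta2 < 1e10   (observation-noise variance)

theta2 controls how much of the frame-to-frame scatter is attributed to
measurement noise rather than to the mean; it is the knob that sets the
bias direction of the downstream molecule-number estimate.  The
per-frame fluctuation variance is then the squared residual
``(y_t - E[Y_t])^2``.

Hyperparameter optimisation is delegated to scikit-learn's
GaussianProcessRegressor (restarts sample uniformly in the log of each
bound interval); the posterior mean at the observed times is computed in
closed form from the fitted kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .preprocess import CellTrace

__all__ = [
    "GPHyperparams",
    "SmoothedTrace",
    "BOUNDS",
    "fit_gp",
    "predict_mean",
    "residual_variance",
    "smooth_trace",
]

#: hard box bounds for (theta0, theta1, theta2)
BOUNDS = {
    "theta0": (1e3, 1e14),
    "theta1": (1e-8, 1.0),
    "theta2": (10.0, 1e10),
}


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential kernel hyperparameters (see module docstring)."""

    theta0: float
    theta1: float
    theta2: float
    n_restarts: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("theta0", "theta1", "theta2"):
            lo, hi = BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v:g} outside bounds [{lo:g}, {hi:g}]")

    @property
    def length_scale(self) -> float:
        """Kernel length-scale in seconds (theta1 = 1/length_scale^2)."""
        return float(1.0 / np.sqrt(self.theta1))


@dataclass(frozen=True)
class SmoothedTrace:
    """Per-frame mean and fluctuation-variance estimates for one cell."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.mean) == len(self.var)):
            raise ValueError("times, mean, var must have equal length")
        if np.any(np.asarray(self.var) < 0):
            raise ValueError("variance estimates must be non-negative")


def _kernel_matrix(t: np.ndarray, hyper: GPHyperparams) -> np.ndarray:
    d2 = (t[:, None] - t[None, :]) ** 2
    return hyper.theta0 * np.exp(-0.5 * hyper.theta1 * d2)


def fit_gp(trace: CellTrace, n_restarts: int = 5, seed: int = 0) -> GPHyperparams:
    """Maximise the GP marginal likelihood within the box bounds.

    The trace is mean-centred before fitting (the GP prior mean is zero).
    """
    y = np.asarray(trace.values, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if y.size < 10:
        raise ValueError("GP smoothing needs at least 10 time points")
    yc = y - y.mean()

    t0_lo, t0_hi = BOUNDS["theta0"]
    t1_lo, t1_hi = BOUNDS["theta1"]
    t2_lo, t2_hi = BOUNDS["theta2"]
    theta0_init = float(np.clip(yc.var(), t0_lo * 1.01, t0_hi * 0.99))
    theta2_init = float(
        np.clip(0.5 * np.mean(np.diff(yc) ** 2), t2_lo * 1.01, t2_hi * 0.99)
    )
    # length-scale bounds: l = theta1**-0.5, so bounds invert and swap
    kernel = (
        ConstantKernel(theta0_init, (t0_lo, t0_hi))
        * RBF(100.0, (t1_hi**-0.5, t1_lo**-0.5))
        + WhiteKernel(theta2_init, (t2_lo, t2_hi))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=0.0,
        n_restarts_optimizer=n_restarts,
        normalize_y=False,
        random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(t[:, None], yc)
        k = gpr.kernel_
        theta0 = float(k.k1.k1.constant_value)
        ls = float(k.k1.k2.length_scale)
        theta2 = float(k.k2.noise_level)
        converged = True
    except Exception:
        theta0, ls, theta2 = theta0_init, 100.0, theta2_init
        converged = False
    eps = 1e-12
    theta0 = float(np.clip(theta0, t0_lo + eps, t0_hi))
    theta1 = float(np.clip(ls**-2, t1_lo + eps, t1_hi))
    theta2 = float(np.clip(theta2, t2_lo + eps, t2_hi))
    return GPHyperparams(theta0, theta1, theta2,
                         n_restarts=n_restarts, converged=converged)


def predict_mean(trace: CellTrace, hyper: GPHyperparams) -> np.ndarray:
    """GP posterior mean at the observed times.

    The centring offset removed before fitting is restored, so the output
    is on the scale of the data.  A small jitter is added if the noisy
    kernel matrix is not numerically positive definite.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    yc = y - y.mean()
    K = _kernel_matrix(t, hyper)
    Kn = K + hyper.theta2 * np.eye(t.size)
    for jitter in (0.0, 1e-10, 1e-6):
        try:
            c = cho_factor(Kn + jitter * np.trace(Kn) / t.size * np.eye(t.size))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("kernel matrix not positive definite")
    return K @ cho_solve(c, yc) + y.mean()


def residual_variance(trace: CellTrace, mean: np.ndarray) -> np.ndarray:
    """Per-frame fluctuation variance estimate: (y_t - E[Y_t])^2."""
    y = np.asarray(trace.values, dtype=float)
    m = np.asarray(mean, dtype=float)
    if y.shape != m.shape:
        raise ValueError("mean must align with the trace")
    return (y - m) ** 2


def smooth_trace(trace: CellTrace, n_restarts: int = 5,
                 seed: int = 0) -> tuple[SmoothedTrace, GPHyperparams]:
    """Fit hyperparameters, predict the mean and derive variances."""
    hyper = fit_gp(trace, n_restarts=n_restarts, seed=seed)
    mean = predict_mean(trace, hyper)
    var = residual_variance(trace, mean)
    return SmoothedTrace(times=trace.times, mean=mean, var=var), hyper
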