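"""Trace corrections, the cell-fluorescence summary and per-cell fits.

The correction arithmetic follows the standard wide-field workflow:
element-wise flat-field division, background subtraction from a cell-free
region, then subtraction of the per-time-point mean of bleached wild-type
(non-fluorescent) cells to remove autofluorescence.  Cell fluorescence is
summarised as the sum of the brightest 80% of in-mask pixels.  Each
corrected trace can be fitted with a bi-exponential decay
``f_i = a0 + a1*l1^i + a2*l2^i`` over frame index i, and cells with
sudden single-frame drops are rejected by a robust QC rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CellTrace",
    "BiExpFit",
    "flatfield_correct",
    "background_subtract",
    "cell_fluorescence",
    "autofluorescence_correct",
    "fit_biexponential",
    "qc_filter",
]


@dataclass(frozen=True)
class CellTrace:
    """One cell's time-stamped fluorescence values."""

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    corrections: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"times not strictly increasing for {self.cell_id}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite fluorescence for {self.cell_id}")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if self.times.size > 1 else math.nan

    def with_values(self, values: np.ndarray, correction: str) -> "CellTrace":
        return replace(
            self, values=np.asarray(values, float),
            corrections=self.corrections + (correction,),
        )


@dataclass(frozen=True)
class BiExpFit:
    """Bi-exponential decay fit f_i = a0 + a1*l1^i + a2*l2^i.

    l1 >= l2 by convention (slow component first); ``rates(dt)`` converts
    the per-frame survival factors to rates in 1/s.
    """

    a0: float
    a1: float
    a2: float
    ell1: float
    ell2: float
    rss: float
    converged: bool = True

    def predict(self, i: np.ndarray) -> np.ndarray:
        i = np.asarray(i, dtype=float)
        return self.a0 + self.a1 * self.ell1**i + self.a2 * self.ell2**i

    def rates(self, dt: float) -> tuple[float, float]:
        return -math.log(self.ell1) / dt, -math.log(self.ell2) / dt


def flatfield_correct(pixels: np.ndarray, flatfield: np.ndarray) -> np.ndarray:
    """Divide an image element-wise by the (median-1-normalised) flat field."""
    pixels = np.asarray(pixels, dtype=float)
    flatfield = np.asarray(flatfield, dtype=float)
    if pixels.shape != flatfield.shape:
        raise ValueError("pixels and flatfield shapes differ")
    if np.any(flatfield <= 0):
        raise ValueError("flat field must be strictly positive everywhere")
    return pixels / flatfield


def background_subtract(values: np.ndarray, background_level: float) -> np.ndarray:
    """Subtract the mean pixel value of a cell-free region.

    Negative results are preserved; the noise model has support for
    negative fluorescence.
    """
    if not np.isfinite(background_level):
        raise ValueError("background level must be finite")
    return np.asarray(values, dtype=float) - background_level


def cell_fluorescence(pixels: Iterable[float], fraction: float = 0.8) -> float:
    """Sum of the brightest ``fraction`` of in-mask pixels (count ceiled)."""
    px = np.asarray(list(pixels) if not isinstance(pixels, np.ndarray) else pixels,
                    dtype=float).ravel()
    if px.size == 0:
        raise ValueError("empty pixel mask")
    k = math.ceil(fraction * px.size)
    return float(np.sort(px)[::-1][:k].sum())


def autofluorescence_correct(
    traces: Sequence[CellTrace], wildtype_traces: Sequence[CellTrace]
) -> list[CellTrace]:
    """Subtract the per-time-point mean of wild-type cells from every trace."""
    if not wildtype_traces:
        raise ValueError("need at least one wild-type trace")
    grid = wildtype_traces[0].times
    for wt in wildtype_traces:
        if wt.times.shape != grid.shape or not np.allclose(wt.times, grid):
            raise ValueError("wild-type traces do not share one time grid")
    mean_af = np.mean([wt.values for wt in wildtype_traces], axis=0)
    out = []
    for tr in traces:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise ValueError(f"trace {tr.cell_id} not on the wild-type time grid")
        out.append(tr.with_values(tr.values - mean_af, "autofluorescence"))
    return out


def _biexp_residuals(p: np.ndarray, i: np.ndarray, y: np.ndarray) -> np.ndarray:
    a0, a1, a2, l1, l2 = p
    return a0 + a1 * l1**i + a2 * l2**i - y


def _loglinear_rate(y: np.ndarray) -> float:
    """Per-frame survival from a log-linear fit; ignores non-positive y."""
    i = np.arange(y.size, dtype=float)
    pos = y > 0
    if pos.sum() < 2:
        return 0.9
    slope = np.polyfit(i[pos], np.log(y[pos]), 1)[0]
    return float(np.clip(np.exp(slope), 1e-6, 1.0))


def fit_biexponential(trace: CellTrace, n_restarts: int = 3,
                      seed: int = 0) -> BiExpFit:
    """Least-squares bi-exponential fit over the frame index.

    Initialised from log-linear fits of the first and last thirds of the
    trace, with bounded parameters (0 < l <= 1) and multi-start restarts
    on failure.  Non-convergence is flagged, not raised.
    """
    y = np.asarray(trace.values, dtype=float)
    n = y.size
    if n < 6:
        raise ValueError("bi-exponential fit needs at least 6 time points")
    i = np.arange(n, dtype=float)

    third = max(n // 3, 2)
    l_fast = _loglinear_rate(y[:third])
    l_slow = _loglinear_rate(y[-third:])
    amp = max(y[0] - y[-1], 1.0)
    starts = [np.array([max(y[-1], 0.0), amp / 2, amp / 2,
                        min(max(l_slow, l_fast), 1.0), min(l_slow, l_fast)])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(np.array([
            y[-1] * rng.uniform(0, 2),
            amp * rng.uniform(0.1, 1.0),
            amp * rng.uniform(0.1, 1.0),
            rng.uniform(0.9, 1.0),
            rng.uniform(0.3, 0.95),
        ]))

    lo = [-np.inf, 0.0, 0.0, 1e-9, 1e-9]
    hi = [np.inf, np.inf, np.inf, 1.0, 1.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(_biexp_residuals, p0, args=(i, y),
                                bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and best.cost <= sol.cost and sol.cost < 1e-20:
            break
    if best is None:
        return BiExpFit(y[-1], 0.0, 0.0, 1.0, 1.0,
                        rss=float(np.sum((y - y[-1]) ** 2)), converged=False)
    a0, a1, a2, l1, l2 = best.x
    if l2 > l1:  # canonical ordering: slow component first
        a1, a2, l1, l2 = a2, a1, l2, l1
    return BiExpFit(a0, a1, a2, l1, l2, rss=float(2 * best.cost),
                    converged=bool(best.success))


def qc_filter(
    traces: Sequence[CellTrace], drop_threshold: float = 5.0
) -> tuple[list[CellTrace], dict[str, str]]:
    """Reject cells with large systematic deviations (sudden drops).

    A cell is rejected when any frame drops below the local trend by
    more than ``drop_threshold`` robust standard deviations.  The trend
    is a centred 5-frame rolling median, which follows bleaching decay
    of any curvature but ignores isolated outlier frames; residuals are
    standardised by a local noise scale (the larger of a rolling MAD of
    the residuals and a second-difference noise estimate, both over 9
    frames) because the measurement noise shrinks as the cell bleaches.
    Set the threshold to ``inf`` to disable.
    Returns (kept, rejection log).
    """
    kept: list[CellTrace] = []
    rejected: dict[str, str] = {}
    for tr in traces:
        y = tr.values
        if y.size < 7 or not np.isfinite(drop_threshold):
            kept.append(tr)
            continue
        trend = (
            pd.Series(y).rolling(5, center=True, min_periods=2).median()
        ).to_numpy()
        dev = y - trend
        local_mad = (
            pd.Series(np.abs(dev))
            .rolling(9, center=True, min_periods=4)
            .median()
            .to_numpy()
        )
        # second differences cancel the local linear trend; their median
        # absolute value estimates the per-frame noise sd robustly
        d2 = np.abs(np.diff(y, 2))
        sigma2 = (
            pd.Series(d2).rolling(9, center=True, min_periods=4).median()
        ).to_numpy() / (0.6745 * np.sqrt(6.0))
        sigma2 = np.pad(sigma2, 1, mode="edge")
        scale = np.maximum(1.4826 * local_mad, np.maximum(sigma2, 1e-12))
        r = dev / scale
        # the centred trend is unreliable in the first/last two frames,
        # where ongoing decay itself would register as a drop
        r = r[2:-2]
        worst = -r.min() if r.min() < 0 else 0.0
        if worst > drop_threshold:
            i = int(np.argmin(r)) + 2
            rejected[tr.cell_id] = (
                f"sudden drop at frame {i}: {worst:.2f} robust standard "
                f"deviations below the local trend (threshold {drop_threshold:g})"
            )
        else:
            kept.append(tr)
    return kept, rejected
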