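"""Trace CSV input/output, run configuration, and result serialisation.

Traces travel as long-format CSV with columns ``cell_id, time_s,
fluorescence`` (one row per cell per frame); posterior samples as CSV
with one row per draw; results as JSON with an embedded configuration
hash and seed so every output can be traced to the run that made it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import CellTrace

__all__ = [
    "RunConfig",
    "read_traces",
    "traces_from_frame",
    "write_traces",
    "write_results",
]

REQUIRED_COLUMNS = ("cell_id", "time_s", "fluorescence")


@dataclass
class RunConfig:
    """All run-level knobs with their defaults.

    Defaults mirror the standard experiment: frames every 10 s, 45 of
    them; 10 tempered chains; GP hyperparameter box bounds fixed in
    :mod:`bleachnum.smoothing`; posterior-KDE kernel sd 0.1 (log space).
    """

    seed: int = 0
    dt: float = 10.0
    n_frames: int = 45
    drop_first: int = 0
    y0_convention: str = "smoothed"
    qc_threshold: float = 5.0
    gp_restarts: int = 5
    min_positive: int = 30
    noise_model: str = "quadratic"
    n_chains: int = 10
    n_iter: int = 4000
    burn_in: float = 0.5
    sigma_k: float = 0.1
    prior_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_frames < 2:
            raise ValueError("dt must be positive and n_frames >= 2")
        if self.drop_first < 0 or self.drop_first >= self.n_frames:
            raise ValueError("drop_first out of range")
        if self.y0_convention not in ("smoothed", "raw"):
            raise ValueError("y0_convention must be 'smoothed' or 'raw'")
        if self.noise_model not in ("quadratic", "constant"):
            raise ValueError("noise_model must be 'quadratic' or 'constant'")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in must lie in [0, 1)")
        if self.n_chains < 1 or self.n_iter < 1:
            raise ValueError("n_chains and n_iter must be positive")
        if self.qc_threshold <= 0:
            raise ValueError("qc_threshold must be positive (inf disables)")
        if self.sigma_k <= 0 or self.gp_restarts < 0 or self.min_positive < 1:
            raise ValueError("invalid configuration value")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def traces_from_frame(df: pd.DataFrame, dt: float | None = None,
                      rtol: float = 1e-6) -> list[CellTrace]:
    """Group a long-format frame into time-sorted CellTrace objects.

    Order-independent; duplicate (cell, time) pairs and non-numeric
    values are reported with the offending cell / rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    values = pd.to_numeric(df["fluorescence"], errors="coerce")
    bad = df.index[times.isna() | values.isna()]
    if len(bad):
        raise ValueError(f"non-numeric values in rows {list(bad[:10])}")
    out = []
    work = df.assign(time_s=times, fluorescence=values)
    for cid, grp in work.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicate timestamps for cell {cid!r}")
        if dt is not None and t.size > 1:
            if not np.allclose(np.diff(t), dt, rtol=rtol, atol=rtol * dt):
                raise ValueError(
                    f"cell {cid!r} not uniformly sampled at dt={dt}"
                )
        out.append(
            CellTrace(str(cid), t, grp["fluorescence"].to_numpy(dtype=float))
        )
    return out


def read_traces(path, dt: float | None = None) -> list[CellTrace]:
    """Read a trace CSV (cell_id, time_s, fluorescence)."""
    return traces_from_frame(pd.read_csv(path), dt=dt)


def write_traces(traces, path) -> None:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "time_s": tr.times, "fluorescence": tr.values,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict, path, config: RunConfig | None = None) -> None:
    """Write a results JSON with the config hash and seed embedded."""
    payload = {"results": _jsonable(results)}
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_hash"] = config.hash()
        payload["seed"] = config.seed
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
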