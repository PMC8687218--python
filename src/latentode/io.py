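"""Data containers, CSV I/O, and run configuration.

Time-series tables are plain CSV: a ``time`` column followed by one
column per component, one row per observation time. Rows of the
in-memory table correspond one-to-one to model components; unobserved
components carry NaN entries and are flagged in ``observed_mask``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ParseError

__all__ = [
    "TimeSeriesData",
    "read_timeseries",
    "write_timeseries",
    "RunConfig",
    "load_run_config",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeSeriesData:
    """Observed time courses of a network.

    ``values`` has shape (N, n+1); ``truth``, present for synthetic data,
    bundles the noise-free trajectories, the generating latent signal and
    weights, the rate draw and the seed.
    """

    times: np.ndarray
    values: np.ndarray
    component_names: tuple = None
    observed_mask: np.ndarray = None
    noise_kind: Optional[str] = None
    sigma: Optional[float] = None
    truth: Optional[dict] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ParseError("times must be strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise ParseError("value columns must match the time grid")
        n = self.values.shape[0]
        if self.component_names is None:
            self.component_names = tuple(f"x{i + 1}" for i in range(n))
        self.component_names = tuple(self.component_names)
        if len(self.component_names) != n:
            raise ParseError("component names must match the value rows")
        if self.observed_mask is None:
            self.observed_mask = np.ones(n, dtype=bool)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        obs = self.values[self.observed_mask]
        if np.any(~np.isfinite(obs)):
            raise ParseError("observed components contain missing entries")
        if self.noise_kind == "lognormal" and np.any(obs <= 0):
            raise ParseError("lognormal data must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def observed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.observed_mask)


def read_timeseries(path) -> TimeSeriesData:
    """Read a ``time,<c1>,...,<cN>`` CSV into a :class:`TimeSeriesData`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0].strip().lower() != "time":
        raise ParseError("first column must be named 'time'", column=0)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy()
                             & frame[col].notna().to_numpy())
        if bad.size or converted.isna().any():
            row = int(bad[0]) if bad.size else int(
                np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(
                f"non-numeric or missing cell in column {col!r}",
                row=row, column=col,
            )
        frame[col] = converted
    times = frame.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise ParseError(f"times not strictly increasing at row {row}",
                         row=row, column="time")
    values = frame.iloc[:, 1:].to_numpy(dtype=float).T
    return TimeSeriesData(times=times, values=values,
                          component_names=tuple(frame.columns[1:]))


def write_timeseries(path, data: TimeSeriesData) -> None:
    frame = pd.DataFrame({"time": data.times})
    for name, row in zip(data.component_names, data.values):
        frame[name] = row
    frame.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every knob has an explicit default."""

    data: Optional[str] = None
    model: Optional[dict] = None
    noise_kind: str = "normal"
    k_dim: Optional[int] = None
    lambda_grid: Optional[list] = None
    strategy: str = "forward"
    criterion: str = "bic"
    observed: Optional[list] = None
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.seed is None or int(self.seed) < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        self.seed = int(self.seed)
        if self.noise_kind not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown noise kind {self.noise_kind!r}")
        if self.strategy not in ("best_subset", "forward", "backward"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.criterion not in ("aic", "bic"):
            raise ConfigurationError(f"unknown criterion {self.criterion!r}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if cfg.data is not None and not Path(cfg.data).exists():
        raise ConfigurationError(f"data file {cfg.data} does not exist")
    return cfg
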