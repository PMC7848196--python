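"""Continuous-time forcing signals built from 30-min samples.

The model is driven by three measured inputs — physical activity ``A``,
plasma norepinephrine ``NE`` and glycemia ``glc`` — sampled every 30 min
over 24 h (48 nodes). ODE integration needs the signals at arbitrary
times, so each is lifted to a continuous function of t by interpolation.
The default is a monotone piecewise cubic (PCHIP), which passes through
every sample exactly and cannot undershoot below the sample range, so
nonnegative samples yield nonnegative signals. Signals are treated as
24 h-periodic: the node at t=24 repeats the midnight sample, and
evaluation wraps modulo 24 so burn-in over several days is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, interp1d

from .exceptions import DomainError, InvalidConfigError

INTERP_MODES = ("pchip", "linear", "zoh")

SIGNAL_NAMES = ("A", "NE", "glc")


def half_hour_grid(n: int = 48, step: float = 0.5) -> np.ndarray:
    """The canonical 24-h sampling grid: t = 0, 0.5, ..., 23.5 h."""
    return np.arange(n) * step


def _build_interpolant(grid: np.ndarray, samples: np.ndarray, mode: str):
    # close the 24-h period so t in (grid[-1], 24] is covered
    tg = np.append(grid, 24.0)
    ys = np.append(samples, samples[0])
    if mode == "pchip":
        return PchipInterpolator(tg, ys, extrapolate=False)
    if mode == "linear":
        return interp1d(tg, ys, kind="linear", bounds_error=True)
    if mode == "zoh":
        return interp1d(tg, ys, kind="previous", bounds_error=True)
    raise InvalidConfigError(f"unknown interpolation mode {mode!r}")


@dataclass
class InputSignals:
    """Evaluable 24-h trajectories of activity, norepinephrine, glycemia.

    Parameters
    ----------
    grid : array of sample times in hours (strictly increasing, in [0, 24))
    A, NE, glc : samples on ``grid``; A must be >= 0, NE and glc > 0
    mode : interpolation mode, one of "pchip", "linear", "zoh"
    """

    grid: np.ndarray
    A: np.ndarray
    NE: np.ndarray
    glc: np.ndarray
    mode: str = "pchip"
    group: str = "dipper"
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise InvalidConfigError("grid must be 1-D strictly increasing")
        if self.grid[0] < 0 or self.grid[-1] >= 24.0:
            raise InvalidConfigError("grid must lie in [0, 24)")
        for name in SIGNAL_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.grid.shape:
                raise InvalidConfigError(f"{name} samples must match grid length")
            if not np.all(np.isfinite(arr)):
                raise DomainError(f"{name} samples contain non-finite values")
        if np.any(self.A < 0):
            raise DomainError("activity samples must be nonnegative")
        if np.any(self.NE <= 0) or np.any(self.glc <= 0):
            raise DomainError("NE and glc samples must be strictly positive")
        if self.mode not in INTERP_MODES:
            raise InvalidConfigError(f"unknown interpolation mode {self.mode!r}")
        self._interp = {
            name: _build_interpolant(self.grid, getattr(self, name), self.mode)
            for name in SIGNAL_NAMES
        }

    def _eval(self, name: str, t):
        tt = np.mod(t, 24.0)
        out = self._interp[name](tt)
        if np.any(~np.isfinite(np.atleast_1d(out))):
            raise DomainError(f"signal {name} not evaluable at t={t!r}")
        return out

    def activity(self, t):
        return self._eval("A", t)

    def norepinephrine(self, t):
        return self._eval("NE", t)

    def glycemia(self, t):
        return self._eval("glc", t)

    def evaluate(self, t):
        """Return (A, NE, glc) at time t (hours)."""
        return self.activity(t), self.norepinephrine(t), self.glycemia(t)

    # ---- I/O ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in SIGNAL_NAMES:
            for t, v in zip(self.grid, getattr(self, name)):
                rows.append({"time_h": t, "variable": name, "value": v,
                             "group": self.group})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "pchip") -> "InputSignals":
        groups = df["group"].unique()
        if len(groups) != 1:
            raise InvalidConfigError("signal frame must contain a single group")
        cols = {}
        grid = None
        for name in SIGNAL_NAMES:
            sub = df[df["variable"] == name].sort_values("time_h")
            if sub.empty:
                raise InvalidConfigError(f"signal frame missing variable {name!r}")
            cols[name] = sub["value"].to_numpy()
            grid = sub["time_h"].to_numpy()
        return cls(grid=grid, mode=mode, group=str(groups[0]), **cols)

    @classmethod
    def from_csv(cls, path, mode: str = "pchip") -> "InputSignals":
        return cls.from_frame(pd.read_csv(path), mode=mode)
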