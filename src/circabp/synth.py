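"""Synthetic 24-h inputs and observed datasets for dipper / non-dipper cohorts.

Real ambulatory studies provide cohort-average 30-min profiles of
activity, norepinephrine, glycemia, blood pressure and heart rate. This
module emulates their statistical structure: diurnal activity with night
rest from midnight to 8 a.m., day-high/night-low norepinephrine, and
glycemia with three postprandial excursions. The non-dipper cohort is
derived from the dipper profiles by the two documented transformations:
norepinephrine raised by 15% during night rest, and glycemia raised by
4.7, 13.3 and 8.1% two hours after breakfast, lunch and dinner.

Observed datasets are produced by forward-simulating the ODE model on
the 48-point grid and applying multiplicative Gaussian noise with a
fixed coefficient of variation, so the generating parameters are known
ground truth for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from .exceptions import AlignmentError, DomainError, InvalidConfigError
from .parameters import ParameterSet
from .signals import InputSignals, half_hour_grid

#: default rest window [start, end) in hours; wake-up fixed at 8 a.m.
REST_WINDOW = (0.0, 8.0)

#: default meal times (breakfast, lunch, dinner) in hours from midnight
MEAL_TIMES = (8.5, 13.0, 20.0)

#: postprandial glycemia increments for the non-dipper cohort, in percent,
#: applied 2 h after breakfast, lunch and dinner respectively
NON_DIPPER_GLC_INCREMENTS = (4.7, 13.3, 8.1)

#: norepinephrine multiplier applied to the non-dipper rest window
NON_DIPPER_NE_FACTOR = 1.15

GROUPS = ("dipper", "non_dipper")


@dataclass(frozen=True)
class HemodynamicConstants:
    """Constants of the vascular-resistance formula.

    SVR = (MAP - RAP) * 80 / CO with cardiac output CO = SV * HR in
    L/min; 80 converts mmHg·min/L to dyn·s·cm^-5. Mean right atrial
    pressure substitutes central venous pressure (the two are close
    given the low resistance of the large vessels). Defaults are cohort
    averages for essential hypertension: stroke volume 79.5 ml, right
    atrial pressure 5 mmHg.
    """

    sv_ml: float = 79.5
    rap_mmhg: float = 5.0
    unit_factor: float = 80.0
    map_convention: str = "standard"  # (SBP+2*DBP)/3; "alternate": (2*SBP+DBP)/3

    def __post_init__(self):
        if self.sv_ml <= 0 or self.rap_mmhg <= 0:
            raise InvalidConfigError("SV and RAP must be positive")
        if self.map_convention not in ("standard", "alternate"):
            raise InvalidConfigError(
                f"unknown MAP convention {self.map_convention!r}")

    @property
    def map_weights(self) -> tuple[float, float]:
        """(w_SBP, w_DBP) with MAP = w_SBP*SBP + w_DBP*DBP."""
        if self.map_convention == "standard":
            return (1.0 / 3.0, 2.0 / 3.0)
        return (2.0 / 3.0, 1.0 / 3.0)


def _raised_cosine_ramp(t, start, width):
    """0 before start, 1 after start+width, smooth raised cosine between."""
    t = np.asarray(t, dtype=float)
    x = np.clip((t - start) / width, 0.0, 1.0) if width > 0 else (t >= start) * 1.0
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _in_rest(t, rest_window=REST_WINDOW):
    return (np.asarray(t) >= rest_window[0]) & (np.asarray(t) < rest_window[1])


def generate_activity(wake_time: float = 8.0, sleep_time: float = 23.0,
                      peak_level: float = 100.0, night_level: float = 5.0,
                      noise_sd: float = 0.0, seed: int | None = None,
                      grid: np.ndarray | None = None) -> np.ndarray:
    """Diurnal actigraphy-like profile on the half-hour grid.

    Low plateau ``night_level`` during rest, raised-cosine rise over 2 h
    after ``wake_time`` to a daytime plateau ``peak_level`` with a
    shallow post-lunch dip, and a decline from ``sleep_time`` back to
    the night level by midnight. Optional additive Gaussian noise
    (clipped so the profile stays within [0, peak_level]).
    """
    if peak_level < 0 or night_level < 0:
        raise InvalidConfigError("activity levels must be nonnegative")
    if night_level > peak_level:
        raise InvalidConfigError("night_level must not exceed peak_level")
    if grid is None:
        grid = half_hour_grid()
    t = np.asarray(grid, dtype=float)
    up = _raised_cosine_ramp(t, wake_time, 2.0)
    down = 1.0 - _raised_cosine_ramp(t, sleep_time, 24.0 - sleep_time)
    envelope = up * down
    # shallow post-lunch dip, 15% deep, centred at 14:00
    dip = 1.0 - 0.15 * np.exp(-0.5 * ((t - 14.0) / 1.2) ** 2)
    a = night_level + (peak_level - night_level) * envelope * dip
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return np.clip(a, 0.0, peak_level)


def generate_ne(group: str = "dipper", day_level: float = 3.0,
                night_level: float = 1.5, transition_width: float = 1.0,
                rest_window=REST_WINDOW, noise_sd: float = 0.0,
                seed: int | None = None,
                grid: np.ndarray | None = None) -> np.ndarray:
    """Circadian norepinephrine profile (nmol/L), day-high / night-low.

    The non-dipper profile is the dipper profile with every sample in
    the rest window multiplied by 1.15; daytime samples are identical
    between groups.
    """
    if group not in GROUPS:
        raise InvalidConfigError(f"unknown group {group!r}")
    if day_level <= 0 or night_level <= 0:
        raise InvalidConfigError("NE levels must be positive")
    if grid is None:
        grid = half_hour_grid()
    t = np.asarray(grid, dtype=float)
    rise = _raised_cosine_ramp(t, rest_window[1], transition_width)
    fall = 1.0 - _raised_cosine_ramp(t, 23.0, transition_width) \
        if transition_width > 0 else (t < 23.0) * 1.0
    day_frac = rise * fall
    ne = night_level + (day_level - night_level) * day_frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ne = np.maximum(ne + rng.normal(0.0, noise_sd, size=ne.shape),
                        0.05 * night_level)
    if group == "non_dipper":
        ne = np.where(_in_rest(t, rest_window), ne * NON_DIPPER_NE_FACTOR, ne)
    return ne


def generate_glc(group: str = "dipper", baseline: float = 5.0,
                 meal_times=MEAL_TIMES,
                 peak_increments=NON_DIPPER_GLC_INCREMENTS,
                 excursion: float = 2.0, excursion_width: float = 1.5,
                 taper_width: float = 1.0, noise_sd: float = 0.0,
                 seed: int | None = None,
                 grid: np.ndarray | None = None) -> np.ndarray:
    """Glycemia profile (mmol/L) with three postprandial excursions.

    Dipper: ``baseline`` plus a raised-cosine excursion of amplitude
    ``excursion`` after each meal (peaking 1 h post-meal). Non-dipper:
    the dipper profile with the sample 2 h after each meal multiplied by
    1 + increment/100, tapered with a raised cosine of half-width
    ``taper_width`` so the profile stays smooth.
    """
    if group not in GROUPS:
        raise InvalidConfigError(f"unknown group {group!r}")
    if baseline <= 0:
        raise InvalidConfigError("baseline glycemia must be positive")
    meal_times = tuple(meal_times)
    peak_increments = tuple(peak_increments)
    if len(meal_times) != 3 or len(peak_increments) != 3:
        raise InvalidConfigError(
            "exactly three meals (breakfast, lunch, dinner) are required")
    if any(mt < 0 or mt > 24 for mt in meal_times):
        raise InvalidConfigError("meal times must lie in [0, 24]")
    if grid is None:
        grid = half_hour_grid()
    t = np.asarray(grid, dtype=float)
    glc = np.full_like(t, float(baseline))
    for mt in meal_times:
        # excursion peaking 1 h post-meal, raised cosine, half-width excursion_width
        x = np.clip(np.abs(t - (mt + 1.0)) / (2.0 * excursion_width), 0.0, 0.5)
        glc = glc + excursion * 0.5 * (1.0 + np.cos(2.0 * np.pi * x))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        glc = np.maximum(glc + rng.normal(0.0, noise_sd, size=glc.shape),
                         0.1 * baseline)
    if group == "non_dipper":
        factor = np.ones_like(t)
        for mt, inc in zip(meal_times, peak_increments):
            centre = mt + 2.0
            x = np.abs(t - centre) / taper_width if taper_width > 0 else \
                np.where(t == centre, 0.0, 1.0)
            bump = np.where(x <= 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(x, 0, 1))),
                            0.0)
            factor = factor * (1.0 + (inc / 100.0) * bump)
        glc = glc * factor
    return glc


def make_inputs(group: str = "dipper", mode: str = "pchip",
                noise_sd_activity: float = 0.0, seed: int | None = None,
                grid: np.ndarray | None = None, **overrides) -> InputSignals:
    """Assemble the three default input signals for a cohort."""
    if grid is None:
        grid = half_hour_grid()
    seeds = np.random.SeedSequence(seed).spawn(3) if seed is not None else [None] * 3
    to_int = (lambda s: int(s.generate_state(1)[0] % 2**31)) if seed is not None \
        else (lambda s: None)
    a = generate_activity(noise_sd=noise_sd_activity, seed=to_int(seeds[0]),
                          grid=grid, **overrides.get("activity", {}))
    ne = generate_ne(group=group, seed=to_int(seeds[1]), grid=grid,
                     **overrides.get("ne", {}))
    glc = generate_glc(group=group, seed=to_int(seeds[2]), grid=grid,
                       **overrides.get("glc", {}))
    return InputSignals(grid=grid, A=a, NE=ne, glc=glc, mode=mode, group=group)


# ---------------------------------------------------------------------------
# Vascular resistance from pressures and heart rate
# ---------------------------------------------------------------------------

def derive_svr(sbp, dbp, hr,
               constants: HemodynamicConstants = HemodynamicConstants()):
    """Systemic vascular resistance (dyn·s·cm^-5) from SBP, DBP and HR.

    SVR = (MAP - RAP) * 80 / (SV * HR) with cardiac output SV*HR in
    L/min. Vectorized over array inputs.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(sbp <= 0) or np.any(dbp <= 0):
        raise DomainError("pressures must be positive")
    if np.any(hr <= 0):
        raise DomainError("heart rate must be positive (division by CO)")
    ws, wd = constants.map_weights
    mean_ap = ws * sbp + wd * dbp
    co_l_min = constants.sv_ml / 1000.0 * hr
    out = (mean_ap - constants.rap_mmhg) * constants.unit_factor / co_l_min
    return out if out.ndim else float(out)


def propagate_svr_sd(sbp, dbp, hr, sd_sbp, sd_dbp, sd_hr,
                     constants: HemodynamicConstants = HemodynamicConstants()):
    """First-order (delta-method) standard deviation of derived SVR.

    Assumes independent errors in SBP, DBP and HR:
    sd_SVR^2 = sum_x (dSVR/dx)^2 sd_x^2.
    """
    for sd in (sd_sbp, sd_dbp, sd_hr):
        if np.any(np.asarray(sd) < 0):
            raise InvalidConfigError("standard deviations must be >= 0")
    svr = derive_svr(sbp, dbp, hr, constants)
    ws, wd = constants.map_weights
    co_l_min = constants.sv_ml / 1000.0 * np.asarray(hr, dtype=float)
    d_sbp = ws * constants.unit_factor / co_l_min
    d_dbp = wd * constants.unit_factor / co_l_min
    d_hr = -np.asarray(svr) / np.asarray(hr, dtype=float)
    var = (d_sbp * np.asarray(sd_sbp)) ** 2 + (d_dbp * np.asarray(sd_dbp)) ** 2 \
        + (d_hr * np.asarray(sd_hr)) ** 2
    out = np.sqrt(var)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Observed datasets
# ---------------------------------------------------------------------------

@dataclass
class ObservedDataset:
    """Cohort-average 24-h observations on the 30-min grid.

    ``means`` and ``sds`` map each variable (SVR, SBP, HR, DBP) to an
    array aligned with ``grid``; ``provenance`` records how the dataset
    was produced (generator seed and settings, or a file source).
    """

    grid: np.ndarray
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    group: str = "dipper"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        steps = np.diff(self.grid)
        if self.grid.ndim != 1 or np.any(steps <= 0):
            raise InvalidConfigError("grid must be strictly increasing")
        if steps.size and not np.allclose(steps, steps[0]):
            raise InvalidConfigError("observations must be equally spaced")
        for name in model.STATE_NAMES:
            if name not in self.means or name not in self.sds:
                raise InvalidConfigError(f"dataset missing variable {name!r}")
        for table, positive in ((self.means, True), (self.sds, True)):
            for name, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                table[name] = arr
                if arr.shape != self.grid.shape:
                    raise InvalidConfigError(f"{name} array does not match grid")
                if positive and np.any(arr <= 0):
                    raise InvalidConfigError(f"{name} values must be positive")

    @property
    def n_points(self) -> int:
        return self.grid.size

    def as_arrays(self, names=model.STATE_NAMES):
        """(means, sds) stacked as (len(names), N) arrays."""
        y = np.vstack([self.means[n] for n in names])
        s = np.vstack([self.sds[n] for n in names])
        return y, s

    def initial_state(self) -> np.ndarray:
        """First observed data point, the conventional simulation init."""
        return np.array([self.means[n][0] for n in model.STATE_NAMES])

    # ---- I/O ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in model.STATE_NAMES:
            for t, m, s in zip(self.grid, self.means[name], self.sds[name]):
                rows.append({"time_h": t, "variable": name, "mean": m,
                             "sd": s, "group": self.group})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None
                   ) -> "ObservedDataset":
        groups = df["group"].unique()
        if len(groups) != 1:
            raise InvalidConfigError("dataset frame must contain a single group")
        means, sds = {}, {}
        grid = None
        for name in model.STATE_NAMES:
            sub = df[df["variable"] == name].sort_values("time_h")
            if sub.empty:
                raise InvalidConfigError(f"dataset frame missing {name!r}")
            means[name] = sub["mean"].to_numpy()
            sds[name] = sub["sd"].to_numpy()
            grid = sub["time_h"].to_numpy()
        return cls(grid=grid, means=means, sds=sds, group=str(groups[0]),
                   provenance=provenance or {"source": "frame"})

    @classmethod
    def from_csv(cls, path) -> "ObservedDataset":
        return cls.from_frame(pd.read_csv(path), provenance={"source": str(path)})


def generate_dataset(params: ParameterSet, inputs: InputSignals,
                     noise_cv: float = 0.01, seed: int | None = None,
                     dbp_equation: str = "as_printed",
                     sd_floor: float = 1e-6,
                     init: np.ndarray | None = None,
                     rtol: float = 1e-6, atol: float = 1e-9) -> ObservedDataset:
    """Forward-simulate the model and add multiplicative Gaussian noise.

    Observed mean = y_model * (1 + noise_cv * z), z ~ N(0,1) i.i.d. per
    node and variable; the attached standard deviation is
    noise_cv * y_model, floored at ``sd_floor`` so weighting stays
    defined when noise_cv = 0.
    """
    if noise_cv < 0:
        raise InvalidConfigError("noise_cv must be >= 0")
    if init is None:
        init = model.default_initial_state(params, inputs,
                                           dbp_equation=dbp_equation,
                                           rtol=rtol, atol=atol)
    traj = model.simulate(params, inputs, init, inputs.grid, rtol=rtol,
                          atol=atol, dbp_equation=dbp_equation)
    rng = np.random.default_rng(seed)
    means, sds = {}, {}
    for name in model.STATE_NAMES:
        y = traj[name]
        noisy = y * (1.0 + noise_cv * rng.standard_normal(y.shape)) \
            if noise_cv > 0 else y.copy()
        means[name] = np.maximum(noisy, sd_floor)
        sds[name] = np.maximum(noise_cv * np.abs(y), sd_floor)
    provenance = {
        "generator": "circabp.synth.generate_dataset",
        "seed": seed, "noise_cv": noise_cv, "dbp_equation": dbp_equation,
        "params": params.to_dict(), "init": [float(v) for v in init],
        "rtol": rtol, "atol": atol,
    }
    return ObservedDataset(grid=inputs.grid.copy(), means=means, sds=sds,
                           group=params.group, provenance=provenance)
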