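"""The four-state ODE of medium-term blood-pressure regulation.

State variables: systemic vascular resistance (SVR), systolic blood
pressure (SBP), heart rate (HR) and diastolic blood pressure (DBP).
Forcing inputs: physical activity A(t), norepinephrine NE(t) and
glycemia glc(t).

    dSVR/dt = k1 * ki1/(ki1+A) * NE/(glc^n + NE) - SVR/(ki2+SVR) * SVR
    dSBP/dt = k3 * (SVR * HR/(ki3+HR) - SBP)
    dHR/dt  = k2 * A/(ki4+A) - k4 * DBP * HR
    dDBP/dt = k3 * (SVR * HR/(ki3+HR) - SBP)         ["as_printed"]
            = k3 * (SVR * HR/(ki3+HR) - DBP)         ["relaxed_to_dbp"]

Activity inhibits vasoconstriction (Hill inhibition ki1/(ki1+A)) and
drives heart rate (Hill activation A/(ki4+A)); norepinephrine and
glycemia act synergistically on vasoconstriction through NE/(glc^n+NE);
SVR self-limits through metabolic autoregulation; the baroreflex appears
as the -k4*DBP*HR decay of heart rate. The source formulation writes the
DBP equation with the same relaxation target (SBP) as the SBP equation,
which makes the pulse pressure DBP-SBP a conserved quantity; the
"relaxed_to_dbp" variant replaces the target with DBP and is offered
because the printed form is a suspected typo. Neither is asserted as the
intended one; "as_printed" is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import DomainError, IntegrationFailureError, InvalidConfigError
from .parameters import ParameterSet
from .signals import InputSignals

STATE_NAMES = ("SVR", "SBP", "HR", "DBP")

DBP_VARIANTS = ("as_printed", "relaxed_to_dbp")


def rhs(state, t, params: ParameterSet, inputs: InputSignals,
        dbp_equation: str = "as_printed"):
    """Time derivatives (dSVR, dSBP, dHR, dDBP) at time ``t`` (hours)."""
    if dbp_equation not in DBP_VARIANTS:
        raise InvalidConfigError(f"unknown dbp_equation {dbp_equation!r}")
    svr, sbp, hr, dbp = state
    a, ne, glc = inputs.evaluate(t)
    a = float(a); ne = float(ne); glc = float(glc)
    if not np.all(np.isfinite([a, ne, glc])):
        raise DomainError(f"inputs not finite at t={t}")
    if ne <= 0 or glc <= 0:
        raise DomainError(f"NE and glc must be > 0 at t={t} (NE={ne}, glc={glc})")
    p = params
    production = p.k1 * (p.ki1 / (p.ki1 + a)) * (ne / (glc ** p.n + ne))
    d_svr = production - svr / (p.ki2 + svr) * svr
    pressure_drive = p.k3 * (svr * hr / (p.ki3 + hr) - sbp)
    d_sbp = pressure_drive
    d_hr = p.k2 * a / (p.ki4 + a) - p.k4 * dbp * hr
    if dbp_equation == "as_printed":
        d_dbp = pressure_drive
    else:
        d_dbp = p.k3 * (svr * hr / (p.ki3 + hr) - dbp)
    return np.array([d_svr, d_sbp, d_hr, d_dbp])


@dataclass
class StateTrajectory:
    """Simulated SVR/SBP/HR/DBP on a time grid, with solver metadata."""

    grid: np.ndarray
    values: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidConfigError("trajectory grid must be strictly increasing")
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            self.values[name] = arr
            if arr.shape != self.grid.shape:
                raise InvalidConfigError(f"{name} array does not match grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def as_array(self, names=STATE_NAMES) -> np.ndarray:
        """(len(names), N) array in the given variable order."""
        return np.vstack([self.values[n] for n in names])


def simulate(params: ParameterSet, inputs: InputSignals, init, grid,
             rtol: float = 1e-6, atol: float = 1e-9,
             dbp_equation: str = "as_printed",
             method: str = "LSODA") -> StateTrajectory:
    """Integrate the model over ``grid`` starting from ``init``.

    ``init`` is the state at ``grid[0]`` ordered (SVR, SBP, HR, DBP); a
    stiff-capable solver (LSODA by default) is used and the solution is
    reported exactly at the requested grid points.
    """
    grid = np.asarray(grid, dtype=float)
    init = np.asarray(init, dtype=float)
    if init.shape != (4,) or np.any(init <= 0):
        raise InvalidConfigError("init must be four strictly positive values")
    if dbp_equation not in DBP_VARIANTS:
        raise InvalidConfigError(f"unknown dbp_equation {dbp_equation!r}")

    def f(t, y):
        return rhs(y, t, params, inputs, dbp_equation)

    sol = solve_ivp(f, (grid[0], grid[-1]), init, t_eval=grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success or sol.y.shape[1] != grid.size:
        t_fail = float(sol.t[-1]) if sol.t.size else float(grid[0])
        raise IntegrationFailureError(
            f"ODE integration failed near t={t_fail:.3f} h: {sol.message}",
            t_failure=t_fail)
    values = {name: sol.y[i] for i, name in enumerate(STATE_NAMES)}
    meta = {"rtol": rtol, "atol": atol, "method": method,
            "dbp_equation": dbp_equation, "nfev": int(sol.nfev)}
    return StateTrajectory(grid=grid, values=values, metadata=meta)


def svr_production(params: ParameterSet, a: float, ne: float, glc: float) -> float:
    """The vasoconstriction drive k1 * ki1/(ki1+A) * NE/(glc^n+NE)."""
    p = params
    return p.k1 * (p.ki1 / (p.ki1 + a)) * (ne / (glc ** p.n + ne))


def steady_state(params: ParameterSet, a: float, ne: float, glc: float,
                 pulse_pressure: float = 0.0) -> dict[str, float]:
    """Algebraic fixed point of the model under constant inputs.

    Solves SVR*^2/(ki2+SVR*) = production for SVR*, then the coupled
    HR*/SBP* balance with DBP* = SBP* - pulse_pressure (the as-printed
    DBP equation conserves the pulse pressure, so it enters as a given).
    Uses a bracketing root-finder, independent of the ODE solver.
    """
    p = params
    prod = svr_production(params, a, ne, glc)
    # SVR*^2 - prod*SVR* - prod*ki2 = 0, positive root
    svr = 0.5 * (prod + np.sqrt(prod ** 2 + 4 * prod * p.ki2))
    hr_drive = p.k2 * a / (p.ki4 + a)

    def hr_balance(hr):
        sbp = svr * hr / (p.ki3 + hr)
        dbp = sbp - pulse_pressure
        return hr_drive - p.k4 * dbp * hr

    hi = 1.0
    while hr_balance(hi) > 0 and hi < 1e12:
        hi *= 2.0
    lo = hi * 1e-12
    hr = brentq(hr_balance, lo, hi, xtol=1e-12, rtol=1e-14)
    sbp = svr * hr / (p.ki3 + hr)
    return {"SVR": svr, "SBP": sbp, "HR": hr, "DBP": sbp - pulse_pressure}


def default_initial_state(params: ParameterSet, inputs: InputSignals,
                          dbp_equation: str = "as_printed",
                          pulse_pressure: float = 15.0,
                          burn_in_h: float = 48.0,
                          rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """A near-periodic midnight state, found by burn-in.

    Starts from the constant-input fixed point at the midnight input
    values (with the requested pulse pressure) and integrates the forced
    system for ``burn_in_h`` hours of the periodic 24-h inputs; the final
    state serves as the initial condition of a 24-h simulation.
    """
    a0, ne0, glc0 = (float(x) for x in inputs.evaluate(0.0))
    ss = steady_state(params, max(a0, 1e-3), ne0, glc0,
                      pulse_pressure=pulse_pressure)
    y0 = np.array([ss["SVR"], ss["SBP"], ss["HR"], max(ss["DBP"], 1e-3)])
    n_steps = int(burn_in_h * 2) + 1
    grid = np.linspace(0.0, burn_in_h, n_steps)
    traj = simulate(params, inputs, y0, grid, rtol=rtol, atol=atol,
                    dbp_equation=dbp_equation)
    return np.array([traj[name][-1] for name in STATE_NAMES])


# ---------------------------------------------------------------------------
# Analytic Jacobians (used by the variational sensitivity system)
# ---------------------------------------------------------------------------

def state_jacobian(state, t, params: ParameterSet, inputs: InputSignals,
                   dbp_equation: str = "as_printed") -> np.ndarray:
    """d(rhs)/d(state), a 4x4 matrix, rows ordered as STATE_NAMES."""
    svr, sbp, hr, dbp = state
    a, ne, glc = (float(x) for x in inputs.evaluate(t))
    p = params
    J = np.zeros((4, 4))
    J[0, 0] = -svr * (2 * p.ki2 + svr) / (p.ki2 + svr) ** 2
    hr_sat = hr / (p.ki3 + hr)
    dhr_sat = p.ki3 / (p.ki3 + hr) ** 2
    J[1, 0] = p.k3 * hr_sat
    J[1, 1] = -p.k3
    J[1, 2] = p.k3 * svr * dhr_sat
    J[2, 2] = -p.k4 * dbp
    J[2, 3] = -p.k4 * hr
    if dbp_equation == "as_printed":
        J[3, :] = J[1, :]
    else:
        J[3, 0] = p.k3 * hr_sat
        J[3, 2] = p.k3 * svr * dhr_sat
        J[3, 3] = -p.k3
    return J


def parameter_jacobian(state, t, params: ParameterSet, inputs: InputSignals,
                       names, dbp_equation: str = "as_printed") -> np.ndarray:
    """d(rhs)/d(p_j) for the named parameters, a 4 x len(names) matrix."""
    svr, sbp, hr, dbp = state
    a, ne, glc = (float(x) for x in inputs.evaluate(t))
    p = params
    G = glc ** p.n
    ne_frac = ne / (G + ne)
    act_inhib = p.ki1 / (p.ki1 + a)
    hr_sat = hr / (p.ki3 + hr)
    cols = []
    for name in names:
        col = np.zeros(4)
        if name == "k1":
            col[0] = act_inhib * ne_frac
        elif name == "n":
            col[0] = -p.k1 * act_inhib * ne / (G + ne) ** 2 * G * np.log(glc)
        elif name == "ki1":
            col[0] = p.k1 * ne_frac * a / (p.ki1 + a) ** 2
        elif name == "ki2":
            col[0] = svr ** 2 / (p.ki2 + svr) ** 2
        elif name == "ki3":
            d = -p.k3 * svr * hr / (p.ki3 + hr) ** 2
            col[1] = d
            col[3] = d  # same drive in both pressure equations
        elif name == "ki4":
            col[2] = -p.k2 * a / (p.ki4 + a) ** 2
        elif name == "k2":
            col[2] = a / (p.ki4 + a)
        elif name == "k3":
            d_sbp = svr * hr_sat - sbp
            col[1] = d_sbp
            col[3] = d_sbp if dbp_equation == "as_printed" else svr * hr_sat - dbp
        elif name == "k4":
            col[2] = -dbp * hr
        else:
            raise InvalidConfigError(f"unknown parameter {name!r}")
        cols.append(col)
    return np.column_stack(cols)
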