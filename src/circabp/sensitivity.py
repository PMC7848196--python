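"""Local sensitivity analysis of the fitted model.

Sensitivity trajectories S_ij(t_n) = dy_i(t_n)/dp_j are integrated with
the variational (forward) equations: the augmented system carries the
4 x p sensitivity matrix alongside the state,

    dS/dt = J_y(t, y) S + J_p(t, y),  S(0) = 0,

with the analytic state and parameter Jacobians of the model. A central
finite-difference method on the plain simulator is available as an
independent cross-check. Relative sensitivities Srel = S * p_j / y_i
make variables and parameters commensurable; the summary index

    delta_j = (1/(k*N)) sum_i sum_n Srel_ij(t_n)^2

aggregates them (mean of squares by default; the root-mean-square
convention is selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model
from .exceptions import IntegrationFailureError, InvalidConfigError
from .parameters import ESTIMATED_NAMES, ParameterSet
from .signals import InputSignals

SENS_METHODS = ("variational", "finite_difference")
DELTA_CONVENTIONS = ("mean_sq", "rms")


@dataclass
class SensitivityTrajectory:
    """Absolute and relative sensitivities on a time grid.

    ``S`` and ``Srel`` have shape (variables, parameters, nodes) with
    variables ordered as (SVR, SBP, HR, DBP); ``y`` is the underlying
    model trajectory, shape (variables, nodes).
    """

    grid: np.ndarray
    param_names: tuple[str, ...]
    S: np.ndarray
    Srel: np.ndarray
    y: np.ndarray
    var_names: tuple[str, ...] = model.STATE_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        k, p, n = len(self.var_names), len(self.param_names), self.grid.size
        for name, arr, shape in (("S", self.S, (k, p, n)),
                                 ("Srel", self.Srel, (k, p, n)),
                                 ("y", self.y, (k, n))):
            if np.asarray(arr).shape != shape:
                raise InvalidConfigError(f"{name} has shape {arr.shape}, "
                                         f"expected {shape}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, var in enumerate(self.var_names):
            for j, par in enumerate(self.param_names):
                for n, t in enumerate(self.grid):
                    rows.append({"time_h": t, "variable": var, "parameter": par,
                                 "S": self.S[i, j, n], "Srel": self.Srel[i, j, n]})
        return pd.DataFrame(rows)


def local_sensitivities(params: ParameterSet, inputs: InputSignals, init,
                        grid, free_names=ESTIMATED_NAMES,
                        method: str = "variational",
                        dbp_equation: str = "as_printed",
                        rtol: float = 1e-8, atol: float = 1e-10,
                        fd_rel_step: float = 1e-6) -> SensitivityTrajectory:
    """Sensitivities of all four variables to the named parameters."""
    if method not in SENS_METHODS:
        raise InvalidConfigError(f"unknown sensitivity method {method!r}")
    grid = np.asarray(grid, dtype=float)
    free_names = tuple(free_names)
    if method == "variational":
        S, y = _variational(params, inputs, init, grid, free_names,
                            dbp_equation, rtol, atol)
    else:
        S, y = _finite_difference(params, inputs, init, grid, free_names,
                                  dbp_equation, rtol, atol, fd_rel_step)
    p_vals = params.to_array(free_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        Srel = S * p_vals[None, :, None] / y[:, None, :]
    return SensitivityTrajectory(grid=grid, param_names=free_names, S=S,
                                 Srel=Srel, y=y,
                                 metadata={"method": method, "rtol": rtol,
                                           "atol": atol,
                                           "dbp_equation": dbp_equation})


def _variational(params, inputs, init, grid, names, dbp_equation, rtol, atol):
    n_par = len(names)
    init = np.asarray(init, dtype=float)

    def f(t, z):
        y = z[:4]
        S = z[4:].reshape(4, n_par)
        dy = model.rhs(y, t, params, inputs, dbp_equation)
        Jy = model.state_jacobian(y, t, params, inputs, dbp_equation)
        Jp = model.parameter_jacobian(y, t, params, inputs, names, dbp_equation)
        dS = Jy @ S + Jp
        return np.concatenate([dy, dS.ravel()])

    z0 = np.concatenate([init, np.zeros(4 * n_par)])
    sol = solve_ivp(f, (grid[0], grid[-1]), z0, t_eval=grid, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success or sol.y.shape[1] != grid.size:
        t_fail = float(sol.t[-1]) if sol.t.size else float(grid[0])
        raise IntegrationFailureError(
            f"variational integration failed near t={t_fail:.3f} h: "
            f"{sol.message}", t_failure=t_fail)
    y = sol.y[:4]
    S = sol.y[4:].reshape(4, n_par, grid.size)
    return S, y


def _finite_difference(params, inputs, init, grid, names, dbp_equation,
                       rtol, atol, rel_step):
    base_traj = model.simulate(params, inputs, init, grid, rtol=rtol,
                               atol=atol, dbp_equation=dbp_equation)
    y = base_traj.as_array()
    S = np.zeros((4, len(names), grid.size))
    for j, name in enumerate(names):
        pj = getattr(params, name)
        h = rel_step * pj
        cols = []
        for p_pert in (params.replace(**{name: pj + h}),
                       params.replace(**{name: pj - h})):
            try:
                traj = model.simulate(p_pert, inputs, init, grid, rtol=rtol,
                                      atol=atol, dbp_equation=dbp_equation)
            except IntegrationFailureError as err:
                raise IntegrationFailureError(
                    f"finite-difference simulation failed for {name}: {err}",
                    t_failure=err.t_failure) from err
            cols.append(traj.as_array())
        S[:, j, :] = (cols[0] - cols[1]) / (2.0 * h)
    return S, y


@dataclass
class SensitivityIndex:
    """Squared-and-averaged relative sensitivities per parameter.

    ``delta`` aggregates over all variables and nodes; ``per_variable``
    (variables x parameters) keeps the per-variable breakdown used in
    bar-chart summaries.
    """

    param_names: tuple[str, ...]
    delta: np.ndarray
    per_variable: np.ndarray
    convention: str = "mean_sq"
    var_names: tuple[str, ...] = model.STATE_NAMES

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, par in enumerate(self.param_names):
            row = {"parameter": par, "delta": self.delta[j]}
            for i, var in enumerate(self.var_names):
                row[f"delta_{var}"] = self.per_variable[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def sensitivity_index(traj: SensitivityTrajectory,
                      convention: str = "mean_sq") -> SensitivityIndex:
    """Aggregate Srel into one index per parameter (and per variable)."""
    if convention not in DELTA_CONVENTIONS:
        raise InvalidConfigError(f"unknown delta convention {convention!r}")
    sq = traj.Srel ** 2
    per_variable = sq.mean(axis=2)          # (variables, parameters)
    delta = per_variable.mean(axis=0)       # mean over variables == (1/kN) double sum
    if convention == "rms":
        per_variable = np.sqrt(per_variable)
        delta = np.sqrt(delta)
    return SensitivityIndex(param_names=traj.param_names, delta=delta,
                            per_variable=per_variable, convention=convention,
                            var_names=traj.var_names)
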