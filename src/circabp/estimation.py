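"""Model calibration: normalized least-squares objective and global fitting.

The objective is a normalized sum of squares over the k = 4 observed
variables and the N grid points,

    F = (1/(k*N)) * sum_i sum_n ((y_exp - y_model) / y_exp)^2 ,

so heterogeneous variables (resistance, pressures, rate) are
commensurable; 100*F is the mean squared normalized error in percent.

Fitting uses a seeded stochastic global search: Latin-hypercube starts
in log-parameter space, scored by the objective, with trust-region
least-squares refinement of the most promising members. The two-stage
protocol first fits each cohort independently, then freezes the shared
constants (k1, n, ki2) at a consolidated value and refits the four
group-specific constants per cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import model
from .exceptions import (DomainError, FitFailureError,
                         IntegrationFailureError, InvalidConfigError)
from .parameters import (ESTIMATED_NAMES, GROUP_SPECIFIC_NAMES, PARAM_NAMES,
                         REFERENCE, SHARED_NAMES, ParameterSet)
from .signals import InputSignals
from .synth import ObservedDataset


def objective(params: ParameterSet, dataset: ObservedDataset,
              inputs: InputSignals | None = None,
              trajectory: model.StateTrajectory | None = None,
              dbp_equation: str = "as_printed",
              rtol: float = 1e-6, atol: float = 1e-9) -> float:
    """Mean normalized squared error F of the model against a dataset.

    Either a precomputed ``trajectory`` on the dataset grid or the
    ``inputs`` needed to simulate one must be supplied; simulation
    starts from the first observed data point.
    """
    r = _normalized_residuals(params, dataset, inputs, trajectory,
                              dbp_equation, rtol, atol)
    return float(np.mean(r ** 2))


def _normalized_residuals(params, dataset, inputs=None, trajectory=None,
                          dbp_equation="as_printed", rtol=1e-6, atol=1e-9):
    """((y_exp - y_model)/y_exp) flattened over variables and nodes."""
    if trajectory is None:
        if inputs is None:
            raise InvalidConfigError("either inputs or trajectory is required")
        trajectory = model.simulate(params, inputs, dataset.initial_state(),
                                    dataset.grid, rtol=rtol, atol=atol,
                                    dbp_equation=dbp_equation)
    elif trajectory.grid.shape != dataset.grid.shape or \
            not np.allclose(trajectory.grid, dataset.grid):
        raise InvalidConfigError("trajectory grid does not match dataset grid")
    y_exp, _ = dataset.as_arrays()
    if np.any(y_exp == 0):
        raise DomainError("y_exp contains zeros; normalization undefined")
    y_mod = trajectory.as_array()
    return ((y_exp - y_mod) / y_exp).ravel()


@dataclass
class FitConfig:
    """Settings of the global search and of the parameter structure.

    ``free`` lists the constants being estimated; everything else is
    held at the values in ``base`` (defaults to the reference set of the
    dataset's cohort). ``bounds`` maps names to positive (lo, hi)
    intervals; unspecified free parameters get ``base`` value / and *
    ``bound_span``. ``shared`` is the subset consolidated across cohorts
    in the two-stage protocol.
    """

    free: tuple[str, ...] = ESTIMATED_NAMES
    fixed: dict[str, float] = field(default_factory=lambda: {"k3": 1.0, "k4": 1.0})
    shared: tuple[str, ...] = SHARED_NAMES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    bound_span: float = 100.0
    base: ParameterSet | None = None
    n_starts: int = 24
    n_refine: int = 3
    max_nfev: int = 200
    # finite-difference step of the refinement Jacobian, in log10-parameter
    # units; must sit well above the ODE solver noise floor (~rtol)
    diff_step: float = 1e-4
    seed: int = 0
    shared_rule: str = "mean"  # or "best": shared values from the better fit
    dbp_equation: str = "as_printed"
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        self.free = tuple(self.free)
        self.shared = tuple(self.shared)
        if set(self.shared) & set(self.fixed):
            raise InvalidConfigError("shared and fixed sets must be disjoint")
        if set(self.free) & set(self.fixed):
            raise InvalidConfigError("free and fixed sets must be disjoint")
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise InvalidConfigError(f"unknown free parameters {sorted(unknown)}")
        if self.shared_rule not in ("mean", "best"):
            raise InvalidConfigError(f"unknown shared_rule {self.shared_rule!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise InvalidConfigError(
                    f"bounds for {name} must be finite positive with lo < hi")

    def resolve_base(self, group: str) -> ParameterSet:
        base = self.base if self.base is not None else REFERENCE[group]
        return base.with_values(self.fixed.keys(), self.fixed.values())

    def resolve_bounds(self, base: ParameterSet) -> dict[str, tuple[float, float]]:
        out = {}
        for name in self.free:
            if name in self.bounds:
                out[name] = self.bounds[name]
            else:
                v = getattr(base, name)
                out[name] = (v / self.bound_span, v * self.bound_span)
        return out

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "free", "shared", "bound_span", "n_starts", "n_refine", "max_nfev",
            "diff_step", "seed", "shared_rule", "dbp_equation", "rtol", "atol")}
        d["fixed"] = dict(self.fixed)
        d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        d["free"] = list(self.free)
        d["shared"] = list(self.shared)
        if self.base is not None:
            d["base"] = self.base.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if "base" in d and d["base"] is not None:
            d["base"] = ParameterSet.from_dict(d["base"])
        if "bounds" in d:
            d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of one calibration run."""

    params: ParameterSet
    objective: float
    trace: np.ndarray          # best-so-far objective per evaluation
    free: tuple[str, ...]
    seed: int
    n_evaluations: int
    converged: bool

    def __post_init__(self):
        self.trace = np.asarray(self.trace, dtype=float)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "trace": [float(v) for v in self.trace],
            "free": list(self.free),
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(params=ParameterSet.from_dict(d["params"]),
                   objective=d["objective"], trace=np.asarray(d["trace"]),
                   free=tuple(d["free"]), seed=d["seed"],
                   n_evaluations=d["n_evaluations"], converged=d["converged"])

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class _Tracker:
    """Accumulates the monotone best-so-far objective trace."""

    def __init__(self):
        self.best = np.inf
        self.trace: list[float] = []
        self.n = 0

    def record(self, f: float):
        self.n += 1
        if f < self.best:
            self.best = f
        self.trace.append(self.best)


def fit(dataset: ObservedDataset, inputs: InputSignals,
        config: FitConfig | None = None) -> FitResult:
    """Global stochastic fit of the free parameters to one dataset.

    Latin-hypercube starts in log10 space over the bounds, objective
    scoring of every start, then bounded trust-region least-squares
    refinement of the ``n_refine`` best. Fully reproducible under
    ``config.seed``.
    """
    config = config or FitConfig()
    base = config.resolve_base(dataset.group)
    free = tuple(n for n in config.free if n not in config.fixed)
    bounds = config.resolve_bounds(base)
    lo = np.log10([bounds[n][0] for n in free])
    hi = np.log10([bounds[n][1] for n in free])
    tracker = _Tracker()

    def residuals(x_log):
        p = base.with_values(free, 10.0 ** np.asarray(x_log))
        try:
            r = _normalized_residuals(p, dataset, inputs,
                                      dbp_equation=config.dbp_equation,
                                      rtol=config.rtol, atol=config.atol)
        except (IntegrationFailureError, DomainError):
            r = np.full(4 * dataset.n_points, 1e6)
        tracker.record(float(np.mean(r ** 2)))
        return r / np.sqrt(r.size)   # so sum(r^2) == F

    sampler = qmc.LatinHypercube(d=len(free),
                                 seed=np.random.default_rng(config.seed))
    starts = qmc.scale(sampler.random(config.n_starts), lo, hi)
    # always include the base point: the protocol refits around a reference
    x_base = np.log10(base.to_array(free))
    if np.all(x_base >= lo) and np.all(x_base <= hi):
        starts = np.vstack([x_base, starts])
    scores = []
    for x in starts:
        f = float(np.sum(residuals(x) ** 2) * 1.0)
        scores.append(f)
    scores = np.asarray(scores)
    order = np.argsort(scores)
    if not np.isfinite(scores[order[0]]) or scores[order[0]] >= 1e12:
        raise FitFailureError("no optimizer start produced an integrable model")

    best_x, best_f = starts[order[0]], scores[order[0]]
    for idx in order[:config.n_refine]:
        sol = least_squares(residuals, starts[idx], bounds=(lo, hi),
                            method="trf", max_nfev=config.max_nfev,
                            diff_step=config.diff_step,
                            xtol=1e-12, ftol=1e-12, gtol=1e-10)
        f = float(np.sum(sol.fun ** 2))
        if f < best_f:
            best_f, best_x = f, sol.x
    params = base.with_values(free, 10.0 ** best_x).replace(group=dataset.group)
    return FitResult(params=params, objective=best_f,
                     trace=np.asarray(tracker.trace), free=free,
                     seed=config.seed, n_evaluations=tracker.n,
                     converged=bool(np.isfinite(best_f)))


@dataclass
class JointFitResult:
    """Two-stage shared-parameter calibration across the two cohorts."""

    dipper: FitResult
    non_dipper: FitResult
    shared_values: dict[str, float]
    stage1: dict[str, FitResult]

    @property
    def total_objective(self) -> float:
        return self.dipper.objective + self.non_dipper.objective

    def to_dict(self) -> dict:
        return {"dipper": self.dipper.to_dict(),
                "non_dipper": self.non_dipper.to_dict(),
                "shared_values": dict(self.shared_values),
                "stage1": {k: v.to_dict() for k, v in self.stage1.items()}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def joint_fit(dipper: ObservedDataset, non_dipper: ObservedDataset,
              dipper_inputs: InputSignals, non_dipper_inputs: InputSignals,
              config: FitConfig | None = None) -> JointFitResult:
    """Stage 1: independent cohort fits. Stage 2: consolidate the shared
    constants (arithmetic mean by default, or the better-fitting
    cohort's values) and refit the group-specific constants per cohort.

    With the shared set frozen the summed two-cohort objective
    separates, so the stage-2 refits run independently per cohort. An
    empty shared set reduces to the two independent stage-1 fits.
    """
    config = config or FitConfig()
    if dipper.grid.shape != non_dipper.grid.shape or \
            not np.allclose(dipper.grid, non_dipper.grid):
        raise InvalidConfigError("cohort datasets must share the time grid")
    stage1 = {}
    for ds, ins in ((dipper, dipper_inputs), (non_dipper, non_dipper_inputs)):
        stage1[ds.group] = fit(ds, ins, config)
    shared = tuple(n for n in config.shared if n in config.free)
    if not shared:
        return JointFitResult(dipper=stage1["dipper"],
                              non_dipper=stage1["non_dipper"],
                              shared_values={}, stage1=stage1)
    r_d, r_n = stage1["dipper"], stage1["non_dipper"]
    if config.shared_rule == "mean":
        shared_values = {n: 0.5 * (getattr(r_d.params, n) + getattr(r_n.params, n))
                         for n in shared}
    else:
        better = r_d if r_d.objective <= r_n.objective else r_n
        shared_values = {n: getattr(better.params, n) for n in shared}
    stage2_free = tuple(n for n in config.free if n not in shared)
    results = {}
    for ds, ins in ((dipper, dipper_inputs), (non_dipper, non_dipper_inputs)):
        base = config.resolve_base(ds.group).with_values(
            shared_values.keys(), shared_values.values())
        cfg2 = FitConfig(**{**config.to_dict(),
                            "free": stage2_free, "base": base})
        results[ds.group] = fit(ds, ins, cfg2)
    return JointFitResult(dipper=results["dipper"],
                          non_dipper=results["non_dipper"],
                          shared_values=shared_values, stage1=stage1)
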