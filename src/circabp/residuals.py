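"""Residual diagnostics on the directly measured variables.

Residuals R_i(t_n) = y_exp,i(t_n) - y_model,i(t_n) are computed for HR,
SBP and DBP only: the observed SVR is itself calculated from pressures
and heart rate, so including it would double-count measurement error.
Residuals are pooled across the three variables (their units are mixed,
matching the single quantile-quantile summary of the calibrated model)
and normality is assessed with a Shapiro–Wilk test at alpha = 0.05,
alongside QQ coordinates and a Sturges-binned histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, DegenerateSampleError, InvalidConfigError
from .model import StateTrajectory
from .synth import ObservedDataset

#: variables entering the residual analysis: the non-calculated ones
NON_CALCULATED = ("HR", "SBP", "DBP")


@dataclass
class ResidualSet:
    """Raw residuals per variable plus the pooled vector."""

    grid: np.ndarray
    per_variable: dict[str, np.ndarray]
    var_names: tuple[str, ...] = NON_CALCULATED

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.per_variable[v] for v in self.var_names])


def compute_residuals(dataset: ObservedDataset, trajectory: StateTrajectory,
                      variables=NON_CALCULATED) -> ResidualSet:
    """Raw data-minus-model differences on the dataset grid."""
    if trajectory.grid.shape != dataset.grid.shape or \
            not np.allclose(trajectory.grid, dataset.grid):
        raise AlignmentError("trajectory grid does not match dataset grid")
    per_variable = {v: dataset.means[v] - trajectory[v] for v in variables}
    return ResidualSet(grid=dataset.grid.copy(), per_variable=per_variable,
                       var_names=tuple(variables))


@dataclass
class NormalityResult:
    """Shapiro–Wilk outcome with QQ and histogram summaries."""

    statistic: float
    p_value: float
    alpha: float
    reject_normality: bool
    qq_theoretical: np.ndarray
    qq_ordered: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"statistic": float(self.statistic),
                "p_value": float(self.p_value),
                "alpha": float(self.alpha),
                "reject_normality": bool(self.reject_normality),
                "n": int(self.n),
                "hist_edges": self.hist_edges.tolist(),
                "hist_counts": self.hist_counts.tolist()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qq_coordinates(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal QQ pairs with Blom plotting positions.

    Returns (theoretical quantiles, ordered sample); the sample is not
    standardized, so normal data fall on a line with slope sigma and
    intercept mu.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return stats.norm.ppf(probs), x


def normality_assessment(residuals, alpha: float = 0.05,
                         bins: str | int = "sturges") -> NormalityResult:
    """Shapiro–Wilk test plus QQ / histogram data for a residual set.

    ``residuals`` may be a ResidualSet (pooled across HR, SBP, DBP) or a
    plain 1-D array.
    """
    pooled = residuals.pooled if isinstance(residuals, ResidualSet) \
        else np.asarray(residuals, dtype=float).ravel()
    if not 0 < alpha < 1:
        raise InvalidConfigError("alpha must be in (0, 1)")
    if pooled.size < 3:
        raise DegenerateSampleError("need at least 3 residuals")
    if np.ptp(pooled) == 0:
        raise DegenerateSampleError("constant residual vector")
    w, p = stats.shapiro(pooled)
    theo, ordered = qq_coordinates(pooled)
    counts, edges = np.histogram(pooled, bins=bins)
    return NormalityResult(statistic=float(w), p_value=float(p), alpha=alpha,
                           reject_normality=bool(p < alpha),
                           qq_theoretical=theo, qq_ordered=ordered,
                           hist_edges=edges, hist_counts=counts,
                           n=int(pooled.size))


def per_variable_assessment(res: ResidualSet, alpha: float = 0.05,
                            bins: str | int = "sturges"
                            ) -> dict[str, NormalityResult]:
    """Normality assessment for each variable separately."""
    return {v: normality_assessment(res.per_variable[v], alpha=alpha, bins=bins)
            for v in res.var_names}
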