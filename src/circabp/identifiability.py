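"""Practical identifiability: Fisher information, confidence intervals,
parameter correlations.

The Fisher information matrix is assembled from the absolute local
sensitivity slices S(t_n) (parameters x variables) and a diagonal
per-node weighting built from the data standard deviations,

    FIM = sum_n S(t_n) W(t_n) S(t_n)^T .

The default weighting is inverse-variance, W = diag(1/sigma_i^2(t_n)),
which is the Cramér–Rao-consistent choice (less noise, more
information). A literal variance weighting W = diag(sigma_i^2) is
selectable for comparison. By Cramér–Rao, FIM^-1 approximates the
covariance of the estimates: 95% CIs are p_j ± 1.96*sigma_jj and the
correlation kappa_jh = sigma_jh^2/(sigma_jj*sigma_hh); |kappa| > 0.95
flags pairs that threaten identifiability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidConfigError, WeightingDomainError
from .parameters import ParameterSet
from .sensitivity import SensitivityTrajectory
from .synth import ObservedDataset

WEIGHTINGS = ("inverse_variance", "literal")

#: reciprocal-condition-number threshold below which the FIM is singular
RCOND_SINGULAR = 1e-12

#: |correlation| above which a parameter pair threatens identifiability
CORRELATION_THRESHOLD = 0.95


def fisher_information(traj: SensitivityTrajectory, dataset: ObservedDataset,
                       weighting: str = "inverse_variance") -> np.ndarray:
    """FIM (p x p) from sensitivity trajectories and data dispersions."""
    if weighting not in WEIGHTINGS:
        raise InvalidConfigError(f"unknown weighting {weighting!r}")
    if traj.grid.shape != dataset.grid.shape or \
            not np.allclose(traj.grid, dataset.grid):
        raise AlignmentError("sensitivity grid does not match dataset grid")
    _, sds = dataset.as_arrays(traj.var_names)    # (k, N)
    if np.any(sds == 0):
        raise WeightingDomainError("zero standard deviation in dataset")
    w = 1.0 / sds ** 2 if weighting == "inverse_variance" else sds ** 2
    # S: (k, p, N); FIM[j,h] = sum_n sum_i S[i,j,n] w[i,n] S[i,h,n]
    fim = np.einsum("ijn,in,ihn->jh", traj.S, w, traj.S)
    return 0.5 * (fim + fim.T)   # enforce exact symmetry


@dataclass
class FIMResult:
    """Identifiability report for the free parameters.

    When the FIM is numerically singular (reciprocal condition number
    below ``RCOND_SINGULAR`` or non-finite), covariance-based fields are
    None and ``null_space`` carries an orthonormal basis of the
    near-null directions instead.
    """

    param_names: tuple[str, ...]
    values: np.ndarray
    fim: np.ndarray
    condition_number: float
    singular: bool
    covariance: np.ndarray | None = None
    std_errors: np.ndarray | None = None
    ci_halfwidth: np.ndarray | None = None
    correlation: np.ndarray | None = None
    high_correlation_pairs: list = field(default_factory=list)
    null_space: np.ndarray | None = None

    def ci_table(self) -> pd.DataFrame:
        if self.singular:
            raise InvalidConfigError("no CIs available: FIM is singular")
        return pd.DataFrame({
            "parameter": list(self.param_names),
            "estimate": self.values,
            "std_error": self.std_errors,
            "ci95_halfwidth": self.ci_halfwidth,
            "ci95_low": self.values - self.ci_halfwidth,
            "ci95_high": self.values + self.ci_halfwidth,
        })

    def correlation_frame(self) -> pd.DataFrame:
        if self.correlation is None:
            raise InvalidConfigError("no correlation matrix: FIM is singular")
        return pd.DataFrame(self.correlation, index=list(self.param_names),
                            columns=list(self.param_names))

    def to_dict(self) -> dict:
        d = {"param_names": list(self.param_names),
             "values": [float(v) for v in self.values],
             "fim": np.asarray(self.fim).tolist(),
             "condition_number": float(self.condition_number),
             "singular": bool(self.singular),
             "high_correlation_pairs": [
                 [a, b, float(c)] for a, b, c in self.high_correlation_pairs]}
        for name in ("covariance", "std_errors", "ci_halfwidth",
                     "correlation", "null_space"):
            v = getattr(self, name)
            d[name] = None if v is None else np.asarray(v).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confidence_and_correlation(fim: np.ndarray, params: ParameterSet | np.ndarray,
                               param_names: tuple[str, ...],
                               threshold: float = CORRELATION_THRESHOLD,
                               rcond_singular: float = RCOND_SINGULAR
                               ) -> FIMResult:
    """Invert the FIM into CIs and a correlation matrix, or diagnose
    singularity with a null-space basis."""
    fim = np.asarray(fim, dtype=float)
    if isinstance(params, ParameterSet):
        values = params.to_array(param_names)
    else:
        values = np.asarray(params, dtype=float)
    if fim.shape != (len(param_names), len(param_names)):
        raise InvalidConfigError("FIM shape does not match parameter names")
    sv = np.linalg.svd(fim, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if not np.isfinite(cond) or rcond < rcond_singular:
        _, _, vt = np.linalg.svd(fim)
        null_dims = sv <= rcond_singular * max(sv[0], 1.0)
        null_space = vt[null_dims].T if null_dims.any() else vt[-1:].T
        return FIMResult(param_names=tuple(param_names), values=values,
                         fim=fim, condition_number=cond, singular=True,
                         null_space=null_space)
    cov = np.linalg.solve(fim, np.eye(fim.shape[0]))
    cov = 0.5 * (cov + cov.T)
    sigma = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sigma, sigma)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    pairs = []
    for j in range(len(param_names)):
        for h in range(j + 1, len(param_names)):
            if abs(corr[j, h]) > threshold:
                pairs.append((param_names[j], param_names[h],
                              float(corr[j, h])))
    return FIMResult(param_names=tuple(param_names), values=values, fim=fim,
                     condition_number=cond, singular=False, covariance=cov,
                     std_errors=sigma, ci_halfwidth=1.96 * sigma,
                     correlation=corr, high_correlation_pairs=pairs)
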