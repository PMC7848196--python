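"""Model parameters for the circadian blood-pressure ODE system.

The model has nine constants. Seven are estimated from data; ``k3`` and
``k4`` only ensure dimensional homogeneity and are conventionally fixed to
one (they are nearly perfectly correlated with ``ki3`` and ``k2``
respectively, so freeing them destroys identifiability).

Parameter meanings
------------------
k1   basal vasoconstriction rate (SVR units / h)
n    exponent controlling the impact of glycemia on vasodilation
ki1  half-inhibition constant of activity on SVR (activity units);
     larger ki1 means weaker inhibition
ki2  SVR self-regulation constant (SVR units)
ki3  half-saturation constant of HR in the pressure drive (HR units)
ki4  half-activation constant of activity on HR (activity units)
k2   basal heart-rate drive (HR * BP units / h)
k3   dimensional homogeneity constant in the pressure equations, fixed 1
k4   baroreflex rate constant coupling DBP*HR decay, fixed 1
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigError

#: canonical ordering of all nine constants
PARAM_NAMES: tuple[str, ...] = (
    "k1", "n", "ki1", "ki2", "ki3", "ki4", "k2", "k3", "k4",
)

#: the seven constants the calibration estimates (k3, k4 stay fixed at 1)
ESTIMATED_NAMES: tuple[str, ...] = ("k1", "n", "ki1", "ki2", "ki3", "ki4", "k2")

#: constants shared between dipper and non-dipper cohorts in the two-stage fit
SHARED_NAMES: tuple[str, ...] = ("k1", "n", "ki2")

#: constants refitted per cohort in the two-stage fit
GROUP_SPECIFIC_NAMES: tuple[str, ...] = ("ki1", "ki3", "ki4", "k2")


@dataclass(frozen=True)
class ParameterSet:
    """Immutable value object holding the nine model constants.

    All values must be strictly positive (``n`` may be zero). ``group``
    is a free-form cohort label, conventionally ``"dipper"`` or
    ``"non_dipper"``.
    """

    k1: float
    n: float
    ki1: float
    ki2: float
    ki3: float
    ki4: float
    k2: float
    k3: float = 1.0
    k4: float = 1.0
    group: str = "dipper"

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidConfigError(f"parameter {name} is not finite: {v!r}")
            if name == "n":
                if v < 0:
                    raise InvalidConfigError(f"n must be >= 0, got {v}")
            elif v <= 0:
                raise InvalidConfigError(f"parameter {name} must be > 0, got {v}")

    def to_array(self, names: tuple[str, ...] = PARAM_NAMES) -> np.ndarray:
        return np.array([getattr(self, name) for name in names], dtype=float)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def with_values(self, names, values) -> "ParameterSet":
        """Return a copy with the named constants replaced."""
        return self.replace(**dict(zip(names, map(float, values))))

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in PARAM_NAMES}
        d["group"] = self.group
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**{k: d[k] for k in (*PARAM_NAMES, "group") if k in d})


#: Reference calibrated values for the dipper cohort (canonical unit set:
#: activity in device counts, NE in nmol/L, glycemia in mmol/L, time in h).
REFERENCE_DIPPER = ParameterSet(
    k1=614.7, n=2.472, ki1=801.3, ki2=3861.0, ki3=805.3, ki4=24.79,
    k2=7654.0, group="dipper",
)

#: Reference calibrated values for the non-dipper cohort. k1, n and ki2 are
#: shared with the dipper cohort; the four activity/baroreflex constants
#: differ (weaker activity inhibition of SVR, stronger activity activation
#: of HR, lower basal HR drive).
REFERENCE_NON_DIPPER = ParameterSet(
    k1=614.7, n=2.472, ki1=544.2, ki2=3861.0, ki3=748.4, ki4=10.86,
    k2=6808.0, group="non_dipper",
)

REFERENCE = {"dipper": REFERENCE_DIPPER, "non_dipper": REFERENCE_NON_DIPPER}
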