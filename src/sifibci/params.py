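"""Parameter containers for the audiovisual numerosity causal-inference model.

The observer model has nine generative parameters: five govern the numerosity
dimension (visual and auditory evidence noise, the prior probability of a
common cause, and the mean/SD of the Gaussian numerosity prior) and four
govern the temporal dimension (visual and auditory onset noise and the
mean/SD of the Gaussian prior over event time).  In the standard fitting
setup the four temporal parameters are fixed a priori because observers
report only numerosity, so only the five numerosity-side parameters are free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ModelParams",
    "SensorySample",
    "CausalPosterior",
    "Estimates",
    "FIXED_TEMPORAL",
    "default_observer_params",
]

#: Temporal parameters fixed a priori when fitting numerosity reports (ms).
FIXED_TEMPORAL = {
    "sigma_Vt": 60.0,
    "sigma_At": 40.0,
    "mu_tp": 100.0,
    "sigma_tp": 500.0,
}


@dataclass(frozen=True)
class ModelParams:
    """Generative parameters of the 2D causal-inference observer.

    Parameters
    ----------
    sigma_V, sigma_A : float
        SD of the Gaussian sensory noise on visual / auditory numerosity
        evidence (numerosity units).
    p_common : float
        Prior probability that the flash and beep streams share one cause.
    mu_p, sigma_p : float
        Mean and SD of the Gaussian prior over stimulus numerosity.
    sigma_Vt, sigma_At : float
        SD of the Gaussian noise on visual / auditory onset evidence (ms).
    mu_tp, sigma_tp : float
        Mean and SD of the Gaussian prior over event onset time (ms,
        relative to the onset of the first stimulus in the trial).
    """

    sigma_V: float
    sigma_A: float
    p_common: float
    mu_p: float
    sigma_p: float
    sigma_Vt: float = FIXED_TEMPORAL["sigma_Vt"]
    sigma_At: float = FIXED_TEMPORAL["sigma_At"]
    mu_tp: float = FIXED_TEMPORAL["mu_tp"]
    sigma_tp: float = FIXED_TEMPORAL["sigma_tp"]

    def __post_init__(self) -> None:
        for name in ("sigma_V", "sigma_A", "sigma_p", "sigma_Vt", "sigma_At", "sigma_tp"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")
        if not (0.0 <= self.p_common <= 1.0):
            raise ValueError(f"p_common must lie in [0, 1], got {self.p_common!r}")
        for name in ("mu_p", "mu_tp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_observer_params() -> ModelParams:
    """Representative group-mean observer parameters for the flash-beep task.

    Visual numerosity evidence is roughly twice as noisy as auditory
    evidence, the prior over a common cause is moderately strong, and the
    numerosity prior sits between one and two events.  These values serve as
    the default generating truth for synthetic observers.
    """
    return ModelParams(
        sigma_V=0.63,
        sigma_A=0.33,
        p_common=0.62,
        mu_p=1.43,
        sigma_p=1.33,
    )


@dataclass(frozen=True)
class SensorySample:
    """One trial's internal evidence.

    ``x_*`` are numerosity evidence values, ``t_*`` onset evidence in ms.
    Fields for an absent modality are undefined and must not be read; the
    ``has_V`` / ``has_A`` flags record modality presence.
    """

    x_V: float = math.nan
    x_A: float = math.nan
    t_V: float = math.nan
    t_A: float = math.nan
    has_V: bool = True
    has_A: bool = True

    def require_bimodal(self) -> None:
        if not (self.has_V and self.has_A):
            raise ValueError("operation requires a bimodal sample (both modalities present)")


@dataclass(frozen=True)
class CausalPosterior:
    """Posterior over causal structure plus its four likelihood factors."""

    p_c1: float
    L_num_c1: float
    L_num_c2: float
    L_t_c1: float
    L_t_c2: float


@dataclass(frozen=True)
class Estimates:
    """Continuous numerosity estimates for one bimodal trial."""

    s_hat_V: float
    s_hat_A: float
    s_hat_fused: float
    s_hat_V_seg: float
    s_hat_A_seg: float
    p_c1: float = field(default=math.nan)
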