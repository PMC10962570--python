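"""Closed-form forward models for combined T2*-diffusion signals.

Two isotropic models of the voxel signal S(TE, b) acquired at echo time TE
(ms) and diffusion weighting b (s/mm^2):

* **t2s_adc** — a single compartment with mono-exponential T2* relaxation
  and Gaussian diffusion::

      S(TE, b) = s0 * exp(-(TE - te_min)/t2s) * exp(-b * adc)

* **t2s_ivim** — a bicompartmental intravoxel-incoherent-motion model in
  which a perfusing fraction ``f`` of the signal decays with a fast
  pseudo-diffusion coefficient ``d_star`` and its own relaxation time
  ``t2s_p``, while the remaining tissue fraction diffuses with ``adc``
  and relaxes with ``t2s_d``::

      S(TE, b) = s0 * ( f * exp(-b*d_star) * exp(-(TE - te_min)/t2s_p)
                      + (1-f) * exp(-b*adc) * exp(-(TE - te_min)/t2s_d) )

In both models s0 is the observed signal at the shortest echo time of the
scheme with zero diffusion weighting; TE enters only through
(TE - te_min).  Diffusivities are in mm^2/s (typical tissue ADC is about
2e-3), relaxation times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "T2sADCParams",
    "T2sIVIMParams",
    "t2sadc_signal",
    "t2sivim_signal",
    "model_signal",
    "MODEL_IDS",
    "params_type",
]


@dataclass(frozen=True)
class T2sADCParams:
    """Single-compartment parameters: signal scale, relaxation, diffusion.

    s0 : signal at te_min and b = 0 (arbitrary units, >= 0)
    t2s : effective transverse relaxation time, ms (> 0)
    adc : apparent diffusion coefficient, mm^2/s (>= 0)
    """

    s0: float
    t2s: float
    adc: float

    def __post_init__(self) -> None:
        vals = (self.s0, self.t2s, self.adc)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {self}")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        if self.t2s <= 0:
            raise ValueError(f"t2s must be > 0 ms, got {self.t2s}")
        if self.adc < 0:
            raise ValueError(f"adc must be >= 0 mm^2/s, got {self.adc}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.t2s, self.adc], dtype=float)

    @classmethod
    def from_array(cls, x) -> "T2sADCParams":
        s0, t2s, adc = (float(v) for v in x)
        return cls(s0=s0, t2s=t2s, adc=adc)


@dataclass(frozen=True)
class T2sIVIMParams:
    """Bicompartmental parameters.

    s0 : shared signal scale at (te_min, b=0), >= 0
    f : perfusion fraction in [0, 1]
    d_star : pseudo-diffusion coefficient of the perfusing compartment,
        mm^2/s; must exceed ``adc`` (the fast/slow labelling convention)
    t2s_p : perfusing-compartment T2*, ms (> 0)
    adc : diffusing-compartment apparent diffusion coefficient, mm^2/s
    t2s_d : diffusing-compartment T2*, ms (> 0)
    """

    s0: float
    f: float
    d_star: float
    t2s_p: float
    adc: float
    t2s_d: float

    def __post_init__(self) -> None:
        vals = (self.s0, self.f, self.d_star, self.t2s_p, self.adc, self.t2s_d)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {self}")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"perfusion fraction must lie in [0, 1], got {self.f}")
        if self.t2s_p <= 0 or self.t2s_d <= 0:
            raise ValueError(
                f"T2* values must be > 0 ms, got t2s_p={self.t2s_p}, t2s_d={self.t2s_d}"
            )
        if self.adc < 0:
            raise ValueError(f"adc must be >= 0 mm^2/s, got {self.adc}")
        if self.d_star < self.adc:
            raise ValueError(
                f"d_star ({self.d_star}) must be >= adc ({self.adc}): the "
                "larger diffusivity labels the perfusing compartment"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.s0, self.f, self.d_star, self.t2s_p, self.adc, self.t2s_d],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x) -> "T2sIVIMParams":
        s0, f, d_star, t2s_p, adc, t2s_d = (float(v) for v in x)
        return cls(s0=s0, f=f, d_star=d_star, t2s_p=t2s_p, adc=adc, t2s_d=t2s_d)


PARAM_NAMES = {
    "t2s_adc": tuple(f.name for f in fields(T2sADCParams)),
    "t2s_ivim": tuple(f.name for f in fields(T2sIVIMParams)),
}
MODEL_IDS = tuple(PARAM_NAMES)
_PARAM_TYPES = {"t2s_adc": T2sADCParams, "t2s_ivim": T2sIVIMParams}


def params_type(model_id: str):
    """Parameter dataclass for ``model_id`` (raises KeyError if unknown)."""
    try:
        return _PARAM_TYPES[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {MODEL_IDS}"
        ) from None


def t2sadc_signal(params: T2sADCParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Evaluate the single-compartment model on every measurement."""
    dte = scheme.echo_times - scheme.te_min
    return params.s0 * np.exp(-dte / params.t2s - scheme.b_values * params.adc)


def t2sivim_signal(params: T2sIVIMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Evaluate the bicompartmental model on every measurement."""
    dte = scheme.echo_times - scheme.te_min
    b = scheme.b_values
    fast = np.exp(-b * params.d_star - dte / params.t2s_p)
    slow = np.exp(-b * params.adc - dte / params.t2s_d)
    return params.s0 * (params.f * fast + (1.0 - params.f) * slow)


_SIGNAL_FUNCS = {"t2s_adc": t2sadc_signal, "t2s_ivim": t2sivim_signal}


def model_signal(model_id: str, params, scheme: AcquisitionScheme) -> np.ndarray:
    """Dispatch to the forward model named by ``model_id``."""
    try:
        func = _SIGNAL_FUNCS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {MODEL_IDS}"
        ) from None
    expected = _PARAM_TYPES[model_id]
    if not isinstance(params, expected):
        raise TypeError(
            f"model {model_id!r} expects {expected.__name__} parameters, "
            f"got {type(params).__name__}"
        )
    return func(params, scheme)
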