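"""Forward simulation of the four liver kinetic models.

All four models are one- or two-compartment first-order systems driven by an
arterial input C_A(t) and, for the dual-input variants, a portal-venous input
C_PV(t):

* one-tissue compartment model (1TCM):
  dC_T/dt = f C_A(t - dt1) - k C_T(t)
* spleen-delay dual-input (Taniguchi-style): a notional dispersed portal
  compartment dC_PV/dt = f_p C_A(t - dt1) - f_p C_PV(t) feeding
  dC_T/dt = f_A C_A(t - dt1 - dt2) + E f_p C_PV(t - dt2) - k C_T(t),
  with dt1 pre-fixed from a spleen fit;
* fitted-delay dual-input (Rijzewijk-style): same two compartments but with
  an undelayed liver input f_A C_A(t) + E f_p C_PV(t) and dt1 fitted;
* measured-PV dual-input (the new model): the portal input is a measured
  curve, so a single equation suffices:
  dC_T/dt = f_A C_A(t - dt1) + f_P C_PV(t - dt2) - k C_T(t).

Each model is integrated by the explicit one-second recursion

    C_T(i) = f_s * u(i - dt - 1) + (1 - k_s) * C_T(i - 1),   i = 1..T,

with C_T(0) = 0 and per-second rates f_s = f/60, k_s = k/60 (parameters are
stored in the conventional mL/min/mL and /min units).  The recursion,
including its one-sample input lag, is kept exactly in this form; it is a
forward-Euler step of the differential equations above.  The measured liver
signal additionally contains a vascular contribution, modelled as the blood
volume mixture C_PET = (1 - V_B) C_T + V_B * blood, where blood is C_A for
the 1TCM and the flow-weighted mean of C_A and C_PV for the dual-input
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import lfilter

from .curves import SampledCurve

__all__ = [
    "SECONDS_PER_MINUTE",
    "DegenerateParametersError",
    "UnstableRecursionWarning",
    "OneTissueParams",
    "TaniguchiParams",
    "RijzewijkParams",
    "NewModelParams",
    "ModelParams",
    "DerivedQuantities",
    "simulate_1tcm",
    "simulate_pv_compartment",
    "simulate_taniguchi",
    "simulate_rijzewijk",
    "simulate_new_model",
    "blood_input",
    "blend_blood",
    "simulate_pet",
    "derive_quantities",
]

SECONDS_PER_MINUTE = 60.0

#: Delay parameters are integer seconds within this closed interval.
DELAY_RANGE = (0, 65)


class DegenerateParametersError(ValueError):
    """Raised when a parameter combination makes a model expression undefined."""


class UnstableRecursionWarning(UserWarning):
    """Emitted when a per-step washout rate reaches 1 and the recursion may blow up."""


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative rate, got {value}")


def _check_fraction(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_delay(name: str, value: int) -> None:
    if isinstance(value, float) and not value.is_integer():
        raise ValueError(f"{name} must be an integer number of seconds, got {value}")
    lo, hi = DELAY_RANGE
    if not lo <= int(value) <= hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}] s, got {value}")


@dataclass(frozen=True)
class OneTissueParams:
    """1TCM parameters: inflow f (mL/min/mL), washout k (/min), blood volume
    fraction V_B and arterial transit delay dt1 (integer seconds)."""

    f: float
    k: float
    V_B: float = 0.0
    dt1: int = 0

    model_id = "1tcm"

    def __post_init__(self) -> None:
        _check_rate("f", self.f)
        _check_rate("k", self.k)
        _check_fraction("V_B", self.V_B)
        _check_delay("dt1", self.dt1)
        object.__setattr__(self, "dt1", int(self.dt1))


@dataclass(frozen=True)
class TaniguchiParams:
    """Spleen-delay dual-input parameters.

    f_A: arterial flow (mL/min/mL); f_p: portal dispersion rate constant
    (mL/min/mL); E: portosystemic shunting fraction; k: washout (/min);
    V_B: blood volume fraction; dt1: arterial delay fixed from the spleen;
    dt2: additional delay of both liver inputs (integer seconds).
    """

    f_A: float
    f_p: float
    E: float
    k: float
    V_B: float = 0.0
    dt1: int = 0
    dt2: int = 0

    model_id = "taniguchi"

    def __post_init__(self) -> None:
        _check_rate("f_A", self.f_A)
        _check_rate("f_p", self.f_p)
        _check_fraction("E", self.E)
        _check_rate("k", self.k)
        _check_fraction("V_B", self.V_B)
        _check_delay("dt1", self.dt1)
        _check_delay("dt2", self.dt2)
        object.__setattr__(self, "dt1", int(self.dt1))
        object.__setattr__(self, "dt2", int(self.dt2))


@dataclass(frozen=True)
class RijzewijkParams:
    """Fitted-delay dual-input parameters; as :class:`TaniguchiParams` but
    with a single delay dt1 on the dispersed portal compartment only."""

    f_A: float
    f_p: float
    E: float
    k: float
    V_B: float = 0.0
    dt1: int = 0

    model_id = "rijzewijk"

    def __post_init__(self) -> None:
        _check_rate("f_A", self.f_A)
        _check_rate("f_p", self.f_p)
        _check_fraction("E", self.E)
        _check_rate("k", self.k)
        _check_fraction("V_B", self.V_B)
        _check_delay("dt1", self.dt1)
        object.__setattr__(self, "dt1", int(self.dt1))


@dataclass(frozen=True)
class NewModelParams:
    """Measured-PV dual-input parameters: arterial flow f_A, portal flow f_P
    (mL/min/mL), washout k (/min), blood volume fraction V_B and the two
    input delays dt1 (arterial) and dt2 (portal), in integer seconds."""

    f_A: float
    f_P: float
    k: float
    V_B: float = 0.0
    dt1: int = 0
    dt2: int = 0

    model_id = "new_dual_input"

    def __post_init__(self) -> None:
        _check_rate("f_A", self.f_A)
        _check_rate("f_P", self.f_P)
        _check_rate("k", self.k)
        _check_fraction("V_B", self.V_B)
        _check_delay("dt1", self.dt1)
        _check_delay("dt2", self.dt2)
        object.__setattr__(self, "dt1", int(self.dt1))
        object.__setattr__(self, "dt2", int(self.dt2))


ModelParams = Union[OneTissueParams, TaniguchiParams, RijzewijkParams, NewModelParams]


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from fitted parameters.

    f_total: total hepatic blood flow f_A + f_P (mL/min/mL); V_T: water
    partition coefficient f_total / k; portal_fraction: f_P / f_total
    (``None`` for the 1TCM, which has no portal component).
    """

    f_total: float
    V_T: float
    portal_fraction: Optional[float]


def _per_second(rate: float, raw_rates: bool) -> float:
    return rate if raw_rates else rate / SECONDS_PER_MINUTE


def _delayed_input(values: np.ndarray, delay: int) -> np.ndarray:
    """u with u[i] = values(i - delay - 1): the recursion's lagged input term."""
    lag = int(delay) + 1
    out = np.zeros_like(values)
    if lag < values.size:
        out[lag:] = values[: values.size - lag]
    return out


def _decay_recursion(u: np.ndarray, k_s: float) -> np.ndarray:
    """Run C(i) = u(i) + (1 - k_s) C(i - 1) with C(0) = 0 (a first-order IIR)."""
    if k_s >= 1.0:
        warnings.warn(
            f"per-second washout {k_s:.3f} >= 1: the one-second recursion is "
            "unstable for this parameter",
            UnstableRecursionWarning,
            stacklevel=3,
        )
    return lfilter([1.0], [1.0, -(1.0 - k_s)], u)


def simulate_1tcm(
    params: OneTissueParams, aif: SampledCurve, raw_rates: bool = False
) -> SampledCurve:
    """Tissue curve of the delayed 1TCM driven by the arterial input."""
    f_s = _per_second(params.f, raw_rates)
    k_s = _per_second(params.k, raw_rates)
    u = f_s * _delayed_input(aif.values, params.dt1)
    return SampledCurve(_decay_recursion(u, k_s), label="model")


def simulate_pv_compartment(
    f_p: float, dt1: int, aif: SampledCurve, raw_rates: bool = False
) -> SampledCurve:
    """Notional portal compartment: a delayed, dispersed, unit-gain copy of
    the arterial input (dC_PV/dt = f_p C_A(t - dt1) - f_p C_PV)."""
    if f_p <= 0:
        raise ValueError(f"dispersion rate f_p must be positive, got {f_p}")
    fp_s = _per_second(f_p, raw_rates)
    u = fp_s * _delayed_input(aif.values, dt1)
    return SampledCurve(_decay_recursion(u, fp_s), label="portal_vein")


def simulate_taniguchi(
    params: TaniguchiParams, aif: SampledCurve, raw_rates: bool = False
) -> tuple[SampledCurve, SampledCurve]:
    """Tissue and portal-compartment curves of the spleen-delay dual-input model."""
    c_pv = simulate_pv_compartment(params.f_p, params.dt1, aif, raw_rates)
    fa_s = _per_second(params.f_A, raw_rates)
    fp_s = _per_second(params.f_p, raw_rates)
    k_s = _per_second(params.k, raw_rates)
    u = fa_s * _delayed_input(aif.values, params.dt1 + params.dt2)
    u += params.E * fp_s * _delayed_input(c_pv.values, params.dt2)
    return SampledCurve(_decay_recursion(u, k_s), label="model"), c_pv


def simulate_rijzewijk(
    params: RijzewijkParams, aif: SampledCurve, raw_rates: bool = False
) -> tuple[SampledCurve, SampledCurve]:
    """Tissue and portal-compartment curves of the fitted-delay dual-input
    model (undelayed liver inputs; dt1 only delays the portal compartment)."""
    c_pv = simulate_pv_compartment(params.f_p, params.dt1, aif, raw_rates)
    fa_s = _per_second(params.f_A, raw_rates)
    fp_s = _per_second(params.f_p, raw_rates)
    k_s = _per_second(params.k, raw_rates)
    u = fa_s * _delayed_input(aif.values, 0)
    u += params.E * fp_s * _delayed_input(c_pv.values, 0)
    return SampledCurve(_decay_recursion(u, k_s), label="model"), c_pv


def simulate_new_model(
    params: NewModelParams,
    aif: SampledCurve,
    pv: SampledCurve,
    raw_rates: bool = False,
) -> SampledCurve:
    """Tissue curve of the measured-PV dual-input model.

    ``pv`` is a measured portal-vein curve on the same 1-s grid as ``aif``,
    not a simulated compartment.
    """
    if aif.duration != pv.duration:
        raise ValueError("arterial and portal inputs must share the same grid")
    fa_s = _per_second(params.f_A, raw_rates)
    fP_s = _per_second(params.f_P, raw_rates)
    k_s = _per_second(params.k, raw_rates)
    u = fa_s * _delayed_input(aif.values, params.dt1)
    u += fP_s * _delayed_input(pv.values, params.dt2)
    return SampledCurve(_decay_recursion(u, k_s), label="model")


def blood_input(
    params: ModelParams, aif: SampledCurve, pv: Optional[SampledCurve] = None
) -> SampledCurve:
    """The vascular curve entering the blood-volume mixture.

    For the 1TCM this is the arterial input itself; for the dual-input
    models it is the flow-weighted mean of the (undelayed) arterial and
    portal curves, with weights f_A and E*f_p (dispersed-compartment
    variants) or f_A and f_P (measured-PV model).
    """
    if isinstance(params, OneTissueParams):
        return SampledCurve(aif.values.copy(), label="model")
    if pv is None:
        raise ValueError("dual-input blood mixture needs the portal curve")
    if isinstance(params, (TaniguchiParams, RijzewijkParams)):
        w_a, w_p = params.f_A, params.E * params.f_p
    elif isinstance(params, NewModelParams):
        w_a, w_p = params.f_A, params.f_P
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    total = w_a + w_p
    if total <= 0:
        raise DegenerateParametersError(
            "blood mixture undefined: arterial and portal weights sum to zero"
        )
    values = (w_a * aif.values + w_p * pv.values) / total
    return SampledCurve(values, label="model")


def blend_blood(c_t: SampledCurve, blood: SampledCurve, v_b: float) -> SampledCurve:
    """Mix tissue and vascular signal: C_PET = (1 - V_B) C_T + V_B blood."""
    _check_fraction("V_B", v_b)
    if c_t.duration != blood.duration:
        raise ValueError("tissue and blood curves must share the same grid")
    return SampledCurve((1.0 - v_b) * c_t.values + v_b * blood.values, label="model")


def simulate_pet(
    params: ModelParams,
    aif: SampledCurve,
    pv: Optional[SampledCurve] = None,
    raw_rates: bool = False,
) -> SampledCurve:
    """Full model prediction of the measured liver signal for any model.

    Simulates the tissue curve, forms the model's vascular curve and applies
    the blood-volume mixture.  ``pv`` is required (a measured curve) for the
    measured-PV model and ignored by the 1TCM; the dispersed-compartment
    variants generate their own portal curve internally.
    """
    if isinstance(params, OneTissueParams):
        c_t = simulate_1tcm(params, aif, raw_rates)
        blood = blood_input(params, aif)
    elif isinstance(params, TaniguchiParams):
        c_t, c_pv = simulate_taniguchi(params, aif, raw_rates)
        blood = blood_input(params, aif, c_pv)
    elif isinstance(params, RijzewijkParams):
        c_t, c_pv = simulate_rijzewijk(params, aif, raw_rates)
        blood = blood_input(params, aif, c_pv)
    elif isinstance(params, NewModelParams):
        if pv is None:
            raise ValueError("the measured-PV model needs a portal input curve")
        c_t = simulate_new_model(params, aif, pv, raw_rates)
        blood = blood_input(params, aif, pv)
    else:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    return blend_blood(c_t, blood, params.V_B)


def derive_quantities(params: ModelParams) -> DerivedQuantities:
    """Total flow, water partition coefficient and portal flow fraction.

    f_total is f for the 1TCM, f_A + E*f_p for the dispersed-compartment
    dual-input models (the effective portal flow being E*f_p) and f_A + f_P
    for the measured-PV model.  V_T = f_total / k.
    """
    if isinstance(params, OneTissueParams):
        f_total, f_portal = params.f, None
    elif isinstance(params, (TaniguchiParams, RijzewijkParams)):
        f_portal = params.E * params.f_p
        f_total = params.f_A + f_portal
    elif isinstance(params, NewModelParams):
        f_portal = params.f_P
        f_total = params.f_A + f_portal
    else:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    if params.k == 0:
        raise DegenerateParametersError("V_T = f/k is undefined for k = 0")
    portal_fraction = None if f_portal is None else f_portal / f_total
    return DerivedQuantities(
        f_total=f_total, V_T=f_total / params.k, portal_fraction=portal_fraction
    )
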