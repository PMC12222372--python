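"""Least-squares estimation of the kinetic model parameters.

The continuous parameters (flows, washout, fractions) are fitted by an
unconstrained Newton-type minimisation (Levenberg-Marquardt on the residual
vector) of the sum of squared differences

    SSE = sum_{i=1..T} (C_meas(i) - C_PET(i))^2

on the 1-s grid, from the standard initial values f = 1, k = 1, f_A = 0.5,
f_p = 0.6, E = 0.9, f_P = 0.5, V_B = 0.1.  Because the optimiser is
unconstrained, positivity is enforced by an absolute-value transform and the
[0, 1] parameters (E, V_B) by the inverse-logit transform.

The integer transit delays are not part of the continuous search: they are
chosen by exhaustive grid search over 0..65 s (simultaneously for models
with two delays), keeping the delay (pair) with the lowest SSE; ties are
broken towards the smallest dt1, then dt2.  For the spleen-delay dual-input
model, dt1 is first fixed by fitting the delayed 1TCM to the spleen curve
(:func:`fix_delay_from_spleen`).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .curves import FrameTAC, SampledCurve, interpolate_to_seconds
from .kinetics import (
    ModelParams,
    NewModelParams,
    OneTissueParams,
    RijzewijkParams,
    TaniguchiParams,
    DerivedQuantities,
    derive_quantities,
    simulate_pet,
)
from . import metrics as _metrics

__all__ = [
    "DEFAULT_INITIALS",
    "LOGIT_CLAMP",
    "ConfigError",
    "DegenerateDataError",
    "FitConfig",
    "FitResult",
    "objective",
    "transform_params",
    "untransform_params",
    "fit_inner",
    "fit_with_delay_grid",
    "fix_delay_from_spleen",
]

#: Standard initial values for every continuous parameter (by name).
DEFAULT_INITIALS = {
    "f": 1.0,
    "k": 1.0,
    "f_A": 0.5,
    "f_p": 0.6,
    "E": 0.9,
    "f_P": 0.5,
    "V_B": 0.1,
}

#: Raw-scale clamp for logit(0) / logit(1).
LOGIT_CLAMP = 36.0


class ConfigError(ValueError):
    """Raised for inconsistent fit configurations (e.g. an empty delay grid)."""


class DegenerateDataError(ValueError):
    """Raised when the measured curve cannot support a fit (e.g. all zeros)."""


@dataclass(frozen=True)
class _ModelSpec:
    param_cls: type
    continuous: tuple[str, ...]
    transforms: dict[str, str]
    searched_delays: tuple[str, ...]
    fixed_delays: tuple[str, ...]
    n_params: int
    needs_pv: bool
    # alternative inner-fit starts (overrides merged onto the initials);
    # the dual-input likelihoods have a single-input local minimum in which
    # the portal branch collapses to zero, and a portal-dominant start is
    # needed to guarantee the global basin is visited
    extra_starts: tuple = ()


_MODEL_SPECS: dict[str, _ModelSpec] = {
    "1tcm": _ModelSpec(
        OneTissueParams,
        ("f", "k", "V_B"),
        {"f": "abs", "k": "abs", "V_B": "logit"},
        ("dt1",),
        (),
        4,
        False,
    ),
    # Private variant used by the spleen pre-fit when the blood-volume term
    # is switched off; not exposed through the CLI.
    "1tcm_novb": _ModelSpec(
        OneTissueParams,
        ("f", "k"),
        {"f": "abs", "k": "abs"},
        ("dt1",),
        (),
        3,
        False,
    ),
    "taniguchi": _ModelSpec(
        TaniguchiParams,
        ("f_A", "f_p", "E", "k", "V_B"),
        {"f_A": "abs", "f_p": "abs", "E": "logit", "k": "abs", "V_B": "logit"},
        ("dt2",),
        ("dt1",),
        7,
        False,
        extra_starts=(
            {"f_A": 0.1, "f_p": 1.5},
            {"f_A": 0.3, "f_p": 0.6, "E": 0.5, "k": 0.5},
        ),
    ),
    "rijzewijk": _ModelSpec(
        RijzewijkParams,
        ("f_A", "f_p", "E", "k", "V_B"),
        {"f_A": "abs", "f_p": "abs", "E": "logit", "k": "abs", "V_B": "logit"},
        ("dt1",),
        (),
        6,
        False,
        extra_starts=(
            {"f_A": 0.1, "f_p": 1.5},
            {"f_A": 0.3, "f_p": 0.6, "E": 0.5, "k": 0.5},
        ),
    ),
    "new_dual_input": _ModelSpec(
        NewModelParams,
        ("f_A", "f_P", "k", "V_B"),
        {"f_A": "abs", "f_P": "abs", "k": "abs", "V_B": "logit"},
        ("dt1", "dt2"),
        (),
        6,
        True,
        extra_starts=({"f_A": 0.1, "f_P": 1.2},),
    ),
}

MODEL_IDS = ("1tcm", "taniguchi", "rijzewijk", "new_dual_input")


@dataclass
class FitConfig:
    """Everything the fit needs besides the data.

    ``delay_min``/``delay_max``/``delay_stride`` define the integer delay
    grid (seconds).  With ``refine=True`` and a stride > 1, a coarse pass is
    followed by a stride-1 search in a window of +/- (stride - 1) around the
    coarse winner — a documented acceleration of the exhaustive search.
    ``warm_start`` starts each grid cell's inner optimisation from the
    previous cell's solution instead of the standard initials; it roughly
    halves the grid-search time but can hand a poor basin from one cell to
    the next, so it is off by default.
    """

    initials: dict = field(default_factory=lambda: dict(DEFAULT_INITIALS))
    delay_min: int = 0
    delay_max: int = 65
    delay_stride: int = 1
    refine: bool = False
    gtol: float = 1e-8
    max_iter: int = 500
    mse_floor: float = 1e-12
    warm_start: bool = False
    spleen_blood_volume: bool = True
    raw_rates: bool = False
    interp: str = "conserving"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.interp not in ("midpoint", "conserving"):
            raise ConfigError(f"unknown interpolation method '{self.interp}'")
        if not 0 <= self.delay_min <= self.delay_max <= 65:
            raise ConfigError(
                f"delay grid [{self.delay_min}, {self.delay_max}] must sit within [0, 65]"
            )
        if self.delay_stride < 1:
            raise ConfigError("delay stride must be >= 1")
        if self.gtol <= 0 or self.max_iter <= 0 or self.mse_floor <= 0:
            raise ConfigError("tolerances and iteration limits must be positive")

    def delay_grid(self) -> list[int]:
        grid = list(range(self.delay_min, self.delay_max + 1, self.delay_stride))
        if not grid:
            raise ConfigError("empty delay grid")
        return grid

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class FitResult:
    """Outcome of a delay-grid fit.

    ``trace`` records one ``(delays, sse, converged)`` triple per visited
    grid cell; the reported delays are the grid minimiser and ``sse`` is the
    corresponding minimum of the objective.
    """

    model: str
    params: ModelParams
    sse: float
    fitted_cpet: SampledCurve
    derived: Optional[DerivedQuantities]
    metrics: Optional["_metrics.FitMetrics"]
    trace: list
    diagnostics: dict


def transform_params(
    raw: Sequence[float], model: str
) -> dict[str, float]:
    """Map the optimiser's unconstrained vector onto constrained parameters."""
    spec = _MODEL_SPECS[model]
    out = {}
    for name, value in zip(spec.continuous, raw):
        out[name] = abs(value) if spec.transforms[name] == "abs" else float(expit(value))
    return out


def untransform_params(values: dict[str, float], model: str) -> np.ndarray:
    """Inverse of :func:`transform_params` on the constraint interior.

    Positive parameters map to themselves; [0, 1] parameters go through the
    logit, clamped to +/-36 at the boundary (with a warning).
    """
    spec = _MODEL_SPECS[model]
    raw = np.empty(len(spec.continuous))
    for i, name in enumerate(spec.continuous):
        v = values[name]
        if spec.transforms[name] == "abs":
            raw[i] = v
        else:
            if v <= 0.0 or v >= 1.0:
                warnings.warn(
                    f"{name}={v} is on the [0, 1] boundary; clamping its raw "
                    f"value to +/-{LOGIT_CLAMP}",
                    stacklevel=2,
                )
                raw[i] = LOGIT_CLAMP if v >= 1.0 else -LOGIT_CLAMP
            else:
                raw[i] = float(np.clip(logit(v), -LOGIT_CLAMP, LOGIT_CLAMP))
    return raw


def _build_params(
    model: str, values: dict[str, float], delays: dict[str, int]
) -> ModelParams:
    spec = _MODEL_SPECS[model]
    kwargs = dict(values)
    kwargs.update(delays)
    if model == "1tcm_novb":
        kwargs.setdefault("V_B", 0.0)
    return spec.param_cls(**kwargs)


def objective(
    params: ModelParams,
    measured: SampledCurve,
    aif: SampledCurve,
    pv: Optional[SampledCurve] = None,
    raw_rates: bool = False,
    blood_volume: bool = True,
) -> float:
    """Sum of squared differences between the measured curve and the model
    prediction over the full 1-s grid."""
    if measured.duration != aif.duration:
        raise ValueError("measured curve and input must share the same 1-s grid")
    if blood_volume:
        pred = simulate_pet(params, aif, pv, raw_rates)
    else:
        from .kinetics import simulate_1tcm  # local: only the spleen path uses this

        pred = simulate_1tcm(params, aif, raw_rates)
    resid = measured.values - pred.values
    return float(resid @ resid)


@dataclass
class _InnerFit:
    values: dict[str, float]
    raw: np.ndarray
    sse: float
    converged: bool
    n_iter: int


def _make_residuals(
    model: str,
    delays: dict[str, int],
    measured: SampledCurve,
    aif: SampledCurve,
    pv: Optional[SampledCurve],
    raw_rates: bool,
    blood_volume: bool,
):
    """Raw-vector residual function for one delay-grid cell.

    Returns ``measured - C_PET`` as a vector; its squared norm equals
    ``objective(transform_params(raw), ...)`` (the equivalence is exercised
    by the recovery tests).  The delay-shifted input arrays are precomputed
    once per cell (delays are fixed within a cell) and no parameter objects
    are constructed per evaluation.
    """
    from scipy.signal import lfilter

    from .kinetics import _delayed_input  # shared lag convention

    meas = measured.values
    A = aif.values
    scale = 1.0 if raw_rates else 1.0 / 60.0

    def _residual(pred: np.ndarray) -> np.ndarray:
        return meas - pred

    def _decay(u: np.ndarray, k_s: float) -> np.ndarray:
        return lfilter([1.0], [1.0, -(1.0 - k_s)], u)

    if model in ("1tcm", "1tcm_novb"):
        Ad = _delayed_input(A, delays["dt1"])

        def fun(raw: np.ndarray) -> np.ndarray:
            f, k = abs(raw[0]), abs(raw[1])
            ct = _decay(f * scale * Ad, k * scale)
            if blood_volume:
                vb = expit(raw[2])
                return _residual((1.0 - vb) * ct + vb * A)
            return _residual(ct)

        return fun

    if model in ("taniguchi", "rijzewijk"):
        Ad1 = _delayed_input(A, delays["dt1"])
        if model == "taniguchi":
            liver_lag_a = delays["dt1"] + delays["dt2"]
            liver_lag_p = delays["dt2"]
        else:
            liver_lag_a = 0
            liver_lag_p = 0
        Ad_liver = _delayed_input(A, liver_lag_a)

        def fun(raw: np.ndarray) -> np.ndarray:
            fa, fp, k = abs(raw[0]), abs(raw[1]), abs(raw[3])
            E, vb = float(expit(raw[2])), float(expit(raw[4]))
            fps = fp * scale
            cpv = lfilter([fps], [1.0, -(1.0 - fps)], Ad1)
            u = fa * scale * Ad_liver + E * fps * _delayed_input(cpv, liver_lag_p)
            ct = _decay(u, k * scale)
            w = fa + E * fp
            blood = (fa * A + E * fp * cpv) / w if w > 0 else A
            return _residual((1.0 - vb) * ct + vb * blood)

        return fun

    if model == "new_dual_input":
        Ad1 = _delayed_input(A, delays["dt1"])
        P = pv.values
        Pd2 = _delayed_input(P, delays["dt2"])

        def fun(raw: np.ndarray) -> np.ndarray:
            fa, fP, k = abs(raw[0]), abs(raw[1]), abs(raw[2])
            vb = float(expit(raw[3]))
            u = scale * (fa * Ad1 + fP * Pd2)
            ct = _decay(u, k * scale)
            w = fa + fP
            blood = (fa * A + fP * P) / w if w > 0 else A
            return _residual((1.0 - vb) * ct + vb * blood)

        return fun

    raise ConfigError(f"unknown model '{model}'")  # pragma: no cover


def fit_inner(
    model: str,
    delays: dict[str, int],
    measured: SampledCurve,
    aif: SampledCurve,
    pv: Optional[SampledCurve],
    config: FitConfig,
    raw_start: Optional[np.ndarray] = None,
    tight: bool = False,
) -> _InnerFit:
    """Newton-type minimisation of the objective at fixed integer delays.

    The objective is a sum of squares, so the inner solver is a
    trust-region Gauss-Newton method (``least_squares``) on the residual
    vector over the transformed, unconstrained parameters, with Jacobian
    column scaling — it keeps descending the flat, ill-conditioned valleys
    near a perfect fit where finite differences of the scalar SSE drown in
    rounding noise.  The likelihood surfaces are multimodal (the dual-input
    models have a single-input local minimum with the portal branch
    collapsed, and the shunting fraction can saturate its logit), so each
    fit is run from the standard initials plus a small set of deterministic
    alternative starts and the best optimum is kept; an explicit
    ``raw_start`` runs that start only.  ``tight`` pushes the tolerances to
    machine precision (used to polish the winning grid cell).
    Non-convergence within the evaluation budget is flagged, not discarded:
    the achieved SSE still participates in the delay-grid argmin.
    """
    spec = _MODEL_SPECS[model]
    blood_volume = model != "1tcm_novb"
    if raw_start is not None:
        starts = [np.asarray(raw_start, dtype=float)]
    else:
        starts = [
            untransform_params(
                {n: config.initials[n] for n in spec.continuous}, model
            )
        ]
        for overrides in spec.extra_starts:
            merged = {n: config.initials[n] for n in spec.continuous}
            merged.update(overrides)
            starts.append(untransform_params(merged, model))

    residuals = _make_residuals(
        model, delays, measured, aif, pv, config.raw_rates, blood_volume
    )
    if tight:
        tols = dict(ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=20000)
    else:
        tols = dict(
            ftol=1e-9,
            xtol=1e-9,
            gtol=config.gtol,
            max_nfev=config.max_iter * (len(spec.continuous) + 1),
        )

    best = None
    best_sse = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x0 in starts:
            res = least_squares(residuals, x0, method="trf", x_scale="jac", **tols)
            sse = float(res.fun @ res.fun)
            if best is None or sse < best_sse:
                best, best_sse = res, sse
    return _InnerFit(
        values=transform_params(best.x, model),
        raw=np.asarray(best.x, dtype=float),
        sse=best_sse,
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
    )


def _delay_combos(
    model: str, grid: Sequence[int], dt1_fixed: Optional[int]
) -> list[dict[str, int]]:
    spec = _MODEL_SPECS[model]
    combos = []
    names = spec.searched_delays
    for combo in itertools.product(grid, repeat=len(names)):
        delays = dict(zip(names, combo))
        if spec.fixed_delays:
            if dt1_fixed is None:
                raise ConfigError(
                    f"model '{model}' needs dt1 fixed in advance (from the spleen)"
                )
            delays["dt1"] = int(dt1_fixed)
        combos.append(delays)
    return combos


def fit_with_delay_grid(
    model: str,
    measured: SampledCurve,
    aif: SampledCurve,
    pv: Optional[SampledCurve] = None,
    config: Optional[FitConfig] = None,
    dt1_fixed: Optional[int] = None,
    measured_frames: Optional[FrameTAC] = None,
) -> FitResult:
    """Exhaustive delay-grid search wrapped around the inner optimiser.

    Runs :func:`fit_inner` for every delay (or delay pair) on the grid and
    returns the global grid minimiser; ties are broken towards the smallest
    dt1, then the smallest dt2 (the lexicographic visiting order combined
    with strict improvement).  When ``measured_frames`` is given, the
    frame-level error metrics are attached to the result.
    """
    if model not in _MODEL_SPECS:
        raise ConfigError(f"unknown model '{model}'; expected one of {MODEL_IDS}")
    config = config or FitConfig()
    spec = _MODEL_SPECS[model]
    if spec.needs_pv and pv is None:
        raise ConfigError("the measured-PV model needs a portal input curve")
    if not np.any(measured.values):
        raise DegenerateDataError("measured curve is identically zero")

    def search(combos, warm_raw, trace):
        best = None
        best_delays = None
        for delays in combos:
            inner = fit_inner(
                model, delays, measured, aif, pv, config,
                raw_start=warm_raw if config.warm_start else None,
            )
            if config.warm_start:
                warm_raw = inner.raw
            trace.append((dict(delays), inner.sse, inner.converged))
            if best is None or inner.sse < best.sse:
                best, best_delays = inner, delays
        return best, best_delays, warm_raw

    trace: list = []
    combos = _delay_combos(model, config.delay_grid(), dt1_fixed)
    best, best_delays, warm_raw = search(combos, None, trace)
    refined = False

    if config.refine and config.delay_stride > 1:
        lo, hi = config.delay_min, config.delay_max
        window = config.delay_stride - 1
        axes = []
        for name in spec.searched_delays:
            center = best_delays[name]
            axes.append(
                (name, range(max(lo, center - window), min(hi, center + window) + 1))
            )
        fine_combos = []
        for combo in itertools.product(*(rng for _, rng in axes)):
            delays = {name: int(v) for (name, _), v in zip(axes, combo)}
            if spec.fixed_delays:
                delays["dt1"] = int(dt1_fixed)
            fine_combos.append(delays)
        fine_best, fine_delays, _ = search(fine_combos, warm_raw, trace)
        if fine_best.sse < best.sse:
            best, best_delays = fine_best, fine_delays
        refined = True

    # polish the winning cell to machine precision, from its own solution
    # and from the standard multi-start set
    for candidate in (
        fit_inner(
            model, best_delays, measured, aif, pv, config,
            raw_start=best.raw, tight=True,
        ),
        fit_inner(model, best_delays, measured, aif, pv, config, tight=True),
    ):
        if candidate.sse < best.sse:
            best = candidate

    params = _build_params(model, best.values, best_delays)
    blood_volume = model != "1tcm_novb"
    if blood_volume:
        fitted = simulate_pet(params, aif, pv, config.raw_rates)
    else:
        from .kinetics import simulate_1tcm

        fitted = simulate_1tcm(params, aif, config.raw_rates)
    derived = derive_quantities(params) if params.k > 0 else None
    fit_metrics = None
    if measured_frames is not None:
        fit_metrics = _metrics.compute_metrics(
            fitted, measured_frames, spec.n_params, mse_floor=config.mse_floor
        )
    n_conv = sum(1 for _, _, ok in trace if ok)
    return FitResult(
        model=model,
        params=params,
        sse=best.sse,
        fitted_cpet=fitted,
        derived=derived,
        metrics=fit_metrics,
        trace=trace,
        diagnostics={
            "n_cells": len(trace),
            "n_converged": n_conv,
            "refined": refined,
            "winner_converged": best.converged,
            "winner_iterations": best.n_iter,
        },
    )


def fix_delay_from_spleen(
    spleen: FrameTAC, aorta: FrameTAC, config: Optional[FitConfig] = None
) -> int:
    """Fix the arterial transit delay dt1 from the spleen.

    Fits the delayed 1TCM to the spleen curve (the measured spleen activity
    standing in for the tissue concentration) with the full delay grid and
    returns the winning dt1 for use in the spleen-delay dual-input model.
    The blood-volume mixture is included by default and can be switched off
    via ``config.spleen_blood_volume``.
    """
    config = config or FitConfig()
    if not np.any(spleen.values):
        raise DegenerateDataError("spleen curve is identically zero")
    grid_end = int(round(spleen.schedule.span))
    measured = interpolate_to_seconds(spleen, grid_end, method=config.interp)
    aif = interpolate_to_seconds(aorta, grid_end, method=config.interp)
    model = "1tcm" if config.spleen_blood_volume else "1tcm_novb"
    result = fit_with_delay_grid(model, measured, aif, config=config)
    return int(result.params.dt1)
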