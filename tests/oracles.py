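"""Independent fine-step reference solutions for the kinetic models.

These oracles never touch the package's one-second recursion: they evaluate
the continuous first-order systems by direct convolution with the
exponential impulse response on a 0.01-s grid, which is exact for these
linear models up to the fine-grid quadrature error.
"""

import numpy as np
from scipy.signal import fftconvolve

DT_FINE = 0.01


def fine_grid(grid_end=280):
    return np.arange(0.0, grid_end + DT_FINE, DT_FINE)


def gamma_aif_fine(t, amplitude=170.0, onset=8.0, shape=3.0, scale=6.0,
                   recirc_fraction=0.15, recirc_tau=40.0):
    """The synthetic arterial input evaluated analytically on any grid."""
    d = np.maximum(t - onset, 0.0)
    out = amplitude * d**shape * np.exp(-d / scale)
    peak = amplitude * (shape * scale) ** shape * np.exp(-shape)
    out = out + recirc_fraction * peak * (1.0 - np.exp(-d / recirc_tau)) * (d > 0)
    return out


def shift_fine(x, delay_s):
    n = int(round(delay_s / DT_FINE))
    out = np.zeros_like(x)
    if n < x.size:
        out[n:] = x[: x.size - n] if n else x
    return out


def conv_decay(u_per_s, k_per_min, t_fine):
    """Solution of dC/dt = u(t) - (k/60) C(t), C(0) = 0, by convolution."""
    kern = np.exp(-(k_per_min / 60.0) * t_fine) * DT_FINE
    return fftconvolve(u_per_s, kern)[: t_fine.size]


def at_integer_seconds(x_fine, grid_end=280):
    idx = np.round(np.arange(1, grid_end + 1) / DT_FINE).astype(int)
    return x_fine[idx]


def pv_compartment_fine(aif_fine, f_p, delay_s, t_fine):
    return (f_p / 60.0) * conv_decay(shift_fine(aif_fine, delay_s), f_p, t_fine)


def rel_l2(a, b):
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def oracle_1tcm(params, aif_fine, t_fine):
    u = (params.f / 60.0) * shift_fine(aif_fine, params.dt1)
    return conv_decay(u, params.k, t_fine)


def oracle_taniguchi(params, aif_fine, t_fine):
    c_pv = pv_compartment_fine(aif_fine, params.f_p, params.dt1, t_fine)
    u = (params.f_A / 60.0) * shift_fine(aif_fine, params.dt1 + params.dt2)
    u += params.E * (params.f_p / 60.0) * shift_fine(c_pv, params.dt2)
    return conv_decay(u, params.k, t_fine), c_pv


def oracle_rijzewijk(params, aif_fine, t_fine):
    c_pv = pv_compartment_fine(aif_fine, params.f_p, params.dt1, t_fine)
    u = (params.f_A / 60.0) * aif_fine + params.E * (params.f_p / 60.0) * c_pv
    return conv_decay(u, params.k, t_fine), c_pv


def oracle_new_model(params, aif_fine, pv_fine, t_fine):
    u = (params.f_A / 60.0) * shift_fine(aif_fine, params.dt1)
    u += (params.f_P / 60.0) * shift_fine(pv_fine, params.dt2)
    return conv_decay(u, params.k, t_fine)


def measured_curve_fine(curve_values, t_fine):
    """Linear interpolation of a 1-s sampled curve onto the fine grid
    (zero at t = 0), for feeding measured inputs to the oracles."""
    knots = np.concatenate([[0.0], np.arange(1.0, curve_values.size + 1)])
    vals = np.concatenate([[0.0], curve_values])
    return np.interp(t_fine, knots, vals)
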