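"""Brute-force fixed-step Euler reference for the TKTD survival variants.

Kept deliberately independent of the package's piecewise-analytic solver:
states are advanced by explicit first-order Euler on a uniform grid and the
hazard/running-max are accumulated on the same grid.  Linear recurrences are
evaluated with an IIR filter, which is algebraically identical to the Euler
loop but fast enough for very small steps.
"""

import numpy as np
from scipy.signal import lfilter


def euler_survival(variant, params, profile, dt=2e-5, T=None):
    """Times and survival probabilities on the Euler grid."""
    T = profile.end_time if T is None else T
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    cext = np.zeros(n)
    for a, b, c in profile.segments():
        cext[(t[:-1] >= a) & (t[:-1] < b)] = c
    if variant.tk_included == "full":
        tk = variant.tk_params
        cint = lfilter([dt * tk.k_in], [1, -(1 - dt * tk.k_out)], cext)
        cint = np.concatenate([[0.0], cint])
        metric = lfilter([dt * params.k_d], [1, -(1 - dt * params.k_d)], cint[:-1])
        metric = np.concatenate([[0.0], metric])
    else:
        metric = lfilter([dt * params.k_d], [1, -(1 - dt * params.k_d)], cext)
        metric = np.concatenate([[0.0], metric])
    if variant.death_mechanism == "sd":
        integrand = params.k_k * np.maximum(metric - params.z, 0.0) + params.h_b
        H = np.concatenate([[0.0], np.cumsum(integrand[:-1]) * dt])
        S = np.exp(-H)
    else:
        run_max = np.maximum.accumulate(metric)
        with np.errstate(divide="ignore"):
            F = np.where(
                run_max > 0.0,
                1.0 / (1.0 + (run_max / params.alpha) ** (-params.beta)),
                0.0,
            )
        S = (1.0 - F) * np.exp(-params.h_b * t)
    return t, S


def euler_survival_at(variant, params, profile, times, dt=2e-5):
    """Euler survival interpolated onto arbitrary observation times."""
    t, S = euler_survival(variant, params, profile, dt=dt)
    return np.interp(np.asarray(times, dtype=float), t, S)
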