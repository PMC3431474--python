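"""Forward simulation of the four TKTD survival variants.

Two death mechanisms are supported:

* **Stochastic death (SD)** — every organism shares one effect threshold z;
  above it the instantaneous hazard grows in proportion to the exceedance of
  the dose metric (killing rate k_k), on top of a constant background hazard
  h_b.  Survival is S(t) = exp(-H(t)) with H the cumulative hazard.
* **Individual tolerance (IT)** — each organism owns a fixed threshold drawn
  from a log-logistic distribution (median alpha, width beta); death is
  instantaneous on first exceedance, so the fraction dead F(t) is the
  threshold CDF evaluated at the *running maximum* of the dose metric, and
  S(t) = (1 - F(t)) * exp(-h_b t).

Each mechanism runs with either of two dose metrics:

* **full** — measured toxicokinetics included: internal concentration
  C_int (one-compartment model, pre-calibrated k_in/k_out) drives scaled
  damage D* via dD*/dt = k_d (C_int - D*), units nmol/g;
* **reduced** — toxicokinetics lumped: scaled internal concentration C*_int
  follows dC*/dt = k_d (C_ext - C*) directly from the water concentration,
  units nmol/mL, with k_d the dominant (slower) of elimination and damage
  recovery.

All dynamics are linear ODEs driven by a step function, so every segment has
a closed-form solution of the shape ``A + (p + q*tau) exp(-r*tau)`` with at
most two exponential rates.  Integration, threshold-crossing location and
running-maximum tracking are done on these closed forms (root-finding with
Brent's method between analytically-located stationary points), never on a
fixed time grid — trajectories are exact to root-finding tolerance and
independent of the output grid.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from scipy import optimize

from .exceptions import ConfigurationError, DomainError, ParameterError
from .exposure import ExposureProfile
from .tk import TKParameters

__all__ = [
    "SDParameters",
    "ITParameters",
    "ModelVariant",
    "Trajectory",
    "dose_metric",
    "survival",
    "survival_sd",
    "survival_it",
    "background_survival",
]

# relative tolerance below which k_d and k_out are treated as equal and the
# degenerate t*exp(-k t) solution is used (numerical stability near k_d=k_out)
_EQUAL_RATE_RTOL = 1e-9
_BRENT_XTOL = 1e-11


@dataclass(frozen=True)
class SDParameters:
    """Stochastic-death parameters.

    k_d : damage recovery rate (full) or dominant rate constant (reduced), d^-1
    k_k : killing rate, g nmol^-1 d^-1 (full) or mL nmol^-1 d^-1 (reduced)
    z   : effect threshold, nmol/g (full) or nmol/mL (reduced)
    h_b : background hazard rate, d^-1
    """

    k_d: float
    k_k: float
    z: float
    h_b: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d <= 0 or self.k_k <= 0:
            raise ParameterError("k_d and k_k must be strictly positive")
        if self.z < 0 or self.h_b < 0:
            raise ParameterError("z and h_b must be non-negative")


@dataclass(frozen=True)
class ITParameters:
    """Individual-tolerance parameters.

    k_d   : dose-metric rate constant, d^-1
    alpha : median of the log-logistic threshold distribution (dose-metric units)
    beta  : width (shape) parameter of the distribution, unitless
    h_b   : background hazard rate, d^-1
    """

    k_d: float
    alpha: float
    beta: float
    h_b: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("k_d, alpha and beta must be strictly positive")
        if self.h_b < 0:
            raise ParameterError("h_b must be non-negative")


TDParameters = Union[SDParameters, ITParameters]


@dataclass(frozen=True)
class ModelVariant:
    """Which death mechanism and which dose metric a model uses.

    Full variants require pre-calibrated toxicokinetic parameters; reduced
    variants must not carry any.
    """

    death_mechanism: Literal["sd", "it"]
    tk_included: Literal["full", "reduced"]
    tk_params: TKParameters | None = None

    def __post_init__(self) -> None:
        if self.death_mechanism not in ("sd", "it"):
            raise ConfigurationError("death_mechanism must be 'sd' or 'it'")
        if self.tk_included not in ("full", "reduced"):
            raise ConfigurationError("tk_included must be 'full' or 'reduced'")
        if self.tk_included == "full" and self.tk_params is None:
            raise ConfigurationError("full variants require pre-calibrated TK parameters")
        if self.tk_included == "reduced" and self.tk_params is not None:
            raise ConfigurationError("reduced variants must not carry TK parameters")

    @property
    def name(self) -> str:
        return f"{self.death_mechanism}-{self.tk_included}"

    @classmethod
    def from_name(cls, name: str, tk_params: TKParameters | None = None) -> "ModelVariant":
        """Parse names like ``'sd-full'`` or ``'it-reduced'``."""
        mech, _, tk = name.partition("-")
        return cls(mech, tk, tk_params if tk == "full" else None)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Trajectory:
    """Dense model output at the requested times.

    ``cumulative_hazard`` is filled for SD models, ``threshold_cdf`` for IT
    models; the other is None.
    """

    times: np.ndarray
    dose_metric: np.ndarray
    survival: np.ndarray
    cumulative_hazard: np.ndarray | None = None
    threshold_cdf: np.ndarray | None = None


# --------------------------------------------------------------------------
# closed-form segment solutions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _Segment:
    """Closed-form dose-metric solution on [t0, t1]:

    value(tau) = const + sum_i (coef_i + tcoef_i * tau) * exp(-rate_i * tau)

    with tau measured from t0.  At most two terms occur (double-exponential
    full-model solution); the t*exp form appears only in the equal-rate
    degenerate case.
    """

    t0: float
    t1: float
    const: float
    terms: tuple[tuple[float, float, float], ...]  # (coef, rate, tcoef)

    @property
    def length(self) -> float:
        return self.t1 - self.t0

    def value_s(self, tau: float) -> float:
        """Scalar fast path of :meth:`value`."""
        v = self.const
        for coef, rate, tcoef in self.terms:
            v += (coef + tcoef * tau) * math.exp(-rate * tau)
        return v

    def value(self, tau):
        if np.isscalar(tau):
            return self.value_s(float(tau))
        tau = np.asarray(tau, dtype=float)
        v = np.full(tau.shape, self.const)
        for coef, rate, tcoef in self.terms:
            v = v + (coef + tcoef * tau) * np.exp(-rate * tau)
        return v

    def deriv(self, tau: float) -> float:
        d = 0.0
        for coef, rate, tcoef in self.terms:
            d += (tcoef - rate * (coef + tcoef * tau)) * math.exp(-rate * tau)
        return d

    def integral(self, a: float, b: float) -> float:
        """Exact integral of value over [a, b] (tau coordinates)."""

        def anti(tau: float) -> float:
            s = self.const * tau
            for coef, rate, tcoef in self.terms:
                s -= ((coef + tcoef * tau) / rate + tcoef / rate**2) * math.exp(-rate * tau)
            return s

        return anti(b) - anti(a)

    def stationary_point(self) -> float | None:
        """Interior zero of the derivative in (0, length), if any.

        With at most two exponential terms the derivative has at most one
        sign change, located in closed form.
        """
        terms = self.terms
        if len(terms) == 0:
            return None
        if len(terms) == 1:
            coef, rate, tcoef = terms[0]
            if tcoef == 0.0:
                return None
            tau = (tcoef - rate * coef) / (rate * tcoef)
        else:
            (c1, r1, _), (c2, r2, _) = terms
            # -r1 c1 e^{-r1 t} - r2 c2 e^{-r2 t} = 0
            if c1 == 0.0 or c2 == 0.0 or r1 == r2:
                return None
            ratio = -(r2 * c2) / (r1 * c1)
            if ratio <= 0.0:
                return None
            tau = math.log(ratio) / (r2 - r1)
        return tau if 0.0 < tau < self.length else None


def _tk_segments(profile: ExposureProfile, tk: TKParameters, c0: float = 0.0) -> list[_Segment]:
    """Closed-form internal-concentration segments (one-compartment model)."""
    segs: list[_Segment] = []
    state = c0
    for a, b, c in profile.segments():
        asym = tk.k_in * c / tk.k_out
        segs.append(_Segment(a, b, asym, ((state - asym, tk.k_out, 0.0),)))
        state = asym + (state - asym) * math.exp(-tk.k_out * (b - a))
    return segs


def _reduced_segments(profile: ExposureProfile, k_d: float, c0: float = 0.0) -> list[_Segment]:
    """Scaled-internal-concentration segments (reduced dose metric)."""
    segs: list[_Segment] = []
    state = c0
    for a, b, c in profile.segments():
        segs.append(_Segment(a, b, c, ((state - c, k_d, 0.0),)))
        state = c + (state - c) * math.exp(-k_d * (b - a))
    return segs


def _damage_segments(cint_segs: Sequence[_Segment], k_d: float) -> list[_Segment]:
    """Scaled-damage segments driven by closed-form internal concentration.

    Within a segment C_int(tau) = A + B exp(-k_out tau), so
    D*(tau) = A + P exp(-k_out tau) + Q exp(-k_d tau) with
    P = k_d B / (k_d - k_out), Q = D0 - A - P.  When k_d ~ k_out the limit
    D*(tau) = A + (k_d B tau + D0 - A) exp(-k tau) is used instead.
    """
    segs: list[_Segment] = []
    state = 0.0
    for cs in cint_segs:
        A = cs.const
        (B, k_out, _), = cs.terms
        if abs(k_d - k_out) <= _EQUAL_RATE_RTOL * max(k_d, k_out):
            seg = _Segment(cs.t0, cs.t1, A, ((state - A, k_d, k_d * B),))
        else:
            P = k_d * B / (k_d - k_out)
            terms = []
            if P != 0.0:
                terms.append((P, k_out, 0.0))
            terms.append((state - A - P, k_d, 0.0))
            seg = _Segment(cs.t0, cs.t1, A, tuple(terms))
        segs.append(seg)
        state = seg.value_s(seg.length)
    return segs


def dose_metric_segments(
    variant: ModelVariant, params: TDParameters, profile: ExposureProfile
) -> list[_Segment]:
    """Closed-form segments of the variant's dose metric over the profile."""
    if variant.tk_included == "full":
        assert variant.tk_params is not None
        return _damage_segments(_tk_segments(profile, variant.tk_params), params.k_d)
    return _reduced_segments(profile, params.k_d)


def _locate(segs: Sequence[_Segment], t: float) -> int:
    """Index of the segment containing t (right-open; end time maps to last)."""
    i = bisect.bisect_right([s.t0 for s in segs], t) - 1
    return min(max(i, 0), len(segs) - 1)


def dose_metric(
    variant: ModelVariant,
    params: TDParameters,
    profile: ExposureProfile,
    times: Sequence[float],
) -> np.ndarray:
    """Dose metric (D* for full, C*_int for reduced) at the given times."""
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > profile.end_time):
        raise DomainError("times outside the profile domain")
    segs = dose_metric_segments(variant, params, profile)
    out = np.empty_like(t)
    for j, tj in enumerate(t):
        s = segs[_locate(segs, tj)]
        out[j] = s.value_s(tj - s.t0)
    return out


# --------------------------------------------------------------------------
# stochastic death
# --------------------------------------------------------------------------


def _monotone_pieces(seg: _Segment, a: float, b: float) -> list[tuple[float, float]]:
    sp = seg.stationary_point()
    if sp is not None and a < sp < b:
        return [(a, sp), (sp, b)]
    return [(a, b)]


def _exceedance_integral(seg: _Segment, a: float, b: float, z: float) -> float:
    """Exact integral of max(value - z, 0) over [a, b] (tau coordinates).

    Threshold crossings are located by Brent root-finding on each monotone
    piece of the closed-form solution, then the integrand is integrated
    analytically between crossings.
    """
    if b <= a:
        return 0.0
    total = 0.0
    for lo, hi in _monotone_pieces(seg, a, b):
        flo = seg.value_s(lo) - z
        fhi = seg.value_s(hi) - z
        if flo <= 0.0 and fhi <= 0.0:
            continue
        if flo >= 0.0 and fhi >= 0.0:
            total += seg.integral(lo, hi) - z * (hi - lo)
            continue
        root = optimize.brentq(seg.value_s, lo, hi, args=(), xtol=_BRENT_XTOL) if False else optimize.brentq(lambda x: seg.value_s(x) - z, lo, hi, xtol=_BRENT_XTOL)
        u, v = (root, hi) if flo < 0.0 else (lo, root)
        total += seg.integral(u, v) - z * (v - u)
    return total


def survival_sd(
    variant: ModelVariant,
    params: SDParameters,
    profile: ExposureProfile,
    times: Sequence[float],
) -> Trajectory:
    """Stochastic-death trajectory: dose metric, cumulative hazard, survival.

    dH/dt = k_k * max(metric - z, 0) + h_b,  S(t) = exp(-H(t)).
    """
    if variant.death_mechanism != "sd":
        raise ConfigurationError("survival_sd requires an SD variant")
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > profile.end_time):
        raise DomainError("times outside the profile domain")
    segs = dose_metric_segments(variant, params, profile)
    # cumulative toxic hazard at each segment start
    cum = np.zeros(len(segs) + 1)
    for i, s in enumerate(segs):
        cum[i + 1] = cum[i] + _exceedance_integral(s, 0.0, s.length, params.z)
    metric = np.empty_like(t)
    hazard = np.empty_like(t)
    for j, tj in enumerate(t):
        i = _locate(segs, tj)
        s = segs[i]
        metric[j] = s.value_s(tj - s.t0)
        hazard[j] = (
            params.k_k * (cum[i] + _exceedance_integral(s, 0.0, tj - s.t0, params.z))
            + params.h_b * tj
        )
    surv = np.exp(-hazard)
    return Trajectory(t, metric, surv, cumulative_hazard=hazard)


# --------------------------------------------------------------------------
# individual tolerance
# --------------------------------------------------------------------------


def _segment_max_until(seg: _Segment, tau: float) -> float:
    """Maximum of the segment solution over [0, tau]."""
    cand = [seg.value_s(0.0), seg.value_s(tau)]
    sp = seg.stationary_point()
    if sp is not None and sp < tau:
        cand.append(seg.value_s(sp))
    return max(cand)


def survival_it(
    variant: ModelVariant,
    params: ITParameters,
    profile: ExposureProfile,
    times: Sequence[float],
) -> Trajectory:
    """Individual-tolerance trajectory: dose metric, threshold CDF, survival.

    F(t) is the log-logistic CDF (median alpha, width beta) of the running
    maximum of the dose metric; S(t) = (1 - F(t)) exp(-h_b t).  Running
    maxima are tracked exactly: interior extrema of each closed-form segment
    are located analytically, so F never depends on an output grid.
    """
    if variant.death_mechanism != "it":
        raise ConfigurationError("survival_it requires an IT variant")
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > profile.end_time):
        raise DomainError("times outside the profile domain")
    segs = dose_metric_segments(variant, params, profile)
    # running max at each segment start
    run = np.zeros(len(segs) + 1)
    for i, s in enumerate(segs):
        run[i + 1] = max(run[i], _segment_max_until(s, s.length))
    metric = np.empty_like(t)
    cdf = np.empty_like(t)
    for j, tj in enumerate(t):
        i = _locate(segs, tj)
        s = segs[i]
        metric[j] = s.value_s(tj - s.t0)
        m = max(run[i], _segment_max_until(s, tj - s.t0))
        if m <= 0.0:
            cdf[j] = 0.0
        else:
            cdf[j] = 1.0 / (1.0 + (m / params.alpha) ** (-params.beta))
    surv = (1.0 - cdf) * np.exp(-params.h_b * t)
    return Trajectory(t, metric, surv, threshold_cdf=cdf)


def survival(
    variant: ModelVariant,
    params: TDParameters,
    profile: ExposureProfile,
    times: Sequence[float],
) -> Trajectory:
    """Dispatch to :func:`survival_sd` or :func:`survival_it` by variant."""
    if variant.death_mechanism == "sd":
        if not isinstance(params, SDParameters):
            raise ConfigurationError("SD variant requires SDParameters")
        return survival_sd(variant, params, profile, times)
    if not isinstance(params, ITParameters):
        raise ConfigurationError("IT variant requires ITParameters")
    return survival_it(variant, params, profile, times)


def background_survival(h_b: float, t) -> float | np.ndarray:
    """Background survival exp(-h_b * t) of unexposed organisms."""
    if h_b < 0:
        raise DomainError("h_b must be non-negative")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("t must be non-negative")
    out = np.exp(-h_b * arr)
    return out if out.shape else float(out)
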