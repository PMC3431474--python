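"""One-compartment toxicokinetics.

The organism is treated as a single well-mixed compartment.  Internal
concentration C_int (nmol/g wet weight) follows

    dC_int/dt = k_in * C_ext(t) - k_out * C_int,

with uptake rate constant k_in (mL g^-1 d^-1) and total loss rate constant
k_out (d^-1; elimination plus biotransformation of the parent compound —
losses are not split further).  With piecewise-constant external
concentration the ODE is solved exactly segment by segment:

    C_int(t) = A + (C_int(t_seg) - A) * exp(-k_out * (t - t_seg)),
    A = k_in * c / k_out.

Derived quantities: the bioaccumulation factor BAF = k_in / k_out (L/kg),
the time to eliminate a given fraction of the body burden, and the
lipid-normalised internal lethal concentration ILC50 = BAF * LC50 / lipid
fraction (converted nmol -> umol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .exceptions import DataError, DomainError, ParameterError
from .exposure import ExposureProfile

__all__ = [
    "TKParameters",
    "TKObservations",
    "simulate_internal",
    "fit_tk",
    "TKFitResult",
    "baf",
    "elimination_time",
    "lipid_normalized_ilc50",
]


@dataclass(frozen=True)
class TKParameters:
    """Uptake (mL g^-1 d^-1) and total loss (d^-1) rate constants."""

    k_in: float
    k_out: float

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise ParameterError("k_in and k_out must be strictly positive")


@dataclass(frozen=True)
class TKObservations:
    """Internal-concentration measurements paired with their exposure profile.

    Concentrations are means of pooled whole-body samples, nmol/g wet weight.
    """

    times: tuple[float, ...]
    internal_concentrations: tuple[float, ...]
    exposure: ExposureProfile

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        c = tuple(float(x) for x in self.internal_concentrations)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "internal_concentrations", c)
        if len(t) != len(c):
            raise DataError("times and concentrations must have equal length")
        if any(x < 0 or x > self.exposure.end_time for x in t):
            raise DomainError("observation times outside exposure domain")
        if any(x < 0 for x in c):
            raise DataError("internal concentrations must be non-negative")


def simulate_internal(
    profile: ExposureProfile,
    params: TKParameters,
    times: Sequence[float],
    c0: float = 0.0,
) -> np.ndarray:
    """Exact internal concentrations at ``times`` (sorted, within the profile).

    Organisms start uncontaminated by default (``c0 = 0`` at t=0).
    """
    if c0 < 0:
        raise DomainError("initial internal concentration must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.size and (t[0] < 0 or t[-1] > profile.end_time or np.any(np.diff(t) < 0)):
        raise DomainError("times must be sorted and within the profile domain")
    out = np.empty_like(t)
    state = float(c0)
    segs = profile.segments()
    for j, (a, b, c) in enumerate(segs):
        asym = params.k_in * c / params.k_out
        mask = (t >= a) & ((t <= b) if j == len(segs) - 1 else (t < b))
        out[mask] = asym + (state - asym) * np.exp(-params.k_out * (t[mask] - a))
        state = asym + (state - asym) * math.exp(-params.k_out * (b - a))
    return out


@dataclass
class TKFitResult:
    """Least-squares TK calibration result."""

    params: TKParameters
    rss: float
    stderr: dict[str, float]
    converged: bool
    n_evaluations: int


def fit_tk(
    datasets: Sequence[TKObservations],
    init: TKParameters | None = None,
) -> TKFitResult:
    """Least-squares fit of (k_in, k_out) jointly to all datasets.

    All residuals (model minus observed internal concentration, untransformed)
    are pooled with equal weight; a single parameter pair is returned even
    when uptake-only and uptake+depuration designs are mixed.  Approximate
    standard errors come from the Jacobian at the optimum.
    """
    if not datasets:
        raise DataError("at least one TK dataset required")
    n_obs = sum(len(d.times) for d in datasets)
    if n_obs < 2:
        raise DataError("need at least as many observations as parameters (2)")
    if init is None:
        init = TKParameters(10.0, 1.0)

    def residuals(logp: np.ndarray) -> np.ndarray:
        p = TKParameters(*np.exp(np.clip(logp, -30, 30)))
        res = []
        for d in datasets:
            model = simulate_internal(d.exposure, p, d.times)
            res.append(model - np.asarray(d.internal_concentrations))
        return np.concatenate(res)

    sol = optimize.least_squares(
        residuals, np.log([init.k_in, init.k_out]), method="lm", max_nfev=2000
    )
    est = np.exp(sol.x)
    params = TKParameters(*est)
    rss = float(2 * sol.cost)
    dof = max(n_obs - 2, 1)
    try:
        cov_log = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        se = np.sqrt(np.diag(cov_log)) * est  # delta method from log scale
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return TKFitResult(
        params=params,
        rss=rss,
        stderr={"k_in": float(se[0]), "k_out": float(se[1])},
        converged=bool(sol.success),
        n_evaluations=int(sol.nfev),
    )


def baf(params: TKParameters) -> float:
    """Bioaccumulation factor k_in / k_out (mL/g, i.e. L/kg)."""
    return params.k_in / params.k_out


def elimination_time(params: TKParameters, fraction: float = 0.95) -> float:
    """Time (days) to eliminate ``fraction`` of the body burden in clean water."""
    if not 0.0 < fraction < 1.0:
        raise DomainError("fraction must lie strictly between 0 and 1")
    return -math.log(1.0 - fraction) / params.k_out


def lipid_normalized_ilc50(baf_l_per_kg: float, lc50: float, lipid_fraction: float) -> float:
    """Lipid-normalised internal lethal concentration, umol per g lipid.

    ILC50 = BAF [L/kg] x LC50 [nmol/mL] / lipid fraction, with nmol -> umol.
    """
    if baf_l_per_kg <= 0 or lc50 <= 0:
        raise DomainError("BAF and LC50 must be positive")
    if not 0.0 < lipid_fraction <= 1.0:
        raise DomainError("lipid fraction must lie in (0, 1]")
    return baf_l_per_kg * lc50 / lipid_fraction / 1000.0
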