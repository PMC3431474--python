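"""Log-logistic dose-response fits for daily LC50 values.

Survival after a fixed exposure duration is modelled as a two-parameter
sigmoid of log concentration with the top fixed at 100% and the bottom at
0%:

    survival% = 100 / (1 + (c / LC50)^slope),

fitted by least squares on percent survival versus log10 concentration.
95% confidence limits come from the asymptotic covariance of the fitted
log10(LC50), giving the usual asymmetric interval on the concentration
scale (the convention of standard dose-response software).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import DataError, DomainError
from .calibration import SurvivalDataset

__all__ = ["DoseResponsePoint", "LCxResult", "fit_lc50", "lc_profile_over_days"]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One tested concentration with its surviving fraction and group size."""

    concentration: float
    fraction_surviving: float
    n: int

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DomainError("concentration must be positive")
        if not 0.0 <= self.fraction_surviving <= 1.0:
            raise DomainError("fraction_surviving must lie in [0, 1]")


@dataclass
class LCxResult:
    """Fitted LC50 with Hill slope and asymptotic 95% confidence limits."""

    lc50: float
    hill_slope: float
    ci_95: tuple[float, float]
    identifiable: bool = True
    day: int | None = None


def _curve(logc: np.ndarray, log_lc50: float, slope: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** (slope * (logc - log_lc50)))


def fit_lc50(points: Sequence[DoseResponsePoint], day: int | None = None) -> LCxResult:
    """Least-squares log-logistic fit of percent survival vs log10 concentration.

    Requires at least three distinct concentrations.  Data entirely above or
    entirely below 50% survival do not pin down the midpoint; the fit is then
    returned with ``identifiable=False`` and NaN confidence limits rather
    than raising.
    """
    if len({p.concentration for p in points}) < 3:
        raise DataError("need at least three distinct concentrations")
    logc = np.log10([p.concentration for p in points])
    y = 100.0 * np.asarray([p.fraction_surviving for p in points])
    identifiable = y.min() < 50.0 < y.max()
    p0 = (float(np.median(logc)), 3.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = optimize.curve_fit(_curve, logc, y, p0=p0, maxfev=10000)
    lc50 = 10.0 ** popt[0]
    if identifiable and np.all(np.isfinite(pcov)):
        dof = max(len(y) - 2, 1)
        tval = stats.t.ppf(0.975, dof)
        se = np.sqrt(pcov[0, 0])
        ci = (10.0 ** (popt[0] - tval * se), 10.0 ** (popt[0] + tval * se))
    else:
        identifiable = False
        ci = (float("nan"), float("nan"))
    return LCxResult(
        lc50=float(lc50),
        hill_slope=float(popt[1]),
        ci_95=ci,
        identifiable=identifiable,
        day=day,
    )


def lc_profile_over_days(acute_datasets: Sequence[SurvivalDataset]) -> list[LCxResult]:
    """LC50 for every observation day of a constant-exposure acute series.

    Each dataset is one tested concentration (its profile must be constant).
    Days at which no dataset reports a count are skipped with a warning, as
    is any violation of the expected non-increasing LC50-over-time pattern
    (flagged, never forced).
    """
    if not acute_datasets:
        raise DataError("no acute datasets supplied")
    days = sorted({t for ds in acute_datasets for t in ds.observation_times if t > 0})
    results: list[LCxResult] = []
    for d in days:
        pts = []
        for ds in acute_datasets:
            if d not in ds.observation_times:
                continue
            i = ds.observation_times.index(d)
            pts.append(
                DoseResponsePoint(
                    concentration=ds.exposure.concentration_at(0.0),
                    fraction_surviving=ds.survivor_counts[i] / ds.n_initial,
                    n=ds.n_initial,
                )
            )
        if len(pts) < 3:
            warnings.warn(f"day {d}: fewer than three concentrations observed; skipped")
            continue
        results.append(fit_lc50(pts, day=int(d)))
    lcs = [r.lc50 for r in results if r.identifiable]
    if any(b > a * (1 + 1e-9) for a, b in zip(lcs, lcs[1:])):
        warnings.warn("LC50 sequence increases with exposure time; check the data")
    return results
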