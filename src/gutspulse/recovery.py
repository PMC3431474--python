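"""Organism recovery times after a defined exposure pulse.

Recovery time is the time, measured from the start of a single constant
pulse (1 day by default), at which the model's dose metric has fallen to
5% of the maximum it reached — i.e. 95% organism recovery.  Because the
dose-metric dynamics are linear, the result does not depend on the pulse
concentration.

For reduced models the metric peaks exactly at pulse end and decays as a
single exponential, so recovery time = pulse_duration + ln(20)/k_d.  For
full models the scaled damage keeps rising briefly after transfer to clean
water (the internal concentration has not yet emptied) and then decays as a
double exponential; the peak and the 5% crossing are located on the
closed-form solution.
"""

from __future__ import annotations

import math
from typing import Sequence

from scipy import optimize

from .exceptions import DomainError, GutsError
from .exposure import ExposureProfile
from .survival import (
    ModelVariant,
    TDParameters,
    _monotone_pieces,
    _segment_max_until,
    dose_metric_segments,
)

__all__ = ["recovery_time"]


def recovery_time(
    variant: ModelVariant,
    params: TDParameters,
    pulse_duration: float = 1.0,
    pulse_concentration: float = 28.0,
    recovery_fraction: float = 0.95,
    origin: str = "pulse_start",
) -> float:
    """Time for the dose metric to fall to (1 - recovery_fraction) of its max.

    Parameters
    ----------
    origin
        ``'pulse_start'`` (default) measures from the start of the pulse,
        ``'pulse_end'`` from the transfer to clean water.
    """
    if pulse_duration <= 0:
        raise DomainError("pulse_duration must be positive")
    if not 0.0 < recovery_fraction < 1.0:
        raise DomainError("recovery_fraction must lie in (0, 1)")
    if origin not in ("pulse_start", "pulse_end"):
        raise DomainError("origin must be 'pulse_start' or 'pulse_end'")
    rates = [params.k_d]
    if variant.tk_included == "full":
        assert variant.tk_params is not None
        rates.append(variant.tk_params.k_out)
    horizon = pulse_duration + 100.0 / min(rates)
    profile = ExposureProfile.from_segments(
        [(0.0, pulse_duration, pulse_concentration), (pulse_duration, horizon, 0.0)]
    )
    segs = dose_metric_segments(variant, params, profile)

    # global maximum of the metric and the time it occurs
    peak_val, peak_t = 0.0, 0.0
    for s in segs:
        for lo, hi in _monotone_pieces(s, 0.0, s.length):
            for tau in (lo, hi):
                v = float(s.value(tau))
                if v > peak_val:
                    peak_val, peak_t = v, s.t0 + tau
    if peak_val <= 0.0:
        raise GutsError("dose metric never becomes positive")
    target = (1.0 - recovery_fraction) * peak_val

    # first crossing below the target after the peak
    for s in segs:
        if s.t1 <= peak_t:
            continue
        start = max(0.0, peak_t - s.t0)
        for lo, hi in _monotone_pieces(s, start, s.length):
            vlo, vhi = float(s.value(lo)), float(s.value(hi))
            if vlo >= target and vhi < target:
                root = optimize.brentq(
                    lambda x: float(s.value(x)) - target, lo, hi, xtol=1e-12
                )
                t = s.t0 + root
                return t if origin == "pulse_start" else t - pulse_duration
    raise GutsError(
        f"dose metric did not drop to {(1 - recovery_fraction):.0%} of its "
        f"maximum within the {horizon:.1f}-day horizon"
    )
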