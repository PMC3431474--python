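"""Piecewise-constant exposure scenarios.

External concentration in water drives every downstream model in this
package.  Exposure is represented as a step function of time: a sequence of
segments, each with a constant concentration, covering ``[0, end_time]``.
Segments are left-closed / right-open, so the value *at* a breakpoint is the
new segment's concentration — the convention the event-driven ODE solvers
rely on.

Units are fixed package-wide: time in days, water concentration in nmol/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DomainError

__all__ = ["ExposureProfile", "concentration_at", "time_weighted_average"]


@dataclass(frozen=True)
class ExposureProfile:
    """A piecewise-constant external concentration time series.

    Parameters
    ----------
    start_times
        Segment start times in days; strictly increasing, first must be 0.
    concentrations
        One non-negative concentration (nmol/mL) per segment.
    end_time
        End of the scenario in days; must exceed the last start time.
    """

    start_times: tuple[float, ...]
    concentrations: tuple[float, ...]
    end_time: float

    def __post_init__(self) -> None:
        st = tuple(float(t) for t in self.start_times)
        cc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "concentrations", cc)
        object.__setattr__(self, "end_time", float(self.end_time))
        if len(st) == 0 or len(st) != len(cc):
            raise DomainError("need one concentration per segment and at least one segment")
        if st[0] != 0.0:
            raise DomainError("first segment must start at t=0")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise DomainError("segment start times must be strictly increasing")
        if any(c < 0 for c in cc):
            raise DomainError("concentrations must be non-negative")
        if self.end_time <= st[-1]:
            raise DomainError("end_time must exceed the last segment start")

    # ------------------------------------------------------------------ build
    @classmethod
    def constant(cls, concentration: float, end_time: float) -> "ExposureProfile":
        """Constant exposure at one concentration over ``[0, end_time]``."""
        return cls((0.0,), (float(concentration),), end_time)

    @classmethod
    def from_segments(cls, segments: Iterable[tuple[float, float, float]]) -> "ExposureProfile":
        """Build from ``(t_start, t_end, concentration)`` triples.

        Segments must be contiguous and start at 0.
        """
        segs = sorted(segments)
        starts, concs = [], []
        for i, (a, b, c) in enumerate(segs):
            if i == 0 and a != 0.0:
                raise DomainError("segments must start at t=0")
            if i > 0 and a != segs[i - 1][1]:
                raise DomainError("segments must be contiguous")
            starts.append(a)
            concs.append(c)
        return cls(tuple(starts), tuple(concs), segs[-1][1])

    @classmethod
    def pulses(
        cls,
        pulse_starts: Sequence[float],
        pulse_duration: float,
        concentration: float,
        end_time: float,
    ) -> "ExposureProfile":
        """Rectangular pulses of equal height on a clean-water background."""
        starts, concs = [], []
        t = 0.0
        for p in sorted(pulse_starts):
            if p > t:
                starts.append(t)
                concs.append(0.0)
            starts.append(p)
            concs.append(float(concentration))
            t = p + pulse_duration
        if t < end_time:
            starts.append(t)
            concs.append(0.0)
        return cls(tuple(starts), tuple(concs), end_time)

    # ------------------------------------------------------------------ query
    def segments(self) -> list[tuple[float, float, float]]:
        """Return ``(t_start, t_end, concentration)`` triples covering the profile."""
        edges = list(self.start_times) + [self.end_time]
        return [
            (edges[i], edges[i + 1], self.concentrations[i])
            for i in range(len(self.concentrations))
        ]

    def concentration_at(self, t: float) -> float:
        """Concentration at time ``t`` (right-open convention at breakpoints)."""
        t = float(t)
        if t < 0.0 or t > self.end_time:
            raise DomainError(f"t={t} outside profile domain [0, {self.end_time}]")
        # right-open: at a breakpoint the NEW segment applies; at end_time the last
        idx = int(np.searchsorted(self.start_times, t, side="right")) - 1
        return self.concentrations[idx]

    def time_weighted_average(self, t0: float, t1: float) -> float:
        """Mean concentration over the window ``[t0, t1]``."""
        t0, t1 = float(t0), float(t1)
        if not (0.0 <= t0 < t1 <= self.end_time):
            raise DomainError(f"window [{t0}, {t1}] invalid for domain [0, {self.end_time}]")
        total = 0.0
        for a, b, c in self.segments():
            lo, hi = max(a, t0), min(b, t1)
            if hi > lo:
                total += c * (hi - lo)
        return total / (t1 - t0)


def concentration_at(profile: ExposureProfile, t: float) -> float:
    """Functional alias for :meth:`ExposureProfile.concentration_at`."""
    return profile.concentration_at(t)


def time_weighted_average(profile: ExposureProfile, t0: float, t1: float) -> float:
    """Functional alias for :meth:`ExposureProfile.time_weighted_average`."""
    return profile.time_weighted_average(t0, t1)
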