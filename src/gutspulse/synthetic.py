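"""Synthetic data emulating the study's experimental designs.

The generator reproduces the layout of the original experiments on
*Gammarus pulex* exposed to propiconazole, so every stage of the pipeline is
testable without the raw supplementary tables:

* pulsed toxicity, 10 d: two 1-d pulses at 28 nmol/mL separated by a 2-d
  (treatment A) or 6-d (treatment B) clean-water recovery period, plus a
  constant treatment at the corresponding time-weighted average
  concentration, 4.6 nmol/mL (treatment C); ten organisms per beaker, seven
  replicate beakers per treatment, daily observations;
* acute toxicity, 4 d: seven constant concentrations spanning
  8.2-37.4 nmol/mL, two replicate beakers each, daily observations;
* toxicokinetics: 1-d exposure at ~8.7 nmol/mL followed by 5 d (TK1) or
  1 d (TK2) of depuration, eight beakers.

Survival observations are drawn by sequential conditional-binomial thinning,
y_i ~ Binomial(y_{i-1}, S_i / S_{i-1}) — exactly the population-level
distribution implied by the multinomial interval likelihood with independent
individuals, for SD and IT alike.  Internal-concentration observations get
multiplicative log-normal noise with a chosen coefficient of variation
(default 0.15, the order of the analytical recovery spread of the assays
being emulated).  All randomness is funnelled through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DataError, DomainError
from .exposure import ExposureProfile
from .calibration import SurvivalDataset
from .survival import ModelVariant, TDParameters, survival
from .tk import TKObservations, TKParameters, simulate_internal

__all__ = [
    "StudyDesign",
    "make_study_profiles",
    "generate_tk_data",
    "generate_survival_data",
    "generate_control_data",
    "generate_study_survival",
]


def _geomspace7(lo: float, hi: float) -> tuple[float, ...]:
    return tuple(float(x) for x in np.geomspace(lo, hi, 7))


@dataclass(frozen=True)
class StudyDesign:
    """Scenario set and sampling layout of the emulated study."""

    pulse_concentration: float = 28.0  # nmol/mL, around the 1-d LC30
    pulse_duration: float = 1.0  # d
    short_gap: float = 2.0  # d recovery, treatment A
    long_gap: float = 6.0  # d recovery, treatment B
    pulsed_duration: float = 10.0  # d
    twa_concentration: float = 4.6  # nmol/mL, treatment C
    acute_concentrations: tuple[float, ...] = field(
        default_factory=lambda: _geomspace7(8.2, 37.4)
    )
    acute_duration: float = 4.0  # d
    organisms_per_beaker: int = 10
    pulsed_replicates: int = 7
    acute_replicates: int = 2
    control_beakers: int = 2  # non-solvent + solvent control
    tk_concentration: float = 8.7  # nmol/mL, below acute toxicity
    tk1_depuration: float = 5.0  # d
    tk2_depuration: float = 1.0  # d
    tk_replicates: int = 8

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.acute_concentrations):
            raise DomainError("concentrations must be non-negative")
        if min(self.pulse_concentration, self.twa_concentration, self.tk_concentration) < 0:
            raise DomainError("concentrations must be non-negative")

    def pulsed_observation_times(self) -> tuple[float, ...]:
        return tuple(float(t) for t in range(int(self.pulsed_duration) + 1))

    def acute_observation_times(self) -> tuple[float, ...]:
        return tuple(float(t) for t in range(int(self.acute_duration) + 1))


def make_study_profiles(design: StudyDesign = StudyDesign()) -> dict[str, ExposureProfile]:
    """Deterministic exposure profiles for every treatment of the study.

    Keys: ``'A'``, ``'B'``, ``'C'``, ``'acute_1'`` ... ``'acute_7'``,
    ``'TK1'``, ``'TK2'``.
    """
    d = design
    profiles: dict[str, ExposureProfile] = {}
    profiles["A"] = ExposureProfile.pulses(
        [0.0, d.pulse_duration + d.short_gap], d.pulse_duration,
        d.pulse_concentration, d.pulsed_duration,
    )
    profiles["B"] = ExposureProfile.pulses(
        [0.0, d.pulse_duration + d.long_gap], d.pulse_duration,
        d.pulse_concentration, d.pulsed_duration,
    )
    profiles["C"] = ExposureProfile.constant(d.twa_concentration, d.pulsed_duration)
    for i, c in enumerate(d.acute_concentrations, start=1):
        profiles[f"acute_{i}"] = ExposureProfile.constant(c, d.acute_duration)
    profiles["TK1"] = ExposureProfile.pulses(
        [0.0], d.pulse_duration, d.tk_concentration, d.pulse_duration + d.tk1_depuration
    )
    profiles["TK2"] = ExposureProfile.pulses(
        [0.0], d.pulse_duration, d.tk_concentration, d.pulse_duration + d.tk2_depuration
    )
    return profiles


def generate_tk_data(
    profile: ExposureProfile,
    params: TKParameters,
    cv: float = 0.15,
    n_times: int = 10,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> TKObservations:
    """Simulated internal concentrations with multiplicative log-normal noise.

    The noise has unit mean and coefficient of variation ``cv``; ``cv=0``
    returns the exact model values.  Sample times are spread evenly over the
    profile (skipping t=0, where organisms are uncontaminated).
    """
    if cv < 0:
        raise DomainError("cv must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    times = np.linspace(0.0, profile.end_time, n_times + 1)[1:]
    cint = simulate_internal(profile, params, times)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=cint.size)
        cint = cint * noise
    return TKObservations(tuple(times), tuple(cint), profile)


def _binomial_thinning(
    rng: np.random.Generator, n_initial: int, surv: np.ndarray
) -> list[int]:
    surv = np.maximum(surv, 1e-12)
    y = [int(n_initial)]
    for i in range(1, surv.size):
        ratio = min(1.0, surv[i] / surv[i - 1])
        y.append(int(rng.binomial(y[-1], ratio)))
    return y


def generate_survival_data(
    variant: ModelVariant,
    params: TDParameters,
    profile: ExposureProfile,
    n_initial: int,
    observation_times: Sequence[float],
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    treatment_id: str = "synthetic",
) -> SurvivalDataset:
    """Stochastic survivor counts under the model's own statistical structure.

    Counts are drawn sequentially as y_i ~ Binomial(y_{i-1}, S_i / S_{i-1}),
    so the generated data follow exactly the multinomial interval likelihood
    used for calibration.  Counts are non-increasing by construction and
    reproducible under a fixed seed.
    """
    if n_initial <= 0:
        raise DataError("n_initial must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    traj = survival(variant, params, profile, observation_times)
    counts = _binomial_thinning(rng, n_initial, traj.survival)
    return SurvivalDataset(treatment_id, profile, tuple(observation_times), tuple(counts))


def generate_control_data(
    h_b: float,
    n_initial: int,
    observation_times: Sequence[float],
    end_time: float | None = None,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    treatment_id: str = "control",
) -> SurvivalDataset:
    """Survivor counts of an unexposed control beaker, S_b(t) = exp(-h_b t)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    times = tuple(float(t) for t in observation_times)
    profile = ExposureProfile.constant(0.0, end_time if end_time is not None else times[-1])
    surv = np.exp(-h_b * np.asarray(times))
    counts = _binomial_thinning(rng, n_initial, surv)
    return SurvivalDataset(treatment_id, profile, times, tuple(counts))


def generate_study_survival(
    variant: ModelVariant,
    params: TDParameters,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    n_per_treatment: int | None = None,
) -> dict[str, list[SurvivalDataset]]:
    """The full study's survival data under one generating model.

    Returns groups ``'pulsed'`` (treatments A, B, C), ``'acute'`` (the
    seven-concentration series) and ``'controls'`` (unexposed beakers over
    the pulsed schedule, using the model's h_b).  ``n_per_treatment``
    overrides the per-treatment organism total (replicates x beaker size)
    to scale the study up or down; observations stay daily.
    """
    profiles = make_study_profiles(design)
    rng = np.random.default_rng(seed)
    t_pulsed = design.pulsed_observation_times()
    t_acute = design.acute_observation_times()
    n_pulsed = n_per_treatment or design.organisms_per_beaker * design.pulsed_replicates
    n_acute = n_per_treatment or design.organisms_per_beaker * design.acute_replicates
    out: dict[str, list[SurvivalDataset]] = {"pulsed": [], "acute": [], "controls": []}
    for name in ("A", "B", "C"):
        out["pulsed"].append(
            generate_survival_data(
                variant, params, profiles[name], n_pulsed, t_pulsed,
                rng=rng, treatment_id=name,
            )
        )
    for i in range(1, len(design.acute_concentrations) + 1):
        out["acute"].append(
            generate_survival_data(
                variant, params, profiles[f"acute_{i}"], n_acute, t_acute,
                rng=rng, treatment_id=f"acute_{i}",
            )
        )
    n_ctrl = n_per_treatment or design.organisms_per_beaker * design.control_beakers
    out["controls"].append(
        generate_control_data(params.h_b, n_ctrl, t_pulsed, rng=rng, treatment_id="control")
    )
    return out
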