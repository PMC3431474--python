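"""Shared fixtures: study-scale parameter sets and profiles.

Toxicodynamic values mirror the calibrated estimates for *Gammarus pulex*
and propiconazole that the synthetic study emulates.
"""

import numpy as np
import pytest

from gutspulse import (
    ExposureProfile,
    ITParameters,
    ModelVariant,
    SDParameters,
    TKParameters,
)

# pre-calibrated toxicokinetics (uptake mL/g/d, total loss 1/d)
TK = TKParameters(k_in=130.9, k_out=6.9)

# reduced-model estimates calibrated on both data sets
SD_REDUCED_BOTH = SDParameters(k_d=1.7, k_k=0.126, z=16.4)
IT_REDUCED_BOTH = ITParameters(k_d=0.8, alpha=18.7, beta=7.4)

# background hazard matching 90% control survival over 10 d
H_B = float(np.log(10 / 9) / 10)


@pytest.fixture
def tk_params():
    return TK


@pytest.fixture
def pulse_profile():
    """One 1-d pulse at 28 nmol/mL followed by clean water, 10 d."""
    return ExposureProfile.from_segments([(0, 1, 28.0), (1, 10, 0.0)])


@pytest.fixture
def two_pulse_profile():
    """Two 1-d pulses at 28 nmol/mL with a 2-d recovery gap, 10 d."""
    return ExposureProfile.pulses([0.0, 3.0], 1.0, 28.0, 10.0)


@pytest.fixture(params=["sd-full", "sd-reduced", "it-full", "it-reduced"])
def any_variant(request):
    name = request.param
    return ModelVariant.from_name(name, TK if name.endswith("full") else None)


def td_params_for(variant, scale_threshold=True):
    """Study-realistic TD parameters matched to a variant's dose-metric units."""
    scale = TK.k_in / TK.k_out if variant.tk_included == "full" else 1.0
    if variant.death_mechanism == "sd":
        return SDParameters(k_d=1.2, k_k=0.1 / scale, z=12.0 * scale, h_b=H_B)
    return ITParameters(k_d=1.2, alpha=15.0 * scale, beta=5.0, h_b=H_B)
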