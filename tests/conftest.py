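"""Shared fixtures: default models and the reference synthetic stack."""

from __future__ import annotations

import numpy as np
import pytest

from electroscatter.circuit import CircuitParams, Pulse, StimulusProtocol
from electroscatter.config import default_config, permittivity_model_from_config
from electroscatter.electro_optic import SigmoidTransfer
from electroscatter.synthetic import (
    ArrayLayout,
    NoiseModel,
    predict_figures_of_merit,
    render_sequence,
)


@pytest.fixture(scope="session")
def default_model():
    return permittivity_model_from_config(default_config())


@pytest.fixture(scope="session")
def stated_world():
    """The reference acquisition: 16x16 array, 200 fps, programmed SNR ~ 50.

    1-s pulses of 20-100 mV on a -0.35 V holding bias, shot + read noise
    plus slow speckle drift; peak counts chosen so the predicted SNR at
    100 mV is ~50 (the regime of the characterized devices).
    """
    amplitudes = (-0.02, -0.04, -0.06, -0.08, -0.1)
    pulses = tuple(Pulse(a, 1.2 + i * 1.4, 1.0) for i, a in enumerate(amplitudes))
    return {
        "circuit": CircuitParams(1e4, 9.9e5, 6e-9),  # tau ~ 6 ms
        "transfer": SigmoidTransfer(2e4, 6e5, -0.35, 0.12),
        "protocol": StimulusProtocol(
            -0.35, pulses, total_duration=1.2 + 1.4 * len(amplitudes), sampling_rate=200.0
        ),
        "noise": NoiseModel(speckle_drift_sd=0.2, speckle_corr=0.995),
        "layout": ArrayLayout(peak_counts=1200.0),
    }


@pytest.fixture(scope="session")
def programmed_figures(stated_world):
    return predict_figures_of_merit(
        stated_world["layout"],
        stated_world["circuit"],
        stated_world["transfer"],
        stated_world["noise"],
        stated_world["protocol"],
    )


@pytest.fixture(scope="session")
def rendered_stack(stated_world):
    seq, truth = render_sequence(
        stated_world["layout"],
        stated_world["circuit"],
        stated_world["transfer"],
        stated_world["noise"],
        stated_world["protocol"],
        seed=1,
    )
    return seq, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
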