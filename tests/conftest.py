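"""Shared fixtures: the expensive end-to-end runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from oscillobp import (
    ArteryModel,
    CuffModel,
    PressureWaveform,
    builtin_scenarios,
    diastolic_ratio_sweep,
    estimate_pressures,
    extract_envelope,
    run_validation,
    simulate_run,
)


@pytest.fixture(scope="session")
def normal_models():
    return ArteryModel(), CuffModel(), PressureWaveform()


@pytest.fixture(scope="session")
def normal_recording(normal_models):
    artery, cuff, waveform = normal_models
    return simulate_run(artery, cuff, waveform)


@pytest.fixture(scope="session")
def normal_envelope(normal_recording):
    return extract_envelope(normal_recording)


@pytest.fixture(scope="session")
def normal_estimate(normal_envelope, normal_models):
    _, cuff, _ = normal_models
    return estimate_pressures(normal_envelope, cuff)


@pytest.fixture(scope="session")
def validation_report():
    return run_validation(builtin_scenarios())


@pytest.fixture(scope="session")
def ratio_sweep():
    return diastolic_ratio_sweep()


@pytest.fixture
def rng():
    return np.random.default_rng(20120822)
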