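"""Shared fixtures: one stimulus per session and a cached PLV pipeline."""

from __future__ import annotations

import numpy as np
import pytest

import speechsync as ss


@pytest.fixture(scope="session")
def stimulus_spec() -> ss.StimulusSpec:
    """Default accelerating stimulus design: 4.3-4.7 Hz, 12 s plateaus, 60 s."""
    return ss.StimulusSpec()


@pytest.fixture(scope="session")
def stimulus_env(stimulus_spec) -> ss.EnvelopeSeries:
    return ss.generate_stimulus_envelope(stimulus_spec)


@pytest.fixture(scope="session")
def stimulus_banded(stimulus_env) -> ss.EnvelopeSeries:
    return ss.resample_and_band(stimulus_env)


@pytest.fixture(scope="session")
def plv_of(stimulus_spec, stimulus_env, stimulus_banded):
    """Factory: mean PLV of one simulated participant, memoized per spec."""
    cache: dict = {}

    def _plv(pspec: ss.SyntheticParticipantSpec) -> float:
        key = (pspec.mode, pspec.coupling_kappa, pspec.self_rate_hz,
               pspec.motor_jitter_sd_s, pspec.tempo_drift_hz, pspec.seed)
        if key not in cache:
            env = ss.simulate_production(stimulus_env, pspec, stim_spec=stimulus_spec)
            banded = ss.resample_and_band(env)
            cache[key] = ss.compute_plv(ss.phase_pair(stimulus_banded, banded)).plv_mean
        return cache[key]

    return _plv
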