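"""Shared fixtures: small synthetic recordings reused across test modules.

Recordings are generated at reduced duration and sampling rate so the suite
stays fast; the full-scale default configuration is exercised by the
acceptance tests.
"""

import pytest

from rhbreath import SubjectConfig, simulate_subject


@pytest.fixture(scope="session")
def small_config() -> SubjectConfig:
    """Two minutes at reduced rates, default noise."""
    return SubjectConfig(
        duration_s=120.0,
        rh_sample_rate_hz=500.0,
        flow_sample_rate_hz=250.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return simulate_subject(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SubjectConfig:
    """Deterministic waveform: no noise, drift, or per-cycle jitter."""
    return SubjectConfig(
        duration_s=120.0,
        rr_sd_bpm=0.0,
        noise_sd_rh_pct=0.0,
        drift_rh_pct_per_min=0.0,
        peak_jitter_rh_pct=0.0,
        flow_noise_sd_lps=0.0,
        rh_sample_rate_hz=500.0,
        flow_sample_rate_hz=250.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_config):
    return simulate_subject(noiseless_config)
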