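import numpy as np
import pandas as pd
import pytest

from medplast import (GridLayout, ProtocolSpec, WaveformParams, TBS_LTP,
                      get_preset, simulate_slice)


@pytest.fixture(scope="session")
def layout():
    return GridLayout()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free waveform parameters (no artifact) for exact-value tests."""
    return WaveformParams(noise_sd_uV=0.0, artifact_amp_uV=0.0)


@pytest.fixture(scope="session")
def tiny_protocol():
    """A short LTP protocol (2 min baseline + 3 min post) for fast I/O tests."""
    return ProtocolSpec(kind=TBS_LTP, baseline_min=2.0, post_min=3.0)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_protocol, layout):
    """Small noise-free observer TBS bundle (10 sweeps x 64 channels)."""
    params = WaveformParams(noise_sd_uV=0.0)
    return simulate_slice(get_preset("observer"), tiny_protocol, layout,
                          rng_state=11, params=params)


@pytest.fixture(scope="session")
def full_quiet_bundle(layout):
    """Full-length (150-sweep) noise-free naive TBS bundle, shared across tests."""
    params = WaveformParams(noise_sd_uV=0.0, amp_jitter_ln_sd=0.25)
    return simulate_slice(get_preset("naive"), ProtocolSpec(kind=TBS_LTP),
                          layout, rng_state=5, params=params)


def make_feature_table(channel_slopes: dict[int, list[float]],
                       channel_amps: dict[int, float] | None = None,
                       layer: str = "superficial",
                       baseline_min: float = 15.0,
                       sample_period: float = 0.5,
                       slice_id: str = "constructed") -> pd.DataFrame:
    """Constructed baseline-only feature table for QC unit tests.

    ``channel_slopes`` maps channel_id -> per-sweep baseline slope series;
    ``channel_amps`` maps channel_id -> constant baseline amplitude.
    """
    rows = []
    for ch, slopes in channel_slopes.items():
        amp = (channel_amps or {}).get(ch, 50.0)
        for i, s in enumerate(slopes):
            t = i * sample_period
            rows.append({
                "slice_id": slice_id, "condition": "constructed",
                "channel_id": ch, "layer": layer, "sweep_index": i,
                "time_min": t, "is_baseline": t < baseline_min,
                "amplitude_uV": amp, "slope_uV_per_ms": s,
            })
    return pd.DataFrame(rows)
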