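import numpy as np
import pytest

import pacpipe as pp


@pytest.fixture(scope="session")
def single_pair_bank():
    """1x1 filter bank for the well-separated (8, 64) Hz pair."""
    return pp.build_filterbank(lf_centers=[8.0], hf_centers=[64.0])


@pytest.fixture(scope="session")
def coupled_segments():
    """Segmented strongly coupled signal: 8 Hz phase, 64 Hz amplitude, 90 deg
    preference, pink noise, 60 s -> 30 segments."""
    params = pp.SimSignalParams(
        lf_hz=8.0, hf_hz=64.0, phase_pref_deg=90.0, coupling_depth=0.8,
        duration_s=60.0, noise_scale=1.0, seed=42,
    )
    return pp.segment_recording(pp.simulate_coupled_signal(params))


@pytest.fixture(scope="session")
def noiseless_coupled_segments():
    params = pp.SimSignalParams(
        lf_hz=8.0, hf_hz=64.0, phase_pref_deg=90.0, coupling_depth=1.0,
        duration_s=60.0, noise_scale=0.0,
    )
    return pp.segment_recording(pp.simulate_coupled_signal(params))


def make_white_recording(n_channels=3, duration_s=20.0, fs_hz=250.0, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs_hz)
    labels = ["F3", "F4", "P3", "P4", "Fz", "Pz"][:n_channels]
    return pp.Recording(
        data=scale * rng.standard_normal((n_channels, n)),
        fs_hz=fs_hz,
        ch_names=labels,
        subject_id=f"white-{seed}",
    )
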