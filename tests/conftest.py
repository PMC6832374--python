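import numpy as np
import pytest

import icmap


@pytest.fixture(scope="session")
def layout16():
    return icmap.make_layout(16, seed=11)


@pytest.fixture(scope="session")
def layout24():
    return icmap.make_layout(24, seed=3)


@pytest.fixture(scope="session")
def noiseless_recording(layout16):
    """Short three-source session with exact mixing (no sensor noise)."""
    bank = icmap.make_source_bank(
        layout16, ["gradient", "line_noise", "ecg"], seed=5)
    return icmap.simulate_recording(bank, layout16, duration_s=20.0, fs=250.0,
                                    sensor_noise_uv=0.0, seed=5)


@pytest.fixture(scope="session")
def small_sessions(layout24):
    """Six sessions with the full artifact bank, desk scale, for pipeline tests."""
    families = ["eog_vertical", "emg", "ecg", "gradient", "line_noise",
                "alpha", "pink_background"]
    return icmap.simulate_session_batch(
        6, layout24, families, seed=7, duration_s=60.0, fs=250.0,
        sensor_noise_uv=1.0)


@pytest.fixture(scope="session")
def small_decompositions(small_sessions):
    """Per-session ICA plus ground-truth family labels for each component."""
    decs, labels = [], []
    for i, (rec, gt) in enumerate(small_sessions):
        segs = icmap.select_segments(rec, n_sections=30, segment_len_s=2.0,
                                     seed=i)
        dec = icmap.run_ica(segs, n_components=7, seed=i)
        dec.session_id = f"s{i}"
        decs.append(dec)
        labels.extend(icmap.match_to_ground_truth(dec, gt.mixing, gt.labels))
    return decs, labels
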