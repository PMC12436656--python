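"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from fusiconn import preprocess as pp
from fusiconn import synthgen as sg


@pytest.fixture(scope="session")
def single_state_session():
    """ROI-only session with one baseline covariance state (full length)."""
    cfg = sg.SessionConfig(seed=11, motion_frame_rate=0.0, inject_amp=0.0)
    base = sg.base_correlation()
    truth = sg.GroundTruth(
        state_sequence=np.ones(cfg.n_frames, dtype=int),
        state_covariances=[base],
        transition_matrix=np.ones((1, 1)),
    )
    return sg.generate_session(cfg, truth, pixels=False, seed=12), base


@pytest.fixture(scope="session")
def small_pixel_session():
    """Short pixel session on a small grid for image-level operations."""
    cfg = sg.SessionConfig(
        n_rows=26, n_cols=26, t_start_min=-10, t_end_min=10,
        motion_frame_rate=0.0, seed=21,
    )
    base = sg.base_correlation()
    truth = sg.GroundTruth(
        state_sequence=np.ones(cfg.n_frames, dtype=int),
        state_covariances=[base],
        transition_matrix=np.ones((1, 1)),
    )
    return sg.generate_session(cfg, truth, pixels=True, seed=22)


@pytest.fixture(scope="session")
def filtered_roits(single_state_session):
    sess, _ = single_state_session
    r = sess.roits
    sig = pp.bandpass(r.signals, fs=r.fs)
    return pp.RoiTimeSeries(
        signals=sig, time_s=r.time_s, fs=r.fs, valid=r.valid, meta=r.meta
    )
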