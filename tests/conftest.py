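import numpy as np
import pytest

import emgait as eg


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 20-step continuous session with ground truth."""
    params = eg.GaitSimParams(n_steps=20, angle_noise_deg=0.0,
                              noise_sd=0.05, seed=1)
    ha, ka, truth = eg.simulate_kinematics(params)
    return params, ha, ka, truth


@pytest.fixture(scope="session")
def noisy_wo_session():
    """Realistic overground session: noise, jitter, standing interlude."""
    params = eg.GaitSimParams(n_steps=40, angle_noise_deg=0.5,
                              cycle_jitter_cv=0.02,
                              standing_interludes=((20, 10.0),), seed=3)
    ha, ka, truth = eg.simulate_kinematics(params)
    return params, ha, ka, truth


def truth_states(truth, rate, n):
    """Per-sample walking(1)/standing(0) track from generator intervals."""
    ts = np.zeros(n, dtype=np.int8)
    for (s, e, state) in truth.activity_intervals:
        if state == "walking":
            ts[int(round(s * rate)):int(round(e * rate))] = 1
    return ts


def max_nearest_error(detected, truth_times):
    """Worst-case distance from any true event to its nearest detection."""
    detected = np.asarray(detected)
    return max(float(np.min(np.abs(detected - t))) for t in truth_times)
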