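import numpy as np
import pytest

from rtgsd.synthetic_gait import GaitParams, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free 12-cycle trial at 4 km/h with mild cycle jitter."""
    params = GaitParams(speed_kmh=4.0, n_cycles=12, noise_scale=0.0,
                        cycle_jitter_sd=0.02, seed=11)
    trial, truth = generate_trial(params)
    return trial, truth, params


@pytest.fixture(scope="session")
def noisy_trial():
    """12-cycle trial at 4 km/h with the default noise levels."""
    params = GaitParams(speed_kmh=4.0, n_cycles=12, noise_scale=1.0,
                        cycle_jitter_sd=0.02, seed=13)
    trial, truth = generate_trial(params)
    return trial, truth, params


def truth_by(truth, leg, event_type):
    return sorted(e.time for e in truth
                  if e.leg == leg and e.event_type == event_type)


def cycle_windows(truth, leg):
    """(start, stop) time windows delimited by consecutive ipsilateral ICs."""
    ics = truth_by(truth, leg, "IC")
    return list(zip(ics, ics[1:]))


def offline_extremum(trial, leg, channel, t_lo, t_hi, kind):
    """Offline per-window argmin/argmax oracle on the raw channel."""
    rate = trial.sample_rate_kin
    i0, i1 = int(np.ceil(t_lo * rate)), int(np.floor(t_hi * rate))
    seg = trial.channels[leg][channel][i0:i1]
    pick = np.argmax if kind == "maximum" else np.argmin
    idx = i0 + int(pick(seg))
    return idx / rate, trial.channels[leg][channel][idx]
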