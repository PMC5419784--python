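"""Generator contracts: event counts, determinism, waveform anchoring."""

import numpy as np
import pytest

from rtgsd.gait_signals import CHANNEL_UNITS
from rtgsd.synthetic_gait import (
    DEFAULT_EVENT_PHASES,
    GaitParams,
    degrade,
    evaluate_channel,
    generate_trial,
)

from conftest import truth_by


def test_event_counts_and_cyclic_order():
    p = GaitParams(n_cycles=10, noise_scale=0.0, cycle_jitter_sd=0.0)
    trial, truth = generate_trial(p)
    for leg in ("left", "right"):
        for ev in ("IC", "FF", "HO", "TO", "MS"):
            assert len(truth_by(truth, leg, ev)) == 10
        # strictly increasing within type, and the merged stream walks the
        # IC->FF->HO->TO->MS cycle (the right leg starts mid-cycle)
        ics = truth_by(truth, leg, "IC")
        assert all(b > a for a, b in zip(ics, ics[1:]))
        succ = {"IC": "FF", "FF": "HO", "HO": "TO", "TO": "MS", "MS": "IC"}
        seq = [e.event_type for e in sorted(truth, key=lambda e: e.time)
               if e.leg == leg]
        for a, b in zip(seq, seq[1:]):
            assert b == succ[a], (leg, a, b)


def test_same_seed_bit_identical():
    a_trial, a_truth = generate_trial(GaitParams(seed=5, n_cycles=4))
    b_trial, b_truth = generate_trial(GaitParams(seed=5, n_cycles=4))
    for leg in a_trial.legs:
        for name in a_trial.channels[leg]:
            np.testing.assert_array_equal(a_trial.channels[leg][name],
                                          b_trial.channels[leg][name])
        np.testing.assert_array_equal(a_trial.grf[leg], b_trial.grf[leg])
    assert [(e.leg, e.event_type, e.time) for e in a_truth] == \
           [(e.leg, e.event_type, e.time) for e in b_truth]


def test_ground_truth_invariant_to_noise():
    quiet = generate_trial(GaitParams(seed=2, n_cycles=5, noise_scale=0.0))[1]
    loud = generate_trial(GaitParams(seed=2, n_cycles=5, noise_scale=2.0))[1]
    assert [(e.leg, e.event_type, e.time) for e in quiet] == \
           [(e.leg, e.event_type, e.time) for e in loud]


def test_jitter_preserves_within_cycle_ordering():
    p = GaitParams(seed=9, n_cycles=12, cycle_jitter_sd=0.05, noise_scale=0.0)
    _, truth = generate_trial(p)
    for leg in ("left", "right"):
        times = [e.time for e in sorted(truth, key=lambda e: e.time)
                 if e.leg == leg]
        assert all(b > a for a, b in zip(times, times[1:]))


@pytest.mark.parametrize("channel,event,kind", [
    ("shank_angle", "IC", "maximum"),
    ("shank_angular_velocity", "MS", "maximum"),
    ("shank_angular_velocity", "TO", "minimum"),
    ("ankle_angle", "FF", "minimum"),
    ("ankle_angle", "HO", "maximum"),
    ("foot_angular_acceleration", "FF", "minimum"),
    ("shank_vertical_position", "HO", "minimum"),
    ("calcaneus_vertical_velocity", "IC", "minimum"),
])
def test_extremum_phases_match_configuration(channel, event, kind):
    """Dense offline argmin/argmax of each noise-free waveform lands on the
    configured event phase to within one kinematic sample (~0.01 cycle)."""
    phi = np.linspace(0, 1, 20001, endpoint=False)
    y = evaluate_channel(channel, phi)
    pick = np.argmax if kind == "maximum" else np.argmin
    found = phi[int(pick(y))]
    target = DEFAULT_EVENT_PHASES[event]
    dist = min(abs(found - target), 1 - abs(found - target))
    assert dist < 0.01, f"{channel} {kind} at phase {found}, expected {target}"


@pytest.mark.parametrize("channel,threshold,direction,event", [
    ("calcaneus_vertical_velocity", 50.0, "up", "HO"),
    ("toe_vertical_velocity", -50.0, "up", "FF"),
    ("toe_vertical_velocity", 50.0, "up", "TO"),
])
def test_crossing_phases_match_configuration(channel, threshold, direction, event):
    phi = np.linspace(0, 1, 20001, endpoint=False)
    y = evaluate_channel(channel, phi)
    up = np.flatnonzero((y[:-1] < threshold) & (y[1:] >= threshold))
    target = DEFAULT_EVENT_PHASES[event]
    dists = np.abs(phi[up] - target)
    assert dists.min() < 0.005


def test_grf_exceeds_20N_exactly_on_stance():
    phi = np.linspace(0, 1, 20001, endpoint=False)
    from rtgsd.synthetic_gait import _grf_waveform
    g = _grf_waveform(phi, 1.1, DEFAULT_EVENT_PHASES["TO"], 750.0)
    stance = phi <= DEFAULT_EVENT_PHASES["TO"]
    inner = stance & (phi > 0.001) & (phi < DEFAULT_EVENT_PHASES["TO"] - 0.001)
    assert np.all(g[inner] > 20.0)
    assert np.all(g[~stance] <= 20.0)
    assert np.all(g >= 0.0)


def test_param_validation():
    with pytest.raises(ValueError):
        GaitParams(event_phases={"IC": 0.0, "FF": 0.5, "HO": 0.4,
                                 "TO": 0.62, "MS": 0.8}).validate()
    with pytest.raises(ValueError):
        GaitParams(event_phases={"IC": 0.1, "FF": 0.2, "HO": 0.4,
                                 "TO": 0.62, "MS": 0.8}).validate()
    with pytest.raises(ValueError):
        GaitParams(cycle_jitter_sd=0.5).validate()
    with pytest.raises(ValueError):
        GaitParams(n_cycles=0).validate()


def test_speed_period_mapping():
    assert GaitParams(speed_kmh=3.0).period == pytest.approx(1.2)
    assert GaitParams(speed_kmh=4.0).period == pytest.approx(1.1)
    assert GaitParams(speed_kmh=5.0).period == pytest.approx(1.0)
    assert GaitParams(speed_kmh=3.5).period == pytest.approx(1.15)
    assert GaitParams(cycle_period_s=0.9).period == 0.9


def test_amplitude_step_scales_later_cycles():
    p = GaitParams(seed=1, n_cycles=6, noise_scale=0.0, cycle_jitter_sd=0.0,
                   amplitude_step_cycle=3, amplitude_step_factor=1.5)
    trial, truth = generate_trial(p)
    v = trial.channels["left"]["shank_angular_velocity"]
    rate = trial.sample_rate_kin
    ms = truth_by(truth, "left", "MS")
    early = v[int(ms[0] * rate) - 2:int(ms[0] * rate) + 3].max()
    late = v[int(ms[5] * rate) - 2:int(ms[5] * rate) + 3].max()
    assert late == pytest.approx(20 + (early - 20) * 1.5, rel=0.02)


def test_degrade_add_noise_zero_is_identity(clean_trial):
    trial, _, _ = clean_trial
    same = degrade(trial, "add_noise", sd=0.0)
    for leg in trial.legs:
        for name in CHANNEL_UNITS:
            np.testing.assert_array_equal(same.channels[leg][name],
                                          trial.channels[leg][name])


def test_degrade_does_not_mutate_original(clean_trial):
    trial, _, _ = clean_trial
    before = trial.channels["left"]["ankle_angle"].copy()
    degrade(trial, "drop_channel", channel="ankle_angle")
    degrade(trial, "add_noise", sd=5.0, channel="ankle_angle")
    np.testing.assert_array_equal(trial.channels["left"]["ankle_angle"], before)


def test_degrade_unknown_kind_rejected(clean_trial):
    trial, _, _ = clean_trial
    with pytest.raises(ValueError, match="unknown degradation"):
        degrade(trial, "melt")


def test_saturated_grf_never_crosses_reference_threshold(clean_trial):
    from rtgsd.reference_events import ReferenceConfig, detect_grf_events

    trial, _, _ = clean_trial
    capped = degrade(trial, "saturate", channel="grf_vertical", ceiling=15.0)
    events = detect_grf_events(capped.grf["left"], ReferenceConfig(),
                               sample_rate=capped.sample_rate_grf)
    assert events == []
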