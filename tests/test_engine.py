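"""Streaming engine: threshold formula, low-pass filter, extremum firing,
secondary toe-off, update-layer adaptation, causality and soundness."""

import dataclasses
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtgsd.engine import (
    EngineConfig,
    LegDetector,
    OnlineLowPass,
    ThresholdPolicy,
    run,
    run_detailed,
    update_threshold,
)
from rtgsd.evaluation import MatchConfig, evaluate_events
from rtgsd.synthetic_gait import GaitParams, generate_trial
from rtgsd.variants import get_variant, spec_b6, spec_min

from conftest import cycle_windows, offline_extremum, truth_by

CYCLE_SUCCESSOR = {"MS": "IC", "IC": "FF", "FF": "HO", "HO": "TO", "TO": "MS"}


def _force_unreachable_to(spec):
    """Clone a variant with its primary TO definition made unfirable."""
    rules = []
    for r in spec.rules:
        if r.key == "TO":
            bad = 1e9 if "crossing" in r.kind else -1e9
            r = dataclasses.replace(r, threshold_mode="fixed", fixed_value=bad)
        rules.append(r)
    return dataclasses.replace(spec, rules=rules)


# -- update_threshold ------------------------------------------------------

def test_threshold_zero_variance_identity():
    policy = ThresholdPolicy(offset=0.0)
    assert update_threshold([50, 50, 50, 50, 50], policy, "maximum") == 50.0


def test_threshold_single_element_uses_offset_only():
    policy = ThresholdPolicy(offset=5.0)
    assert update_threshold([40.0], policy, "minimum") == pytest.approx(45.0)


def test_threshold_example_history():
    hist = [50, 52, 48, 51, 49]
    policy = ThresholdPolicy(offset=2.0)
    expected = statistics.mean(hist) - 3 * statistics.stdev(hist) - 2.0
    assert update_threshold(hist, policy, "maximum") == pytest.approx(expected, rel=1e-12)


def test_threshold_empty_history_rejected():
    with pytest.raises(ValueError):
        update_threshold([], ThresholdPolicy(), "maximum")


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(-500, 500), min_size=1, max_size=5),
       st.floats(0, 50), st.floats(0, 5),
       st.sampled_from(["maximum", "minimum"]))
def test_threshold_matches_arithmetic_oracle(hist, offset, mult, direction):
    """The adaptive rule equals an independent mean/sample-SD recomputation."""
    policy = ThresholdPolicy(offset=offset, sd_multiplier=mult)
    sd = statistics.stdev(hist) if len(hist) > 1 else 0.0
    margin = mult * sd + offset
    expected = statistics.mean(hist) + (-margin if direction == "maximum" else margin)
    got = update_threshold(hist, policy, direction)
    assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


# -- low-pass filter -------------------------------------------------------

def test_lowpass_dc_gain_is_one():
    f = OnlineLowPass(6.0, 2, 100.0)
    out = [f.step(3.7) for _ in range(50)]
    assert out[-1] == pytest.approx(3.7, rel=1e-9)


def test_lowpass_passband_gain_at_cycle_rate():
    f = OnlineLowPass(6.0, 2, 100.0)
    t = np.arange(1000) / 100.0
    x = np.sin(2 * np.pi * 0.8 * t)
    y = np.array([f.step(v) for v in x])
    ratio = np.abs(y[400:]).max() / np.abs(x[400:]).max()
    assert ratio >= 0.95


def test_lowpass_shrinks_white_noise_variance():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 2000)
    f = OnlineLowPass(6.0, 2, 100.0)
    y = np.array([f.step(v) for v in x])
    assert y[100:].var() < x.var()


# -- streaming extremum detection -----------------------------------------

def test_streaming_max_fires_one_tick_after_peak():
    """Shank angle ramps 10->30 above the 25-deg threshold then drops: IC is
    stamped at the 30-deg sample and fired one tick later (k=1)."""
    spec = spec_min(generic_thresholds={"IC": 25.0})
    det = LegDetector(spec, "left", 100.0)
    det.machine_state = "MS"   # awaiting IC
    base = {ch: 0.0 for ch in spec.required_channels}
    fired = []
    levels = [10, 15, 20, 26, 28, 30, 27, 24]
    for i, lv in enumerate(levels):
        fired += [(i, e) for e in det.step({**base, "shank_angle": float(lv)})]
    assert len(fired) == 1
    tick, ev = fired[0]
    assert ev.event_type == "IC"
    assert tick == 6                   # one reversal tick after the peak
    assert ev.sample_index == 5        # stamped at the 30-deg sample
    assert ev.amplitude == pytest.approx(30.0)


def test_no_crossing_means_no_event_forever():
    spec = spec_min()
    det = LegDetector(spec, "left", 100.0)
    det.machine_state = "MS"
    base = {ch: 0.0 for ch in spec.required_channels}
    for _ in range(500):
        assert det.step(dict(base)) == []
    assert det.machine_state == "MS"


@pytest.mark.parametrize("name", ["rtgsd_min", "rtgsd_b6", "rtgsd_g6"])
def test_extremum_events_match_offline_oracle(clean_trial, name):
    """On noise-free data every extremum-type event time equals the offline
    per-cycle argmin/argmax of its channel within k+1 samples."""
    trial, truth, params = clean_trial
    spec = get_variant(name)
    events = run(trial, spec)
    tol = 2.0 / trial.sample_rate_kin + 1e-9
    checked = 0
    for leg in ("left", "right"):
        for t_lo, t_hi in cycle_windows(truth, leg)[1:-1]:
            for rule in spec.rules:
                if rule.is_flag or rule.kind not in ("maximum", "minimum"):
                    continue
                # search the cycle window shifted to centre this event type
                cand = [e for e in events
                        if e.leg == leg and e.event_type == rule.key
                        and t_lo - 0.3 <= e.time <= t_hi + 0.3]
                t_true = [t for t in truth_by(truth, leg, rule.key)
                          if t_lo - 0.25 <= t <= t_hi + 0.25]
                if not cand or not t_true:
                    continue
                t_ev = min(cand, key=lambda e: abs(e.time - t_true[0])).time
                t_oracle, _ = offline_extremum(
                    trial, leg, rule.channel,
                    t_true[0] - 0.2, t_true[0] + 0.2, rule.kind)
                assert abs(t_ev - t_oracle) <= tol, (name, leg, rule.key)
                checked += 1
    assert checked >= 30


# -- secondary toe-off -----------------------------------------------------

@pytest.mark.parametrize("factory", [spec_min, spec_b6])
def test_unreachable_primary_to_falls_back_to_zero_cross(clean_trial, factory):
    trial, truth, _ = clean_trial
    spec = _force_unreachable_to(factory())
    events = run(trial, spec)
    tos = [e for e in events if e.event_type == "TO"]
    assert tos and all(e.secondary for e in tos)
    # stamped exactly at the raw zero-cross sample
    rate = trial.sample_rate_kin
    for e in tos:
        v = trial.channels[e.leg]["shank_angular_velocity"]
        i = e.sample_index
        assert v[i] >= 0.0 > v[i - 1], (e.leg, e.time)


def test_secondary_never_fires_when_primary_reachable(clean_trial):
    trial, _, _ = clean_trial
    for factory in (spec_min, spec_b6):
        events = run(trial, factory())
        assert not any(e.secondary for e in events)


# -- update layer ----------------------------------------------------------

def test_thresholds_converge_to_amplitudes_without_offset():
    """Identical cycles with zero offset: thresholds converge exactly to the
    event amplitudes (zero-variance fixed point)."""
    p = GaitParams(n_cycles=10, noise_scale=0.0, cycle_jitter_sd=0.0, seed=0)
    trial, truth = generate_trial(p)
    spec = spec_min(offsets={"IC": 0.0, "TO": 0.0, "MS": 0.0})
    _, dets = run_detailed(trial, spec)
    det = dets["left"]
    for key, kind in (("IC", "maximum"), ("TO", "minimum"), ("MS", "maximum")):
        hist = det.history[key]
        assert len(hist) == 5
        assert np.std(hist) < 1e-9          # identical cycles
        assert det.thresholds[key][0] == pytest.approx(hist[-1], abs=1e-9)
        # and the amplitude is the offline per-cycle extremum
        t_lo, t_hi = cycle_windows(truth, "left")[-2]
        _, amp = offline_extremum(trial, "left", spec.rule(key).channel,
                                  t_lo, t_hi, kind)
        assert hist[-1] == pytest.approx(amp, abs=1e-9)


def test_amplitude_step_reconverges_within_history_length():
    """x1.5 amplitude step at cycle 8: thresholds reach the new regime
    within 5 cycles and no false positives occur during the transition."""
    p = GaitParams(n_cycles=16, noise_scale=1.0, cycle_jitter_sd=0.02,
                   seed=21, amplitude_step_cycle=8, amplitude_step_factor=1.5)
    trial, truth = generate_trial(p)
    events, dets = run_detailed(trial, spec_min())
    _, fps, _ = evaluate_events(events, truth, MatchConfig())
    assert fps == []
    log = [r for r in dets["left"].threshold_log if r["event"] == "MS"]
    pre = [r["raw_threshold"] for r in log if r["cycle"] <= 8]
    post = [r["raw_threshold"] for r in log if r["cycle"] >= 14]
    new_amp = 20 + 380 * 1.5   # stepped mid-swing peak
    assert max(pre) < 400      # old regime: threshold below the old peak
    assert min(post) > 400     # new regime: threshold above the old peak
    assert min(post) > new_amp - 150


def test_update_layer_logs_every_update():
    p = GaitParams(n_cycles=6, noise_scale=0.0, seed=4)
    trial, _ = generate_trial(p)
    _, dets = run_detailed(trial, spec_b6())
    log = dets["left"].threshold_log
    assert {r["event"] for r in log} == {"IC", "FF", "MS", "TO_flag"}


# -- whole-run properties --------------------------------------------------

def test_rerun_is_bit_identical(noisy_trial):
    trial, _, _ = noisy_trial
    a = run(trial, get_variant("rtgsd_b6"))
    b = run(trial, get_variant("rtgsd_b6"))
    assert [(e.leg, e.event_type, e.sample_index, e.amplitude) for e in a] == \
           [(e.leg, e.event_type, e.sample_index, e.amplitude) for e in b]


def test_single_leg_trial(noisy_trial):
    trial, _, _ = noisy_trial
    solo = trial.copy()
    del solo.channels["right"]
    del solo.grf["right"]
    events = run(solo, get_variant("rtgsd_min"))
    assert events and all(e.leg == "left" for e in events)


def test_leg_swap_symmetry(noisy_trial):
    trial, _, _ = noisy_trial
    swapped = trial.copy()
    swapped.channels["left"], swapped.channels["right"] = \
        swapped.channels["right"], swapped.channels["left"]
    a = run(trial, get_variant("rtgsd_g6"))
    b = run(swapped, get_variant("rtgsd_g6"))
    flip = {"left": "right", "right": "left"}
    assert sorted((flip[e.leg], e.event_type, e.sample_index) for e in a) == \
           sorted((e.leg, e.event_type, e.sample_index) for e in b)


def test_causality_under_truncation(noisy_trial):
    """Cutting the input after tick t never changes events fired at <= t."""
    trial, _, _ = noisy_trial
    spec = get_variant("rtgsd_b6")
    full = run(trial, spec)
    for cut_s in (3.0, 6.5, 9.25):
        short = trial.copy()
        n = int(cut_s * trial.sample_rate_kin)
        for leg in short.legs:
            for name in short.channels[leg]:
                short.channels[leg][name] = short.channels[leg][name][:n]
            short.grf[leg] = short.grf[leg][:int(cut_s * trial.sample_rate_grf)]
        part = run(short, spec)
        want = [(e.leg, e.event_type, e.sample_index) for e in full
                if e.sample_index < n]
        got = [(e.leg, e.event_type, e.sample_index) for e in part]
        assert got == want


def assert_machine_sound(events, leg):
    seq = [e.event_type for e in sorted(events, key=lambda e: e.time)
           if e.leg == leg]
    for a, b in zip(seq, seq[1:]):
        assert b == CYCLE_SUCCESSOR[a], f"{a}->{b} violates the cycle"


@pytest.mark.parametrize("name", ["rtgsd_min", "rtgsd_b6", "rtgsd_g6"])
def test_state_machine_soundness_random_conditions(name):
    """Random noise/amplitude trials: the fired sequence per leg is always a
    contiguous walk of the MS->IC->FF->HO->TO cycle."""
    rng = np.random.default_rng(77)
    for _ in range(12):
        p = GaitParams(
            speed_kmh=float(rng.choice([3.0, 4.0, 5.0])),
            n_cycles=4,
            noise_scale=float(rng.uniform(0, 1.5)),
            cycle_jitter_sd=float(rng.uniform(0, 0.04)),
            seed=int(rng.integers(0, 2**31)),
            amplitude_step_cycle=0,
            amplitude_step_factor=float(rng.uniform(0.8, 1.3)),
        )
        trial, _ = generate_trial(p)
        events = run(trial, get_variant(name))
        for leg in ("left", "right"):
            assert_machine_sound(events, leg)


def test_frozen_thresholds_keep_soundness(noisy_trial):
    """Deleting the update layer (generic thresholds frozen) changes timing
    but never breaks the state machine."""
    trial, _, _ = noisy_trial
    cfg = EngineConfig(update_rate_divisor=10**9)
    events, dets = run_detailed(trial, spec_min(), cfg)
    assert all(not d.threshold_log for d in dets.values())
    assert events
    for leg in ("left", "right"):
        assert_machine_sound(events, leg)


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(lpf_cutoff=80.0).validate(100.0)
    with pytest.raises(ValueError):
        EngineConfig(reversal_samples=0).validate(100.0)
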