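"""Variant-agnostic double-layered real-time detection engine.

Two layers run in parallel for each leg:

* **Real-time detection layer** -- a five-state machine (MS->IC->FF->HO->TO
  ->MS) plus pre-event *flags*.  An extremum-type event fires at the first
  tick where (a) the machine is in the rule's guard state, (b) the guard
  flag, if any, is raised, (c) the channel has crossed the current raw
  threshold in the event direction, and (d) the signal has reversed for
  ``reversal_samples`` consecutive ticks; the event is stamped at the
  pre-reversal extremum sample.  Crossing-type events fire at the crossing
  tick.  Firing advances the machine and lowers the consumed flag.

* **Update layer** -- once per completed cycle (anchored on MS, deferred a
  little so the causal low-pass filter has caught up) it locates each
  adaptive event in the low-pass-filtered signal near where the real-time
  layer fired, backtracks to the true extremum in the raw signal within a
  short window, pushes that amplitude into a 5-deep history, and recomputes
  the raw and filtered thresholds as ``mean -/+ 3*SD -/+ offset`` (below
  expected peaks for maxima, above expected troughs for minima).  The update
  layer never retroactively edits fired events.

A secondary toe-off definition guards against an unreachable primary TO
threshold: while the machine waits in HO, a negative-to-positive zero
crossing of the shank angular velocity fires TO (marked ``secondary``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .gait_signals import EventSequenceError, GaitEvent, KinematicTrial, ChannelError

logger = logging.getLogger(__name__)

__all__ = [
    "EventRule", "ThresholdPolicy", "EngineConfig", "OnlineLowPass",
    "update_threshold", "LegDetector", "run", "run_detailed",
]

MACHINE_CYCLE = ("MS", "IC", "FF", "HO", "TO")

EXTREMUM_KINDS = ("maximum", "minimum")
CROSSING_KINDS = ("upward_crossing", "downward_crossing", "zero_cross_to_negative")


@dataclass(frozen=True)
class EventRule:
    """One declarative detection rule (event or pre-event flag)."""

    event_type: str            # IC/FF/HO/TO/MS, or the flag's name
    channel: str
    kind: str                  # extremum or crossing kind
    guard_state: str           # machine state in which the rule is armed
    guard_flag: str | None = None
    threshold_mode: str = "fixed"   # 'adaptive' | 'fixed' | 'derived'
    fixed_value: float | None = None
    is_flag: bool = False

    @property
    def key(self) -> str:
        return self.event_type

    @property
    def direction(self) -> str:
        """Extremum direction governing arming and threshold polarity."""
        if self.kind in ("minimum", "zero_cross_to_negative", "downward_crossing"):
            return "minimum"
        return "maximum"

    def validate(self) -> None:
        if self.kind not in EXTREMUM_KINDS + CROSSING_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.threshold_mode not in ("adaptive", "fixed", "derived"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")


@dataclass
class ThresholdPolicy:
    """Adaptive threshold rule: history mean corrected by ``sd_multiplier``
    sample standard deviations and an ``offset``, on the permissive side
    (below peaks for maxima, above troughs for minima)."""

    history_length: int = 5
    sd_multiplier: float = 3.0
    offset: float = 0.0
    direction: str = "maximum"

    def validate(self) -> None:
        if self.history_length < 1:
            raise ValueError("history_length must be >= 1")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


def update_threshold(history, policy: ThresholdPolicy,
                     direction: str | None = None) -> float:
    """Threshold from the last <=5 event amplitudes.

    ``mean - m*SD - offset`` for maximum-type events, ``mean + m*SD +
    offset`` for minimum-type; SD is the sample standard deviation (0 for a
    single element).  Raises ``ValueError`` on an empty history (callers
    keep the generic threshold instead).
    """
    arr = np.asarray(list(history), float)
    if arr.size == 0:
        raise ValueError("empty amplitude history")
    direction = direction or policy.direction
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    margin = policy.sd_multiplier * sd + policy.offset
    return mean - margin if direction == "maximum" else mean + margin


@dataclass
class EngineConfig:
    lpf_cutoff: float = 6.0        # Hz
    lpf_order: int = 2             # causal recursive (Butterworth)
    reversal_samples: int = 1      # k consecutive reversal ticks to confirm
    backtrack_window_ms: float = 50.0   # raw search around the LPF extremum
    search_window_ms: float = 150.0     # LPF search around the fired event
    update_defer_ms: float = 150.0      # update-layer latency after MS
    update_rate_divisor: int = 1        # run the update every n-th cycle
    #: the fallback TO zero-cross only counts after the shank angular
    #: velocity has been negative this long (rejects noise chatter around 0)
    secondary_to_min_negative_ms: float = 30.0
    buffer_s: float = 4.0
    sd_multiplier: float = 3.0
    history_length: int = 5
    #: offset = this fraction of |generic threshold| unless overridden
    offset_fraction: float = 0.05

    def validate(self, sample_rate: float) -> None:
        if not 0 < self.lpf_cutoff < sample_rate / 2:
            raise ValueError("lpf_cutoff must lie in (0, Nyquist)")
        if self.reversal_samples < 1:
            raise ValueError("reversal_samples must be >= 1")
        if self.update_rate_divisor < 1:
            raise ValueError("update_rate_divisor must be >= 1")


class OnlineLowPass:
    """Causal recursive (Butterworth) low-pass, one sample at a time.

    DC gain is 1; the phase lag at the cutoff is the usual -order*45 deg.
    State is initialised at the first sample's steady state so constant
    inputs pass through unchanged from tick 0.
    """

    def __init__(self, cutoff: float, order: int, sample_rate: float):
        self.b, self.a = sps.butter(order, cutoff, fs=sample_rate)
        self._zi_template = sps.lfilter_zi(self.b, self.a)
        self.z: np.ndarray | None = None

    def step(self, x: float) -> float:
        if self.z is None:
            self.z = self._zi_template * x
        y, self.z = sps.lfilter(self.b, self.a, [x], zi=self.z)
        return float(y[0])


class _Ring:
    """Fixed-size ring buffer addressed by absolute sample index."""

    __slots__ = ("data", "n")

    def __init__(self, size: int):
        self.data = np.full(size, np.nan)
        self.n = size

    def append(self, i: int, v: float) -> None:
        self.data[i % self.n] = v

    def window(self, lo: int, hi: int, now: int) -> tuple[np.ndarray, int]:
        """Values for absolute indices [lo, hi] (inclusive), clipped to what
        the buffer still holds; returns (values, abs index of first value)."""
        lo = max(lo, now - self.n + 1, 0)
        hi = min(hi, now)
        idx = np.arange(lo, hi + 1)
        return self.data[idx % self.n], lo


class _Tracker:
    __slots__ = ("armed", "best", "best_idx", "count")

    def __init__(self):
        self.reset()

    def reset(self):
        self.armed = False
        self.best = math.nan
        self.best_idx = -1
        self.count = 0


class LegDetector:
    """Streaming detector for one leg.

    Feed samples (dicts of channel values at the kinematic rate) through
    :meth:`step`; fired events come back as they are confirmed, stamped at
    the extremum/crossing sample.  ``variant`` is a
    :class:`~rtgsd.variants.VariantSpec`.
    """

    def __init__(self, variant, leg: str, sample_rate: float = 100.0,
                 cfg: EngineConfig | None = None, speed_kmh: float | None = None):
        self.variant = variant
        self.leg = leg
        self.rate = float(sample_rate)
        self.cfg = cfg or EngineConfig()
        self.cfg.validate(self.rate)
        self.speed_kmh = speed_kmh

        self.machine_state = "TO"   # awaiting MS, the cycle anchor
        self.flags: dict[str, bool] = {
            r.event_type: False for r in variant.rules if r.is_flag}
        self.i = -1                 # absolute sample index of current tick
        self.cycle_count = 0

        nbuf = int(self.cfg.buffer_s * self.rate)
        self._raw = {ch: _Ring(nbuf) for ch in variant.required_channels}
        self._lpf_buf = {ch: _Ring(nbuf) for ch in variant.required_channels}
        self._filters = {ch: OnlineLowPass(self.cfg.lpf_cutoff, self.cfg.lpf_order,
                                           self.rate)
                         for ch in variant.required_channels}
        self._prev: dict[str, float] = {}

        self._trackers: dict[str, _Tracker] = {r.key: _Tracker()
                                               for r in variant.rules}
        self.thresholds: dict[str, tuple[float, float]] = {}
        self.history: dict[str, list[float]] = {}
        self._lpf_history: dict[str, list[float]] = {}
        self._policies: dict[str, ThresholdPolicy] = {}
        for rule in variant.rules:
            if rule.threshold_mode == "adaptive":
                g = variant.generic_thresholds[rule.key]
                self.thresholds[rule.key] = (g, g)
                self.history[rule.key] = []
                self._lpf_history[rule.key] = []
                offset = variant.offsets.get(
                    rule.key, self.cfg.offset_fraction * abs(g))
                self._policies[rule.key] = ThresholdPolicy(
                    history_length=self.cfg.history_length,
                    sd_multiplier=self.cfg.sd_multiplier,
                    offset=offset, direction=rule.direction)
        self.derived_to_threshold: float | None = None
        self._last_fired: dict[str, tuple[int, float]] = {}
        self._last_updated: dict[str, int] = {}
        self._update_due: int | None = None
        self.threshold_log: list[dict] = []
        self.errors: list[EventSequenceError] = []
        self._secondary_prev: float | None = None
        self._secondary_neg_count = 0

    # -- threshold plumbing -------------------------------------------------

    def _current_threshold(self, rule: EventRule) -> float | None:
        if rule.threshold_mode == "fixed":
            if rule.fixed_value is not None:
                return rule.fixed_value
            return self.variant.generic_thresholds.get(rule.key)
        if rule.threshold_mode == "adaptive":
            return self.thresholds[rule.key][0]
        if rule.threshold_mode == "derived":
            return self.derived_to_threshold  # None until the flag sets it
        raise AssertionError(rule.threshold_mode)

    # -- per-tick processing ------------------------------------------------

    def _rule_active(self, rule: EventRule) -> bool:
        if self.machine_state != rule.guard_state:
            return False
        if rule.guard_flag is not None and not self.flags[rule.guard_flag]:
            return False
        return True

    def step(self, sample: dict[str, float]) -> list[GaitEvent]:
        """Process one kinematic tick; return events fired at this tick."""
        self.i += 1
        i = self.i
        for ch in self.variant.required_channels:
            v = float(sample[ch])
            self._raw[ch].append(i, v)
            self._lpf_buf[ch].append(i, self._filters[ch].step(v))

        fired: list[GaitEvent] = []
        advanced = False
        # flags first: a flag raised this tick gates its event from the next
        for rule in self.variant.rules:
            if not self._rule_active(rule):
                continue
            if advanced and not rule.is_flag:
                continue   # at most one machine-advancing event per tick
            hit = self._evaluate(rule, sample)
            if hit is None:
                continue
            idx, amp = hit
            if rule.is_flag:
                self._fire_flag(rule, idx, amp)
            else:
                fired.append(self._fire_event(rule, idx, amp))
                advanced = True

        if not advanced and self.variant.use_secondary_to \
                and self.machine_state == "HO":
            ev = self._check_secondary_to(sample)
            if ev is not None:
                fired.append(ev)
        if self.machine_state != "HO":
            self._secondary_prev = None
            self._secondary_neg_count = 0

        for ch in self.variant.required_channels:
            self._prev[ch] = float(sample[ch])

        if self._update_due is not None and i >= self._update_due:
            self._update_due = None
            self.update_layer_pass()
        return fired

    def _evaluate(self, rule: EventRule, sample) -> tuple[int, float] | None:
        v = float(sample[rule.channel])
        prev = self._prev.get(rule.channel)
        thr = self._current_threshold(rule)
        tr = self._trackers[rule.key]
        k = self.cfg.reversal_samples
        if rule.kind == "maximum":
            if thr is None:
                return None
            if not tr.armed:
                if v >= thr:
                    tr.armed, tr.best, tr.best_idx, tr.count = True, v, self.i, 0
                return None
            if v > tr.best:
                tr.best, tr.best_idx, tr.count = v, self.i, 0
                return None
            tr.count += 1
            if tr.count >= k:
                return tr.best_idx, tr.best
            return None
        if rule.kind == "minimum":
            if thr is None:
                return None
            if not tr.armed:
                if v <= thr:
                    tr.armed, tr.best, tr.best_idx, tr.count = True, v, self.i, 0
                return None
            if v < tr.best:
                tr.best, tr.best_idx, tr.count = v, self.i, 0
                return None
            tr.count += 1
            if tr.count >= k:
                return tr.best_idx, tr.best
            return None
        if prev is None:
            return None
        if rule.kind == "upward_crossing":
            if thr is not None and prev < thr <= v:
                return self.i, v
        elif rule.kind == "downward_crossing":
            if thr is not None and prev > thr >= v:
                return self.i, v
        elif rule.kind == "zero_cross_to_negative":
            if prev >= 0.0 > v:
                return self.i, v
        return None

    def _fire_flag(self, rule: EventRule, idx: int, amp: float) -> None:
        self.flags[rule.event_type] = True
        self._last_fired[rule.event_type] = (idx, amp)
        self._trackers[rule.event_type].reset()
        if rule.event_type == self.variant.to_flag_name:
            a = self.variant.to_coefficient(self.speed_kmh)
            self.derived_to_threshold = amp * a
        logger.debug("%s: flag %s raised at i=%d amp=%.3f",
                     self.leg, rule.event_type, idx, amp)

    def _fire_event(self, rule: EventRule, idx: int, amp: float,
                    secondary: bool = False) -> GaitEvent:
        ev = GaitEvent(rule.event_type, self.leg, idx / self.rate, idx,
                       amplitude=amp, source=self.variant.source_name,
                       secondary=secondary)
        self.machine_state = rule.event_type
        if rule.guard_flag is not None:
            self.flags[rule.guard_flag] = False
        self._last_fired[rule.event_type] = (idx, amp)
        # re-arm every rule that just became active in the new state
        for r in self.variant.rules:
            if r.guard_state == self.machine_state:
                self._trackers[r.key].reset()
        if rule.event_type == "MS":
            self.cycle_count += 1
            if self.cycle_count % self.cfg.update_rate_divisor == 0:
                defer = int(round(self.cfg.update_defer_ms / 1000.0 * self.rate))
                self._update_due = self.i + defer
        if rule.event_type == "TO":
            self.derived_to_threshold = None
        logger.debug("%s: %s fired at i=%d amp=%.3f%s", self.leg,
                     rule.event_type, idx, amp, " (secondary)" if secondary else "")
        return ev

    def _check_secondary_to(self, sample) -> GaitEvent | None:
        """Fallback TO at the negative-to-positive shank angular velocity
        zero crossing, in case the primary definition goes undetected.

        The velocity must first have stayed negative for
        ``secondary_to_min_negative_ms`` (i.e. the late-stance trough region
        was actually entered) so that noise wiggles around the mid-stance
        baseline cannot trigger a premature toe-off.
        """
        v = float(sample.get("shank_angular_velocity", math.nan))
        prev = self._secondary_prev
        self._secondary_prev = v
        min_neg = max(1, int(round(
            self.cfg.secondary_to_min_negative_ms / 1000.0 * self.rate)))
        if v < 0.0:
            self._secondary_neg_count += 1
            return None
        armed = self._secondary_neg_count >= min_neg
        self._secondary_neg_count = 0
        if armed and prev is not None and prev < 0.0 <= v:
            to_rule = self.variant.rule("TO")
            return self._fire_event(to_rule, self.i, v, secondary=True)
        return None

    # -- update layer -------------------------------------------------------

    def update_layer_pass(self) -> None:
        """Per-cycle adaptive threshold update (decoupled from detection).

        For each adaptive rule that fired since the last pass: find the
        event in the LPF signal near the real-time firing, backtrack to the
        raw extremum within ``backtrack_window_ms``, push its amplitude into
        the history and recompute both thresholds.
        """
        w = int(round(self.cfg.search_window_ms / 1000.0 * self.rate))
        b = int(round(self.cfg.backtrack_window_ms / 1000.0 * self.rate))
        for key, policy in self._policies.items():
            fired = self._last_fired.get(key)
            if fired is None or fired[0] <= self._last_updated.get(key, -1):
                continue
            idx, _ = fired
            rule = self.variant.rule(key)
            minimum = policy.direction == "minimum"
            lpf_win, lo = self._lpf_buf[rule.channel].window(idx - w, idx + w, self.i)
            valid = ~np.isnan(lpf_win)
            if not valid.any() or np.nanstd(lpf_win) == 0.0:
                self.errors.append(EventSequenceError(
                    self.leg, key, "flat filtered signal; threshold update skipped",
                    self.i / self.rate))
                self.errors[-1].log(logger)
                continue
            pick = np.nanargmin if minimum else np.nanargmax
            i_lpf = lo + int(pick(lpf_win))
            lpf_amp = float(self._lpf_buf[rule.channel].data[i_lpf % self._lpf_buf[rule.channel].n])
            raw_win, rlo = self._raw[rule.channel].window(i_lpf - b, i_lpf + b, self.i)
            i_raw = rlo + int(pick(raw_win))
            raw_amp = float(self._raw[rule.channel].data[i_raw % self._raw[rule.channel].n])

            self._push(self.history[key], raw_amp, policy.history_length)
            self._push(self._lpf_history[key], lpf_amp, policy.history_length)
            raw_thr = update_threshold(self.history[key], policy)
            lpf_thr = update_threshold(self._lpf_history[key], policy)
            self.thresholds[key] = (raw_thr, lpf_thr)
            self._last_updated[key] = idx
            self.threshold_log.append({
                "cycle": self.cycle_count, "event": key, "leg": self.leg,
                "raw_threshold": raw_thr, "lpf_threshold": lpf_thr,
                "raw_amplitude": raw_amp, "lpf_amplitude": lpf_amp,
            })
            logger.debug("%s: threshold[%s] -> %.3f (raw) / %.3f (lpf)",
                         self.leg, key, raw_thr, lpf_thr)

    @staticmethod
    def _push(buf: list[float], value: float, maxlen: int) -> None:
        buf.append(value)
        del buf[:-maxlen]


# ---------------------------------------------------------------------------
# Whole-trial driver
# ---------------------------------------------------------------------------

def _check_channels(trial: KinematicTrial, variant, legs) -> None:
    for leg in legs:
        have = set(trial.channels.get(leg, {}))
        missing = sorted(set(variant.required_channels) - have)
        if missing:
            raise ChannelError(
                f"variant {variant.name} requires channel(s) "
                f"{', '.join(missing)} missing for {leg} leg")


def run_detailed(trial: KinematicTrial, variant, cfg: EngineConfig | None = None,
                 legs=None) -> tuple[list[GaitEvent], dict[str, LegDetector]]:
    """Stream a whole trial through one detector per leg.

    Returns the merged, time-sorted event list and the final detectors
    (whose threshold logs and states tests and tooling may inspect).
    """
    legs = list(legs) if legs is not None else list(trial.legs)
    _check_channels(trial, variant, legs)
    speed = trial.metadata.get("speed_kmh")
    detectors = {
        leg: LegDetector(variant, leg, trial.sample_rate_kin, cfg, speed_kmh=speed)
        for leg in legs
    }
    events: list[GaitEvent] = []
    n = trial.n_samples
    for leg, det in detectors.items():
        chans = {ch: trial.channels[leg][ch] for ch in variant.required_channels}
        for i in range(n):
            sample = {ch: arr[i] for ch, arr in chans.items()}
            events.extend(det.step(sample))
    events.sort(key=lambda e: (e.time, e.leg, e.event_type))
    return events, detectors


def run(trial: KinematicTrial, variant, cfg: EngineConfig | None = None,
        legs=None) -> list[GaitEvent]:
    """Run a detection variant over a trial; see :func:`run_detailed`."""
    return run_detailed(trial, variant, cfg, legs)[0]
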