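"""Offline gold-standard event detectors.

IC and TO come from a 20 N threshold on the vertical ground-reaction force;
FF and HO from a 100 mm/s threshold on the toe and calcaneus (heel) vertical
velocities, searched inside the GRF-defined stance windows: FF is the first
post-IC time the toe vertical speed falls (and stays, for at least the
debounce duration) below the threshold; HO the first post-FF time the heel
vertical velocity rises above it.

Events are stamped at the threshold crossing itself; the debounce only
requires the crossing to persist, so on clean signals the detected times are
within one sample of the underlying crossing regardless of the debounce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gait_signals import EventSequenceError, GaitEvent, KinematicTrial

logger = logging.getLogger(__name__)

__all__ = ["ReferenceConfig", "detect_grf_events", "detect_marker_events",
           "detect_reference_events"]


@dataclass
class ReferenceConfig:
    grf_threshold: float = 20.0           # N
    marker_velocity_threshold: float = 100.0  # mm/s
    debounce_ms: float = 30.0             # crossing must persist this long

    def validate(self) -> None:
        if self.grf_threshold <= 0 or self.marker_velocity_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.debounce_ms < 0:
            raise ValueError("debounce must be >= 0")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _debounced_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """True runs after removing sub-debounce chatter on both sides."""
    mask = mask.copy()
    for start, stop in _runs(~mask):  # fill short False gaps
        if stop - start < min_len and start > 0 and stop < len(mask):
            mask[start:stop] = True
    return [(a, b) for a, b in _runs(mask) if b - a >= min_len]


def detect_grf_events(grf_vertical: np.ndarray, cfg: ReferenceConfig | None = None,
                      *, sample_rate: float = 1000.0,
                      leg: str = "left") -> list[GaitEvent]:
    """IC at each debounced upward crossing of the GRF threshold, TO at each
    downward crossing; strict IC,TO alternation starting with IC."""
    cfg = cfg or ReferenceConfig()
    cfg.validate()
    grf = np.asarray(grf_vertical, float)
    if np.any(grf < 0):
        raise ValueError("grf_vertical must be >= 0")
    min_len = max(1, int(round(cfg.debounce_ms / 1000.0 * sample_rate)))
    events: list[GaitEvent] = []
    for start, stop in _debounced_runs(grf >= cfg.grf_threshold, min_len):
        if start == 0:
            # signal begins mid-stance: no observed upward crossing, and the
            # paired TO is dropped too so the stream starts with an IC
            continue
        events.append(GaitEvent("IC", leg, start / sample_rate, start,
                                amplitude=float(grf[start]), source="grf_reference"))
        if stop < len(grf):
            events.append(GaitEvent("TO", leg, stop / sample_rate, stop,
                                    amplitude=float(grf[stop]), source="grf_reference"))
    return events


def detect_marker_events(heel_vv: np.ndarray, toe_vv: np.ndarray,
                         cfg: ReferenceConfig | None = None,
                         grf_events: list[GaitEvent] | None = None,
                         *, sample_rate: float = 100.0,
                         leg: str = "left") -> list[GaitEvent]:
    """FF/HO from toe/heel vertical velocity inside GRF stance windows.

    A stance window with no qualifying crossing yields no FF (or HO) for
    that cycle; the absence is logged as an :class:`EventSequenceError`.
    """
    cfg = cfg or ReferenceConfig()
    cfg.validate()
    heel = np.asarray(heel_vv, float)
    toe = np.asarray(toe_vv, float)
    min_len = max(1, int(round(cfg.debounce_ms / 1000.0 * sample_rate)))
    thr = cfg.marker_velocity_threshold

    grf_events = grf_events or []
    windows = _stance_windows(grf_events, leg)
    events: list[GaitEvent] = []
    for t_ic, t_to in windows:
        i_ic = int(np.ceil(t_ic * sample_rate))
        i_to = len(toe) if np.isinf(t_to) else \
            min(int(np.ceil(t_to * sample_rate)), len(toe))
        if i_to <= i_ic:
            continue
        ff_idx = _first_sustained(np.abs(toe[i_ic:i_to]) < thr, min_len)
        if ff_idx is None:
            EventSequenceError(leg, "FF", "toe speed never settled below "
                               f"{thr} mm/s in stance", t_ic).log(logger)
            continue
        i_ff = i_ic + ff_idx
        events.append(GaitEvent("FF", leg, i_ff / sample_rate, i_ff,
                                amplitude=float(toe[i_ff]), source="marker_reference"))
        ho_idx = _first_sustained(heel[i_ff:i_to] > thr, min_len)
        if ho_idx is None:
            EventSequenceError(leg, "HO", "heel vertical velocity never rose "
                               f"above +{thr} mm/s in stance", t_ic).log(logger)
            continue
        i_ho = i_ff + ho_idx
        events.append(GaitEvent("HO", leg, i_ho / sample_rate, i_ho,
                                amplitude=float(heel[i_ho]), source="marker_reference"))
    return events


def _first_sustained(mask: np.ndarray, min_len: int) -> int | None:
    for start, stop in _runs(mask):
        if stop - start >= min_len:
            return start
    return None


def _stance_windows(grf_events, leg: str) -> list[tuple[float, float]]:
    """[IC, TO) windows per stance; a trailing IC whose TO falls beyond the
    recording yields an open-ended window (searched to the end of data)."""
    ics = sorted(e.time for e in grf_events if e.leg == leg and e.event_type == "IC")
    tos = sorted(e.time for e in grf_events if e.leg == leg and e.event_type == "TO")
    windows = []
    for t_ic in ics:
        later = [t for t in tos if t > t_ic]
        windows.append((t_ic, later[0] if later else float("inf")))
    return windows


def detect_reference_events(trial: KinematicTrial,
                            cfg: ReferenceConfig | None = None) -> list[GaitEvent]:
    """Full reference stream (IC/TO from GRF, FF/HO from markers) per leg."""
    cfg = cfg or ReferenceConfig()
    events: list[GaitEvent] = []
    for leg in trial.legs:
        if leg not in trial.grf:
            logger.warning("no GRF for %s leg: reference IC/TO unavailable", leg)
            continue
        grf_ev = detect_grf_events(trial.grf[leg], cfg,
                                   sample_rate=trial.sample_rate_grf, leg=leg)
        events.extend(grf_ev)
        heel = trial.channel(leg, "calcaneus_vertical_velocity", "reference FF/HO")
        toe = trial.channel(leg, "toe_vertical_velocity", "reference FF/HO")
        events.extend(detect_marker_events(
            heel, toe, cfg, grf_ev, sample_rate=trial.sample_rate_kin, leg=leg))
    events.sort(key=lambda e: (e.leg, e.time))
    return events
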