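"""Domain types, unit conventions and plain-text I/O for gait trials and events.

Conventions used throughout the package (documented once, here):

* Angles are in degrees; angular velocity in deg/s; angular acceleration in
  deg/s^2; segment vertical position in metres; segment vertical velocity in
  mm/s; vertical ground-reaction force (GRF) in newtons.
* Shank (tibia) angle is measured in the sagittal plane with respect to the
  vertical and is positive when the top of the shank is forward of vertical.
  Shank angular velocity is positive during forward (swing) rotation, so the
  mid-swing peak is the per-cycle maximum and the late-stance trough is the
  per-cycle minimum.  Vertical velocities are positive upward.
* Sample indices are 0-based; the time of sample ``i`` is ``i / sample_rate``
  (no half-sample offset).  Kinematics and GRF may live at different rates
  (typically 100 and 1000 Hz); every cross-rate comparison is done in
  seconds, never in samples.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical kinematic channels and their units.  GRF is handled separately
#: because it is sampled at a different rate.
CHANNEL_UNITS: dict[str, str] = {
    "shank_angle": "deg",
    "shank_angular_velocity": "deg/s",
    "ankle_angle": "deg",
    "foot_angular_acceleration": "deg/s2",
    "shank_vertical_position": "m",
    "calcaneus_vertical_velocity": "mm/s",
    "toe_vertical_velocity": "mm/s",
}

GRF_CHANNEL = "grf_vertical"
GRF_UNIT = "N"

KINEMATIC_CHANNELS = tuple(CHANNEL_UNITS)

LEGS = ("left", "right")

#: Stance/gait event types in cycle order.  MS (mid-swing, the peak forward
#: shank angular velocity) anchors the cycle for the detectors.
EVENT_TYPES = ("IC", "FF", "HO", "TO", "MS")

EVENT_SOURCES = (
    "ground_truth",
    "grf_reference",
    "marker_reference",
    "rtgsd_min",
    "rtgsd_b6",
    "rtgsd_g6",
)


class ChannelError(ValueError):
    """A required channel is missing or malformed."""


class UnitsError(ValueError):
    """Declared units do not match the package conventions."""


@dataclass(frozen=True)
class GaitEvent:
    """One detected or ground-truth gait event.

    ``sample_index`` is expressed at the kinematic rate except for
    ``source='grf_reference'`` events, which live on the GRF clock.
    ``secondary`` marks a toe-off produced by the fallback zero-crossing
    definition rather than the variant's primary rule.
    """

    event_type: str
    leg: str
    time: float
    sample_index: int
    amplitude: float = float("nan")
    source: str = "ground_truth"
    secondary: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.leg not in LEGS:
            raise ValueError(f"unknown leg {self.leg!r}")


@dataclass(frozen=True)
class EventSequenceError:
    """A signal condition that contradicts the expected event sequence.

    Emitted (logged / collected) by detectors when e.g. a stance window
    contains no qualifying crossing; never silently dropped.
    """

    leg: str
    expected_state: str
    observed_signal_condition: str
    time: float

    def log(self, log: logging.Logger = logger) -> None:
        log.warning(
            "event-sequence anomaly: leg=%s expected=%s observed=%s t=%.3fs",
            self.leg, self.expected_state, self.observed_signal_condition, self.time,
        )


@dataclass
class KinematicTrial:
    """Multi-channel per-leg time series at a fixed kinematic rate.

    ``channels[leg][name]`` are equal-length float arrays at
    ``sample_rate_kin``; ``grf[leg]``, when present, is a non-negative array
    at ``sample_rate_grf``.  Time is implicit (sample i at i/rate).
    """

    sample_rate_kin: float = 100.0
    sample_rate_grf: float = 1000.0
    channels: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    grf: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def legs(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def n_samples(self) -> int:
        for leg in self.channels.values():
            for arr in leg.values():
                return len(arr)
        return 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate_kin

    def time_kin(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_kin

    def channel(self, leg: str, name: str, context: str = "") -> np.ndarray:
        """Fetch a channel, raising a :class:`ChannelError` naming it if absent."""
        try:
            return self.channels[leg][name]
        except KeyError:
            suffix = f" (required by {context})" if context else ""
            raise ChannelError(
                f"trial has no channel {leg}_{name}{suffix}"
            ) from None

    def validate(self) -> None:
        n = None
        for leg, chans in self.channels.items():
            if leg not in LEGS:
                raise ValueError(f"unknown leg {leg!r}")
            for name, arr in chans.items():
                if name not in CHANNEL_UNITS:
                    raise ChannelError(f"unknown channel {name!r}")
                if n is None:
                    n = len(arr)
                elif len(arr) != n:
                    raise ChannelError(
                        f"ragged channel lengths: {leg}_{name} has {len(arr)}, expected {n}"
                    )
        for leg, arr in self.grf.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{leg}_{GRF_CHANNEL} must be >= 0 everywhere")

    def copy(self) -> "KinematicTrial":
        return replace(
            self,
            channels={leg: {k: v.copy() for k, v in ch.items()}
                      for leg, ch in self.channels.items()},
            grf={leg: v.copy() for leg, v in self.grf.items()},
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Trial I/O
#
# Trial CSV dialect: comma-separated, '.' decimal, one `# units:` header line
# declaring the unit of every column; columns `time_s, <leg>_<channel>, ...`.
# GRF lives in a sibling file `<stem>.grf.csv` because of its different rate.
# ---------------------------------------------------------------------------

def _units_line(columns: list[str]) -> str:
    parts = []
    for col in columns:
        if col == "time_s":
            parts.append("time_s=s")
            continue
        leg, _, name = col.partition("_")
        unit = GRF_UNIT if name == GRF_CHANNEL else CHANNEL_UNITS[name]
        parts.append(f"{col}={unit}")
    return "# units: " + ",".join(parts)


def _parse_units_line(line: str, path: str) -> dict[str, str]:
    if not line.startswith("# units:"):
        raise UnitsError(
            f"{path}: first line must be a '# units:' declaration, got {line[:40]!r}"
        )
    decl = {}
    for item in line[len("# units:"):].strip().split(","):
        if not item:
            continue
        col, _, unit = item.partition("=")
        decl[col.strip()] = unit.strip()
    return decl


def _check_units(declared: dict[str, str], path: str) -> None:
    for col, unit in declared.items():
        if col == "time_s":
            expected = "s"
        else:
            _, _, name = col.partition("_")
            if name == GRF_CHANNEL:
                expected = GRF_UNIT
            elif name in CHANNEL_UNITS:
                expected = CHANNEL_UNITS[name]
            else:
                continue  # unknown column; warned about later
        if unit != expected:
            raise UnitsError(
                f"{path}: column {col} declared in {unit!r}, expected {expected!r}"
            )


def _grf_sibling(path: str) -> str:
    stem, ext = os.path.splitext(path)
    return stem + ".grf" + (ext or ".csv")


def write_trial(trial: KinematicTrial, path: str) -> None:
    """Write a trial to CSV (kinematics) plus a GRF sibling file if present."""
    trial.validate()
    cols: dict[str, np.ndarray] = {"time_s": trial.time_kin()}
    for leg in trial.legs:
        for name, arr in trial.channels[leg].items():
            cols[f"{leg}_{name}"] = arr
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(_units_line(list(df.columns)) + "\n")
        fh.write(f"# sample_rate_kin: {trial.sample_rate_kin}\n")
        for key, val in sorted(trial.metadata.items()):
            fh.write(f"# meta: {key}={val}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    if trial.grf:
        gcols: dict[str, np.ndarray] = {}
        n_grf = max(len(v) for v in trial.grf.values())
        gcols["time_s"] = np.arange(n_grf) / trial.sample_rate_grf
        for leg, arr in trial.grf.items():
            gcols[f"{leg}_{GRF_CHANNEL}"] = arr
        gdf = pd.DataFrame(gcols)
        gpath = _grf_sibling(path)
        with open(gpath, "w") as fh:
            fh.write(_units_line(list(gdf.columns)) + "\n")
            fh.write(f"# sample_rate_grf: {trial.sample_rate_grf}\n")
            gdf.to_csv(fh, index=False, float_format="%.12g")


def _read_commented_csv(path: str) -> tuple[pd.DataFrame, dict[str, str], dict]:
    header: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header.append(line.rstrip("\n"))
            else:
                break
    if not header:
        raise UnitsError(f"{path}: missing '# units:' header line")
    units = _parse_units_line(header[0], path)
    meta: dict = {}
    for line in header[1:]:
        body = line.lstrip("# ").strip()
        if body.startswith("meta:"):
            key, _, val = body[len("meta:"):].strip().partition("=")
            meta[key.strip()] = _coerce(val.strip())
        elif ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = _coerce(val.strip())
    df = pd.read_csv(path, comment="#")
    return df, units, meta


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def read_trial(path: str) -> KinematicTrial:
    """Read a trial CSV written by :func:`write_trial` (or hand-authored).

    The units header is mandatory and checked against the package
    conventions; unknown columns are ignored with a logged warning.  Missing
    channels are *not* an error here -- each detection algorithm validates
    its own channel requirements when it is run.
    """
    df, units, meta = _read_commented_csv(path)
    _check_units(units, path)
    trial = KinematicTrial(
        sample_rate_kin=float(meta.pop("sample_rate_kin", 100.0)),
        metadata={k: v for k, v in meta.items()},
    )
    for col in df.columns:
        if col == "time_s":
            continue
        leg, _, name = col.partition("_")
        if leg in LEGS and name in CHANNEL_UNITS:
            trial.channels.setdefault(leg, {})[name] = df[col].to_numpy(float)
        else:
            logger.warning("%s: ignoring unknown column %r", path, col)
    gpath = _grf_sibling(path)
    if os.path.exists(gpath):
        gdf, gunits, gmeta = _read_commented_csv(gpath)
        _check_units(gunits, gpath)
        trial.sample_rate_grf = float(gmeta.get("sample_rate_grf", 1000.0))
        for col in gdf.columns:
            leg, _, name = col.partition("_")
            if leg in LEGS and name == GRF_CHANNEL:
                trial.grf[leg] = gdf[col].to_numpy(float)
    trial.validate()
    return trial


# ---------------------------------------------------------------------------
# Event-list I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["event_type", "leg", "time_s", "sample_index",
                  "amplitude", "source", "secondary"]


def _event_sort_key(ev: GaitEvent):
    # Stable ordering: time, then left before right, then cycle order of types.
    return (ev.time, LEGS.index(ev.leg), EVENT_TYPES.index(ev.event_type), ev.source)


def events_to_frame(events) -> pd.DataFrame:
    rows = [
        {
            "event_type": ev.event_type,
            "leg": ev.leg,
            "time_s": ev.time,
            "sample_index": ev.sample_index,
            "amplitude": ev.amplitude,
            "source": ev.source,
            "secondary": ev.secondary,
        }
        for ev in sorted(events, key=_event_sort_key)
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(events, path: str) -> None:
    """Write events one per row, time-sorted (left before right on ties)."""
    df = events_to_frame(events)
    df.to_csv(path, index=False, float_format="%.12g")


def read_events(path: str) -> list[GaitEvent]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(GaitEvent(
            event_type=row.event_type,
            leg=row.leg,
            time=float(row.time_s),
            sample_index=int(row.sample_index),
            amplitude=float(row.amplitude),
            source=str(row.source),
            secondary=bool(row.secondary),
        ))
    return out
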