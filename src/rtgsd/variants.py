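"""Declarative event-rule sets for the three detection algorithms.

========  =========================  ==============================  =============================
event     rtgsd_min                  rtgsd_b6                        rtgsd_g6
========  =========================  ==============================  =============================
IC        max shank angle            min shank angular velocity      min calcaneus vertical vel.
                                                                     (flag: its post-MS zero cross
                                                                     to negative)
FF        1st min ankle angle piIC   min foot angular acc. post IC   toe vertical vel. > -50 mm/s
HO        1st max ankle angle piIC   min shank vertical position     calcaneus vertical vel.
                                     post FF (flag: 2nd foot-acc     > +50 mm/s
                                     minimum)
TO        min shank angular vel.     upward crossing of M1*A of      toe vertical vel. > +50 mm/s
                                     shank angular vel. (flag: its
                                     trough, amplitude M1)
MS        max shank angular vel.     max shank angular vel.          max shank angular vel.
========  =========================  ==============================  =============================

"piIC" (post ipsilateral IC) search anchors are realised as state-machine
guards, not time windows.  Adaptive thresholds: rtgsd_min updates MS, IC and
TO; rtgsd_b6 updates IC, FF, MS and the TO flag; rtgsd_g6 updates only MS --
all its event thresholds are fixed at 50 mm/s magnitude.

The B6 toe-off coefficient A(speed) maps walking speed to the fraction of
the shank-angular-velocity trough amplitude M1 at which TO is declared
(midpoint definition).  The published source values are not recoverable, so
the shipped table is a flat placeholder ``A = 0.5`` at 3/4/5 km/h with
linear interpolation; users supply literature values via config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .engine import EventRule

logger = logging.getLogger(__name__)

__all__ = ["VariantSpec", "spec_min", "spec_b6", "spec_g6", "get_variant",
           "VARIANT_NAMES"]

VARIANT_NAMES = ("rtgsd_min", "rtgsd_b6", "rtgsd_g6")

#: Generic initial thresholds (channel units), used until the adaptive
#: update has a history.  Derived from the default synthetic waveform
#: amplitudes; they are configuration data, not algorithm structure.
GENERIC_THRESHOLDS = {
    "rtgsd_min": {
        "IC": 18.0,     # deg, max shank angle ~25
        "FF": -6.0,     # deg, fixed: ankle dips to ~-12
        "HO": 6.0,      # deg, fixed: ankle peaks at ~+10
        "TO": -200.0,   # deg/s, trough ~-300
        "MS": 250.0,    # deg/s, peak ~+400
    },
    "rtgsd_b6": {
        "IC": -60.0,     # deg/s, post-MS trough ~-100
        "FF": -250.0,    # deg/s^2, minimum ~-400
        "HO_flag": -150.0,  # deg/s^2, second minimum ~-250
        "HO": 0.442,     # m, fixed: shank height dips to ~0.43
        "TO_flag": -200.0,  # deg/s, trough ~-300
        "MS": 250.0,
    },
    "rtgsd_g6": {
        "MS": 250.0,
    },
}

#: Adaptive-threshold offsets (channel units).  The offset keeps the
#: threshold a safe margin clear of the expected extremum even while the
#: event history is short (when the 3*SD term is still near zero), at gait
#: onset especially; values are set to roughly 3-5x the expected amplitude
#: variability of each signal.  Tunable via config.
DEFAULT_OFFSETS = {
    "rtgsd_min": {"IC": 3.0, "TO": 40.0, "MS": 40.0},
    "rtgsd_b6": {"IC": 25.0, "FF": 40.0, "TO_flag": 40.0, "MS": 40.0},
    "rtgsd_g6": {"MS": 40.0},
}

#: Placeholder B6 speed->A table (flat 0.5); supply literature values.
DEFAULT_TO_COEFFICIENTS = {3.0: 0.5, 4.0: 0.5, 5.0: 0.5}


@dataclass
class VariantSpec:
    """One algorithm: its rules, flags, thresholds and options."""

    name: str
    rules: list[EventRule]
    generic_thresholds: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    to_coefficient_table: dict[float, float] | None = None
    to_flag_name: str | None = None
    use_secondary_to: bool = False

    @property
    def source_name(self) -> str:
        return self.name

    @property
    def required_channels(self) -> tuple[str, ...]:
        chans = {r.channel for r in self.rules}
        if self.use_secondary_to:
            chans.add("shank_angular_velocity")
        return tuple(sorted(chans))

    @property
    def adaptive_set(self) -> set[str]:
        return {r.key for r in self.rules if r.threshold_mode == "adaptive"}

    def rule(self, key: str) -> EventRule:
        for r in self.rules:
            if r.key == key:
                return r
        raise KeyError(key)

    def to_coefficient(self, speed_kmh: float | None) -> float:
        """A(speed) by linear interpolation, nearest-endpoint outside the
        table's range (with a warning)."""
        if self.to_coefficient_table is None:
            raise ValueError(f"{self.name} has no TO coefficient table")
        speeds = np.array(sorted(self.to_coefficient_table))
        values = np.array([self.to_coefficient_table[s] for s in speeds])
        if speed_kmh is None:
            speed_kmh = float(speeds[len(speeds) // 2])
            logger.warning("no walking speed in trial metadata; using "
                           "A(%g km/h)", speed_kmh)
        if speed_kmh < speeds[0] or speed_kmh > speeds[-1]:
            logger.warning("speed %.2f km/h outside A-table range [%g, %g]; "
                           "using nearest endpoint", speed_kmh, speeds[0], speeds[-1])
        a = float(np.interp(speed_kmh, speeds, values))
        if not 0.0 < a < 1.0:
            raise ValueError(f"A(speed) must lie in (0, 1), got {a}")
        return a

    def validate(self) -> None:
        events = [r.key for r in self.rules if not r.is_flag]
        if sorted(events) != sorted(["IC", "FF", "HO", "TO", "MS"]):
            raise ValueError(f"{self.name}: needs exactly one rule per event, "
                             f"got {events}")
        flags = {r.key for r in self.rules if r.is_flag}
        for r in self.rules:
            r.validate()
            if r.guard_flag is not None and r.guard_flag not in flags:
                raise ValueError(f"{self.name}: rule {r.key} references flag "
                                 f"{r.guard_flag} that no flag rule produces")
            if r.threshold_mode == "adaptive" and r.key not in self.generic_thresholds:
                raise ValueError(f"{self.name}: adaptive rule {r.key} has no "
                                 "generic threshold")
            if r.threshold_mode == "derived" and r.key != "TO":
                raise ValueError("derived threshold mode is reserved for the "
                                 "B6 toe-off rule")


def _with_overrides(defaults: dict, overrides: dict | None) -> dict:
    out = dict(defaults)
    if overrides:
        out.update(overrides)
    return out


def spec_min(generic_thresholds: dict | None = None,
             offsets: dict | None = None) -> VariantSpec:
    """Minimal-instrumentation variant: shank angle/angular velocity plus
    ankle angle; adaptive thresholds on MS, IC and TO only (FF and HO use
    fixed generic thresholds that are never updated)."""
    g = _with_overrides(GENERIC_THRESHOLDS["rtgsd_min"], generic_thresholds)
    rules = [
        EventRule("IC", "shank_angle", "maximum", "MS", threshold_mode="adaptive"),
        EventRule("FF", "ankle_angle", "minimum", "IC",
                  threshold_mode="fixed", fixed_value=g["FF"]),
        EventRule("HO", "ankle_angle", "maximum", "FF",
                  threshold_mode="fixed", fixed_value=g["HO"]),
        EventRule("TO", "shank_angular_velocity", "minimum", "HO",
                  threshold_mode="adaptive"),
        EventRule("MS", "shank_angular_velocity", "maximum", "TO",
                  threshold_mode="adaptive"),
    ]
    spec = VariantSpec("rtgsd_min", rules, generic_thresholds=g,
                       offsets=_with_overrides(DEFAULT_OFFSETS["rtgsd_min"], offsets), use_secondary_to=True)
    spec.validate()
    return spec


def spec_b6(generic_thresholds: dict | None = None,
            offsets: dict | None = None,
            to_coefficient_table: dict | None = None) -> VariantSpec:
    """Shank-angular-velocity-centred variant with the midpoint toe-off:
    the trough (amplitude M1) raises the TO flag and TO fires at the upward
    crossing of M1*A(speed).  Adaptive set: IC, FF, MS and the TO flag."""
    g = _with_overrides(GENERIC_THRESHOLDS["rtgsd_b6"], generic_thresholds)
    rules = [
        EventRule("IC", "shank_angular_velocity", "minimum", "MS",
                  threshold_mode="adaptive"),
        EventRule("FF", "foot_angular_acceleration", "minimum", "IC",
                  threshold_mode="adaptive"),
        EventRule("HO_flag", "foot_angular_acceleration", "minimum", "FF",
                  threshold_mode="fixed", fixed_value=g["HO_flag"], is_flag=True),
        EventRule("HO", "shank_vertical_position", "minimum", "FF",
                  guard_flag="HO_flag", threshold_mode="fixed",
                  fixed_value=g["HO"]),
        EventRule("TO_flag", "shank_angular_velocity", "minimum", "HO",
                  threshold_mode="adaptive", is_flag=True),
        EventRule("TO", "shank_angular_velocity", "upward_crossing", "HO",
                  guard_flag="TO_flag", threshold_mode="derived"),
        EventRule("MS", "shank_angular_velocity", "maximum", "TO",
                  threshold_mode="adaptive"),
    ]
    spec = VariantSpec(
        "rtgsd_b6", rules, generic_thresholds=g, offsets=_with_overrides(DEFAULT_OFFSETS["rtgsd_b6"], offsets),
        to_coefficient_table=dict(to_coefficient_table
                                  if to_coefficient_table is not None
                                  else DEFAULT_TO_COEFFICIENTS),
        to_flag_name="TO_flag", use_secondary_to=True)
    spec.validate()
    return spec


def spec_g6(generic_thresholds: dict | None = None,
            offsets: dict | None = None,
            ic_mode: str = "minimum") -> VariantSpec:
    """Segment-vertical-velocity variant with all event thresholds fixed at
    50 mm/s magnitude; MS (max shank angular velocity) is the only adaptive
    threshold.

    ``ic_mode='minimum'`` (default) stamps IC at the calcaneus vertical
    velocity minimum, enabled by a flag at its post-MS zero crossing to
    negative; ``ic_mode='crossing'`` instead stamps IC at the bare upward
    crossing of -50 mm/s after the same flag.
    """
    g = _with_overrides(GENERIC_THRESHOLDS["rtgsd_g6"], generic_thresholds)
    if ic_mode == "minimum":
        ic_rule = EventRule("IC", "calcaneus_vertical_velocity", "minimum",
                            "MS", guard_flag="IC_flag",
                            threshold_mode="fixed", fixed_value=-50.0)
    elif ic_mode == "crossing":
        ic_rule = EventRule("IC", "calcaneus_vertical_velocity",
                            "upward_crossing", "MS", guard_flag="IC_flag",
                            threshold_mode="fixed", fixed_value=-50.0)
    else:
        raise ValueError(f"unknown ic_mode {ic_mode!r}")
    rules = [
        EventRule("IC_flag", "calcaneus_vertical_velocity",
                  "zero_cross_to_negative", "MS", is_flag=True),
        ic_rule,
        EventRule("FF", "toe_vertical_velocity", "upward_crossing", "IC",
                  threshold_mode="fixed", fixed_value=-50.0),
        EventRule("HO", "calcaneus_vertical_velocity", "upward_crossing",
                  "FF", threshold_mode="fixed", fixed_value=50.0),
        EventRule("TO", "toe_vertical_velocity", "upward_crossing", "HO",
                  threshold_mode="fixed", fixed_value=50.0),
        EventRule("MS", "shank_angular_velocity", "maximum", "TO",
                  threshold_mode="adaptive"),
    ]
    spec = VariantSpec("rtgsd_g6", rules, generic_thresholds=g,
                       offsets=_with_overrides(DEFAULT_OFFSETS["rtgsd_g6"], offsets), use_secondary_to=False)
    spec.validate()
    return spec


_FACTORIES = {"rtgsd_min": spec_min, "rtgsd_b6": spec_b6, "rtgsd_g6": spec_g6,
              "min": spec_min, "b6": spec_b6, "g6": spec_g6}


def get_variant(name: str, **kwargs) -> VariantSpec:
    try:
        return _FACTORIES[name.lower()](**kwargs)
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; choose from "
                         f"{VARIANT_NAMES}") from None
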