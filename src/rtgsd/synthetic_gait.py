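"""Synthetic gait-kinematics generator with analytically known events.

Each leg's channels are smooth periodic waveforms built from circular bump
functions ``exp(kappa*(cos(2*pi*(phi - mu)) - 1))`` placed relative to the
configured event phases, so that in the noise-free limit

* ``shank_angle`` peaks exactly at IC,
* ``shank_angular_velocity`` peaks at MS, has its late-stance trough at TO
  and a second (shallower) trough at IC, crossing zero between the TO trough
  and MS,
* ``ankle_angle`` has its first post-IC minimum at FF and first post-IC
  maximum at HO,
* ``foot_angular_acceleration`` has a post-IC minimum at FF and a second
  minimum between FF and HO (the heel-off pre-event),
* ``shank_vertical_position`` has its post-FF minimum at HO,
* ``calcaneus_vertical_velocity`` crosses +50 mm/s upward exactly at HO,
  crosses zero downward after MS and bottoms out (< -50 mm/s) exactly at IC,
* ``toe_vertical_velocity`` crosses -50 mm/s upward exactly at FF and
  +50 mm/s upward exactly at TO,
* ``grf_vertical`` is a double-hump curve strictly above 20 N exactly on the
  stance interval [IC, TO] and decaying to ~0 elsewhere.

For crossing-type constraints the bump sharpness is solved in closed form
from the bump centre, amplitude and the required crossing phase, so the
crossing sits at the event phase by construction.  Cycle-duration jitter
rescales whole cycles, keeping intra-cycle phase relations exact; additive
Gaussian noise perturbs signals but never the ground-truth labels.

The right leg is the left waveform shifted by half a cycle
(``contralateral_phase``).  Ground-truth event times are continuous (not
snapped to the sample grid); ``sample_index`` is the nearest kinematic frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_signals import (
    CHANNEL_UNITS,
    GaitEvent,
    KinematicTrial,
)

__all__ = ["GaitParams", "generate_trial", "degrade", "DEFAULT_NOISE_SD"]

#: Nominal cycle periods per treadmill speed (s); other speeds interpolate.
SPEED_PERIODS = {3.0: 1.2, 4.0: 1.1, 5.0: 1.0}

DEFAULT_EVENT_PHASES = {"IC": 0.0, "FF": 0.08, "HO": 0.40, "TO": 0.62, "MS": 0.80}

#: Default additive noise SD per channel, ~1-2% of each waveform's
#: peak-to-peak amplitude -- the inputs are model-derived (smoothed)
#: kinematics, not raw sensor data.
DEFAULT_NOISE_SD = {
    "shank_angle": 0.5,                 # deg
    "shank_angular_velocity": 8.0,      # deg/s
    "ankle_angle": 0.4,                 # deg
    "foot_angular_acceleration": 10.0,  # deg/s^2
    "shank_vertical_position": 0.001,   # m
    "calcaneus_vertical_velocity": 8.0,  # mm/s
    "toe_vertical_velocity": 10.0,      # mm/s
    "grf_vertical": 3.0,                # N
}


def _bump(phi: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Periodic unit bump centred at phase ``mu`` with sharpness ``kappa``."""
    return np.exp(kappa * (np.cos(2 * np.pi * (phi - mu)) - 1.0))


def _kappa_for_crossing(amplitude: float, threshold: float, delta: float) -> float:
    """Sharpness so that ``amplitude * bump`` equals ``threshold`` at phase
    distance ``delta`` from the bump centre."""
    if not 0 < threshold < abs(amplitude):
        raise ValueError("threshold must lie strictly inside the bump amplitude")
    return float(np.log(threshold / abs(amplitude)) / (np.cos(2 * np.pi * delta) - 1.0))


@dataclass
class GaitParams:
    """Study conditions for one synthetic walking trial."""

    speed_kmh: float = 4.0
    cycle_period_s: float | None = None  # derived from speed when None
    n_cycles: int = 30
    event_phases: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_PHASES))
    noise_scale: float = 1.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    cycle_jitter_sd: float = 0.02  # s
    seed: int = 0
    contralateral_phase: float = 0.5
    legs: tuple[str, ...] = ("left", "right")
    include_grf: bool = True
    sample_rate_kin: float = 100.0
    sample_rate_grf: float = 1000.0
    grf_peak: float = 750.0  # N
    #: From this cycle on, all kinematic bump amplitudes are multiplied by
    #: ``amplitude_step_factor`` (exercises threshold adaptation).
    amplitude_step_cycle: int | None = None
    amplitude_step_factor: float = 1.0

    @property
    def period(self) -> float:
        if self.cycle_period_s is not None:
            return self.cycle_period_s
        if self.speed_kmh in SPEED_PERIODS:
            return SPEED_PERIODS[self.speed_kmh]
        speeds = sorted(SPEED_PERIODS)
        return float(np.interp(self.speed_kmh, speeds,
                               [SPEED_PERIODS[s] for s in speeds]))

    def validate(self) -> None:
        p = self.event_phases
        order = [p[k] for k in ("IC", "FF", "HO", "TO", "MS")]
        if p["IC"] != 0.0:
            raise ValueError("phase(IC) must be 0")
        if not all(a < b for a, b in zip(order, order[1:])) or not order[-1] < 1:
            raise ValueError("event phases must satisfy 0=IC<FF<HO<TO<MS<1")
        if any(v < 0 for v in self.noise_sd.values()) or self.noise_scale < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.cycle_jitter_sd < 0.2 * self.period:
            raise ValueError("cycle_jitter_sd must be < 0.2 * cycle period")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


# ---------------------------------------------------------------------------
# Waveform templates
# ---------------------------------------------------------------------------

def _channel_bumps(phases: dict[str, float]) -> dict[str, tuple[float, list]]:
    """(baseline, [(mu, amplitude, kappa), ...]) per kinematic channel."""
    ic, ff, ho, to, ms = (phases[k] for k in ("IC", "FF", "HO", "TO", "MS"))
    ho_flag = 0.5 * (ff + ho)          # second foot-acceleration minimum
    push_off = min(to + 0.08, 0.5 * (to + ms))

    # steep heel rise: the +50 crossing (HO anchor) and the +100 level used
    # by the marker reference sit within ~5 ms of each other
    calc_mu = ho + 0.03
    calc_kappa = _kappa_for_crossing(500.0, 50.0, calc_mu - ho)
    toe_neg_mu = ff - 0.04
    toe_neg_kappa = _kappa_for_crossing(400.0, 50.0, ff - toe_neg_mu)
    toe_pos_mu = to + 0.08
    toe_pos_kappa = _kappa_for_crossing(500.0, 50.0, toe_pos_mu - to)

    return {
        "shank_angle": (-10.0, [(ic, 35.0, 8.0)]),
        "shank_angular_velocity": (20.0, [
            (ic, -120.0, 40.0),
            (to, -320.0, 50.0),
            (ms, 380.0, 40.0),
        ]),
        "ankle_angle": (0.0, [
            (ff, -12.0, 120.0),
            (ho, 10.0, 30.0),
            (push_off, -10.0, 60.0),
        ]),
        "foot_angular_acceleration": (0.0, [
            (ff, -400.0, 80.0),
            (ho_flag, -250.0, 80.0),
            (ms - 0.10, 200.0, 60.0),
        ]),
        "shank_vertical_position": (0.45, [
            (ho, -0.02, 40.0),
            (ms, 0.03, 20.0),
        ]),
        "calcaneus_vertical_velocity": (0.0, [
            (calc_mu, 500.0, calc_kappa),
            (ms - 0.05, 20.0, 8.0),
            (ic, -150.0, 80.0),
        ]),
        "toe_vertical_velocity": (0.0, [
            (toe_neg_mu, -400.0, toe_neg_kappa),
            (toe_pos_mu, 500.0, toe_pos_kappa),
            (ic - 0.10, -200.0, 60.0),
        ]),
    }


def evaluate_channel(channel: str, phi: np.ndarray,
                     phases: dict[str, float] | None = None,
                     amplitude_scale: np.ndarray | float = 1.0) -> np.ndarray:
    """Noise-free value of a kinematic channel at cycle phase(s) ``phi``.

    Exposed so tests can compare streaming detections against dense offline
    evaluations of the exact waveform.
    """
    phases = phases or DEFAULT_EVENT_PHASES
    baseline, bumps = _channel_bumps(phases)[channel]
    phi = np.asarray(phi, float)
    dev = np.zeros_like(phi)
    for mu, amp, kappa in bumps:
        dev += amp * _bump(phi, mu, kappa)
    return baseline + amplitude_scale * dev


def _grf_waveform(phi: np.ndarray, period: float, to_phase: float,
                  peak: float) -> np.ndarray:
    """Double-hump vertical GRF: exactly 20 N at the stance edges, > 20 N
    inside [IC, TO], decaying to ~0 within a few ms outside."""
    phi = np.asarray(phi, float)
    out = np.zeros_like(phi)
    stance = phi <= to_phase
    u = np.clip(phi[stance] / to_phase, 0.0, 1.0)
    shape = np.sin(np.pi * u) ** 1.5 * (1.0 - 0.35 * np.exp(-((u - 0.5) / 0.18) ** 2))
    out[stance] = 20.0 + (peak - 20.0) * shape
    # outside stance: distance (s) to the nearest stance edge
    d = np.minimum(phi[~stance] - to_phase, 1.0 - phi[~stance]) * period
    out[~stance] = 20.0 * np.exp(-((d / 0.004) ** 2))
    return out


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def _cycle_timeline(params: GaitParams, rng: np.random.Generator):
    """Jittered cycle start times covering the trial plus a spare cycle."""
    n = params.n_cycles + 1
    jitter = rng.normal(0.0, params.cycle_jitter_sd, size=n) if params.cycle_jitter_sd > 0 \
        else np.zeros(n)
    jitter = np.clip(jitter, -3 * params.cycle_jitter_sd, 3 * params.cycle_jitter_sd)
    periods = params.period + jitter
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    return starts, periods


def _phase_of(t: np.ndarray, starts: np.ndarray, periods: np.ndarray):
    """Cycle index and in-cycle phase of each time point."""
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(periods) - 1)
    phi = (t - starts[idx]) / periods[idx]
    return idx, np.clip(phi, 0.0, np.nextafter(1.0, 0.0))


def generate_trial(params: GaitParams) -> tuple[KinematicTrial, list[GaitEvent]]:
    """Generate one two-leg trial and its exact ground-truth event list."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    starts, periods = _cycle_timeline(params, rng)
    # stop just short of the final cycle boundary (an IC peak): a trial that
    # ends exactly on a half-risen peak has no labelled event there for a
    # detector to agree with
    duration = starts[params.n_cycles] - 0.05 * params.period
    n_kin = int(round(duration * params.sample_rate_kin))
    t_kin = np.arange(n_kin) / params.sample_rate_kin
    idx_kin, phi_kin = _phase_of(t_kin, starts, periods)

    scale_of_cycle = np.ones(len(periods))
    if params.amplitude_step_cycle is not None:
        scale_of_cycle[params.amplitude_step_cycle:] = params.amplitude_step_factor
    scale_kin = scale_of_cycle[idx_kin]

    trial = KinematicTrial(
        sample_rate_kin=params.sample_rate_kin,
        sample_rate_grf=params.sample_rate_grf,
        metadata={"speed_kmh": params.speed_kmh, "subject": "synthetic",
                  "seed": params.seed},
    )

    leg_shift = {"left": 0.0}
    if "right" in params.legs:
        leg_shift["right"] = params.contralateral_phase

    if params.include_grf:
        n_grf = int(round(duration * params.sample_rate_grf))
        t_grf = np.arange(n_grf) / params.sample_rate_grf
        idx_grf, phi_grf = _phase_of(t_grf, starts, periods)

    for leg in params.legs:
        shift = leg_shift[leg]
        phi_leg = (phi_kin + shift) % 1.0
        chans = {}
        for name in CHANNEL_UNITS:
            clean = evaluate_channel(name, phi_leg, params.event_phases, scale_kin)
            sd = params.noise_sd.get(name, 0.0) * params.noise_scale
            noise = rng.normal(0.0, sd, size=n_kin) if sd > 0 else 0.0
            chans[name] = clean + noise
        trial.channels[leg] = chans
        if params.include_grf:
            phi_g = (phi_grf + shift) % 1.0
            grf = _grf_waveform(phi_g, params.period, params.event_phases["TO"],
                                params.grf_peak)
            sd = params.noise_sd.get("grf_vertical", 0.0) * params.noise_scale
            if sd > 0:
                grf = grf + rng.normal(0.0, sd, size=len(grf))
            trial.grf[leg] = np.clip(grf, 0.0, None)

    truth: list[GaitEvent] = []
    for leg in params.legs:
        shift = leg_shift[leg]
        for c in range(params.n_cycles):
            for ev, p in params.event_phases.items():
                # leg phase equals p when base phase equals (p - shift) mod 1
                t_ev = starts[c] + ((p - shift) % 1.0) * periods[c]
                truth.append(GaitEvent(
                    event_type=ev, leg=leg, time=float(t_ev),
                    sample_index=int(round(t_ev * params.sample_rate_kin)),
                    source="ground_truth",
                ))
    truth.sort(key=lambda e: (e.leg, e.time))
    trial.validate()
    return trial, truth


# ---------------------------------------------------------------------------
# Degradations (robustness fixtures)
# ---------------------------------------------------------------------------

def degrade(trial: KinematicTrial, kind: str, *, channel: str | None = None,
            leg: str | None = None, sd: float = 0.0, seed: int = 0,
            ceiling: float | None = None, t_start: float | None = None,
            t_end: float | None = None) -> KinematicTrial:
    """Return a degraded copy of ``trial``; ground truth is unaffected.

    kinds: ``drop_channel`` (remove a kinematic channel), ``add_noise``
    (extra Gaussian noise on one channel or all), ``saturate`` (clip a
    channel, or the GRF, at ``ceiling``), ``flatten`` (hold a channel
    constant over [t_start, t_end] seconds).
    """
    out = trial.copy()
    legs = [leg] if leg else list(out.legs)
    if kind == "drop_channel":
        if channel is None:
            raise ValueError("drop_channel requires a channel name")
        for lg in legs:
            out.channels[lg].pop(channel, None)
    elif kind == "add_noise":
        rng = np.random.default_rng(seed)
        for lg in legs:
            names = [channel] if channel else list(out.channels[lg])
            for name in names:
                arr = out.channels[lg][name]
                if sd > 0:
                    out.channels[lg][name] = arr + rng.normal(0, sd, size=len(arr))
    elif kind == "saturate":
        if ceiling is None:
            raise ValueError("saturate requires a ceiling")
        for lg in legs:
            if channel == "grf_vertical" or (channel is None and out.grf):
                if lg in out.grf:
                    out.grf[lg] = np.clip(out.grf[lg], 0.0, ceiling)
            elif channel in out.channels[lg]:
                arr = out.channels[lg][channel]
                out.channels[lg][channel] = np.clip(arr, None, ceiling)
            else:
                raise ValueError(f"unknown channel {channel!r}")
    elif kind == "flatten":
        if channel is None or t_start is None or t_end is None:
            raise ValueError("flatten requires channel, t_start and t_end")
        for lg in legs:
            arr = out.channels[lg][channel]
            i0 = int(round(t_start * out.sample_rate_kin))
            i1 = int(round(t_end * out.sample_rate_kin))
            arr[i0:i1] = arr[min(i0, len(arr) - 1)]
    else:
        raise ValueError(f"unknown degradation {kind!r}")
    return out
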