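"""Seeded simulator of VR head-rotation streams with ground-truth events.

The generator emulates a target-orienting paradigm on a 90 Hz head-mounted
display: each trial starts with a 500 ms stationary fixation period, after
which the participant orients toward a target at one of several
eccentricities (10-50 deg) in one of eight compass directions, holds, and
returns to center.  Two target conditions are modelled:

* **instant** — the target jumps to its eccentric location, eliciting a
  ballistic head movement with a raised-cosine speed profile whose peak
  velocity follows a main-sequence relation (peak = slope x amplitude,
  with lognormal scatter);
* **pursuit** — the target glides at 20 deg/s, eliciting a sustained
  near-constant-speed rotation with short cosine ramps.

Head gain is below 1 (the head covers only part of the gaze shift; 60% by
default).  Orientation noise is smooth (low-passed) per-axis jitter, as
from tracker noise plus postural sway.  Simulated raters reproduce human
annotation behaviour: Gaussian onset/offset jitter, optional deterministic
shifts, a per-event miss probability, and an optional peak-speed floor
below which movements go unnoticed.

All randomness flows from ``SimConfig.seed`` through per-trial and
per-rater substreams, so equal seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .classifiers import LabelSeries, MovementEvent, events_to_labels
from .fitting import SubjectData
from .kinematics import OrientationTrace, compute_kinematics

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_trace",
    "simulate_raters",
    "simulate_subjects",
    "direction_label",
]

_COMPASS = {0: "E", 45: "NE", 90: "N", 135: "NW", 180: "W", 225: "SW", 270: "S", 315: "SE"}


def direction_label(theta_deg: float) -> str:
    """Compass label for a screen direction (0 = rightward, CCW)."""
    key = int(round(theta_deg / 45.0) * 45) % 360
    return _COMPASS[key]


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Movement-generating parameters mirror the paradigm being emulated
    (90 Hz sampling, 10-50 deg eccentricities in 8 directions, 20 deg/s
    pursuit target, 500 ms pre-trial fixation).  Free parameters are set
    to values typical of seated VR head tracking: head gain 0.6 (heads
    under-rotate relative to gaze), main-sequence slope 6 (deg/s)/deg
    with 10% lognormal scatter, smooth orientation jitter of 0.02 deg SD,
    rater boundary jitter of 20 ms SD with a 5% miss rate.
    """

    rate: float = 90.0
    n_trials: int = 20
    condition: str = "instant"            # 'instant' | 'pursuit'
    eccentricities: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    pursuit_speed: float = 20.0           # deg/s
    head_gain: float = 0.6                # fraction of eccentricity the head covers
    main_sequence_slope: float = 6.0      # (deg/s)/deg : peak velocity per amplitude
    peak_velocity_noise_sd: float = 0.1   # lognormal sigma on peak velocity
    noise_sd_deg: float = 0.02            # per-axis orientation jitter SD
    noise_cutoff_hz: float = 5.0          # jitter smoothness
    rest_duration_s: float = 0.5          # pre-trial fixation hold
    hold_duration_s: float = 0.3          # dwell between movements
    pursuit_ramp_s: float = 0.1
    trial_duration_s: float | None = None  # None: computed to fit all movements
    corrective_prob: float = 0.0          # probability of a small follow-up movement
    corrective_amplitude_range: tuple[float, float] = (2.0, 5.0)
    n_raters: int = 2
    rater_jitter_sd_ms: float = 20.0
    rater_miss_prob: float = 0.05
    rater_onset_shift_ms: float = 0.0
    rater_offset_shift_ms: float = 0.0
    rater_min_peak_speed: float | None = None  # events slower than this go unlabeled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("instant", "pursuit"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.eccentricities or not self.directions:
            raise ValueError("eccentricity and direction sets must be non-empty")
        for name in ("noise_sd_deg", "rater_jitter_sd_ms", "peak_velocity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimOutput:
    """Simulator result: the trace, exact ground truth, and rater labels."""

    trace: OrientationTrace
    truth_events: list[MovementEvent]
    rater_labels: list[LabelSeries]
    markers: list[tuple[float, str]] = field(default_factory=list)

    @property
    def truth_labels(self) -> LabelSeries:
        return events_to_labels(self.truth_events, self.trace.timestamps)


# ---------------------------------------------------------------------------
# movement profiles: angle covered as a function of normalized time

def _raised_cosine_fraction(tau: np.ndarray) -> np.ndarray:
    """Fraction of amplitude covered at normalized time tau (speed is a
    raised cosine: v(t) = Vp/2 * (1 - cos(2 pi tau)), Vp = 2A/T)."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def _pursuit_fraction(t: np.ndarray, T: float, ramp: float) -> np.ndarray:
    """Fraction covered for a trapezoid-like speed profile with cosine ramps
    of length ``ramp`` and plateau speed A/(T - ramp)."""
    t = np.clip(t, 0.0, T)
    # unit plateau speed, later normalized by total area T - ramp
    up = np.clip(t, 0.0, ramp)
    area = 0.5 * (up - (ramp / np.pi) * np.sin(np.pi * up / ramp))
    mid = np.clip(t - ramp, 0.0, T - 2 * ramp)
    area = area + mid
    dn = np.clip(t - (T - ramp), 0.0, ramp)
    area = area + 0.5 * (dn + (ramp / np.pi) * np.sin(np.pi * dn / ramp))
    return area / (T - ramp)


@dataclass(frozen=True)
class _Move:
    start: float        # s, within trial
    duration: float     # s
    signed_amp: float   # deg along the trial axis (negative = return)
    peak: float         # deg/s
    kind: str           # 'instant' | 'pursuit'


def _move_fraction(move: _Move, t: np.ndarray, ramp: float) -> np.ndarray:
    rel = t - move.start
    if move.kind == "instant":
        return _raised_cosine_fraction(rel / move.duration)
    return _pursuit_fraction(rel, move.duration, ramp)


def _smooth_noise(rng: np.random.Generator, n: int, rate: float,
                  sd_deg: float, cutoff: float) -> np.ndarray:
    """(n, 3) smooth per-axis angular jitter with the requested SD."""
    if sd_deg == 0 or n < 20:
        return np.zeros((n, 3))
    white = rng.standard_normal((n, 3))
    b, a = butter(2, cutoff / (rate / 2), btype="low")
    smooth = filtfilt(b, a, white, axis=0)
    smooth /= smooth.std(axis=0, keepdims=True)
    return smooth * sd_deg


def _trial_duration(cfg: SimConfig) -> float:
    sigma = cfg.peak_velocity_noise_sd
    t_inst = 2.0 / cfg.main_sequence_slope * math.exp(3.0 * sigma)
    a_max = cfg.head_gain * max(cfg.eccentricities) + cfg.corrective_amplitude_range[1]
    if cfg.condition == "instant":
        t_move = t_inst
        t_ret = t_inst
    else:
        t_move = a_max / cfg.pursuit_speed + cfg.pursuit_ramp_s
        t_ret = t_move
    # fixation + out + (corrective) + return, each separated by a hold
    need = (cfg.rest_duration_s + t_move + cfg.hold_duration_s + t_inst
            + cfg.hold_duration_s + t_ret + 0.3)
    return need


def simulate_trace(cfg: SimConfig) -> SimOutput:
    """Generate one recording: trace, truth events, markers, rater labels.

    Each trial holds fixation for ``rest_duration_s``, makes one orienting
    movement toward the trial's target, optionally a small corrective
    movement, then returns to center.  Truth events carry exact
    (continuous-time) onset/offset, compass direction, amplitude and peak
    velocity.
    """
    trial_dur = cfg.trial_duration_s or _trial_duration(cfg)
    rate = cfg.rate
    n_per_trial = int(round(trial_dur * rate))
    n = n_per_trial * cfg.n_trials
    timestamps = np.arange(n) / rate

    truth: list[MovementEvent] = []
    markers: list[tuple[float, str]] = []
    rotvecs = np.zeros((n, 3))

    for trial in range(cfg.n_trials):
        rng = np.random.default_rng([cfg.seed, trial])
        t0 = trial * trial_dur
        ecc = float(rng.choice(cfg.eccentricities))
        theta = float(rng.choice(cfg.directions))
        amp = cfg.head_gain * ecc

        moves: list[_Move] = []
        cursor = cfg.rest_duration_s
        moves.append(_make_move(cfg, rng, cursor, amp))
        cursor = moves[-1].start + moves[-1].duration + cfg.hold_duration_s
        if rng.random() < cfg.corrective_prob:
            lo, hi = cfg.corrective_amplitude_range
            corr_amp = float(rng.uniform(lo, hi))
            corr = _make_move(cfg, rng, cursor, corr_amp, kind="instant")
            moves.append(corr)
            cursor = corr.start + corr.duration + cfg.hold_duration_s
        total = sum(m.signed_amp for m in moves)
        ret = _make_move(cfg, rng, cursor, total, sign=-1.0)
        moves.append(ret)
        if ret.start + ret.duration > trial_dur - 0.05:
            raise ValueError(
                f"movements ({ret.start + ret.duration:.2f} s) do not fit the "
                f"trial window ({trial_dur:.2f} s); increase trial_duration_s"
            )

        rad = math.radians(theta)
        axis = np.array([-math.sin(rad), math.cos(rad), 0.0])  # moves +Z toward theta
        sel = slice(trial * n_per_trial, (trial + 1) * n_per_trial)
        t_local = timestamps[sel] - t0
        angle = np.zeros(n_per_trial)
        for m in moves:
            angle = angle + m.signed_amp * _move_fraction(m, t_local, cfg.pursuit_ramp_s)
        rotvecs[sel] = np.radians(angle)[:, None] * axis

        for m in moves:
            label = direction_label(theta if m.signed_amp >= 0 else theta + 180.0)
            truth.append(MovementEvent(
                onset=t0 + m.start, offset=t0 + m.start + m.duration,
                direction=label, amplitude=abs(m.signed_amp), peak_velocity=m.peak,
            ))
        markers.append((t0, "trial_start"))
        markers.append((t0 + cfg.rest_duration_s, "target_on"))
        markers.append((t0 + trial_dur - 1e-9, "response"))

    noise_rng = np.random.default_rng([cfg.seed, 999_999_937])
    noise = _smooth_noise(noise_rng, n, rate, cfg.noise_sd_deg, cfg.noise_cutoff_hz)
    path = Rotation.from_rotvec(rotvecs)
    jitter = Rotation.from_euler("YXZ", noise[:, [1, 0, 2]], degrees=True)
    quat = (path * jitter).as_quat()

    trace = OrientationTrace(timestamps=timestamps, quat=quat,
                             sample_rate=rate, markers=markers)
    raters = simulate_raters(truth, timestamps, cfg)
    return SimOutput(trace=trace, truth_events=truth,
                     rater_labels=raters, markers=markers)


def _make_move(cfg: SimConfig, rng: np.random.Generator, start: float,
               amp: float, sign: float = 1.0, kind: str | None = None) -> _Move:
    kind = kind or cfg.condition
    if kind == "instant":
        z = float(np.clip(rng.normal(0.0, cfg.peak_velocity_noise_sd),
                          -3 * cfg.peak_velocity_noise_sd,
                          3 * cfg.peak_velocity_noise_sd))
        peak = cfg.main_sequence_slope * amp * math.exp(z)
        duration = 2.0 * amp / peak
    else:
        duration = amp / cfg.pursuit_speed + cfg.pursuit_ramp_s
        peak = amp / (duration - cfg.pursuit_ramp_s)
    return _Move(start=start, duration=duration, signed_amp=sign * amp,
                 peak=peak, kind=kind)


def simulate_raters(
    truth: list[MovementEvent],
    timestamps: np.ndarray,
    cfg: SimConfig,
) -> list[LabelSeries]:
    """Simulated human raters: jittered, occasionally missed truth events.

    Each rater perturbs every event boundary with Gaussian jitter of
    ``rater_jitter_sd_ms`` plus the deterministic shift fields, drops each
    event with ``rater_miss_prob``, and never reports events whose peak
    velocity falls below ``rater_min_peak_speed``.  Offsets are clamped to
    stay after onsets.
    """
    timestamps = np.asarray(timestamps, float)
    dt = float(np.median(np.diff(timestamps))) if len(timestamps) > 1 else 1.0 / cfg.rate
    out: list[LabelSeries] = []
    for rater in range(cfg.n_raters):
        rng = np.random.default_rng([cfg.seed, 1_000_003, rater])
        events: list[MovementEvent] = []
        for e in truth:
            if (cfg.rater_min_peak_speed is not None
                    and e.peak_velocity is not None
                    and e.peak_velocity < cfg.rater_min_peak_speed):
                continue
            if rng.random() < cfg.rater_miss_prob:
                continue
            jit = cfg.rater_jitter_sd_ms / 1000.0
            onset = (e.onset + cfg.rater_onset_shift_ms / 1000.0
                     + rng.normal(0.0, jit))
            offset = (e.offset + cfg.rater_offset_shift_ms / 1000.0
                      + rng.normal(0.0, jit))
            if offset <= onset:
                offset = onset + dt
            events.append(MovementEvent(onset=onset, offset=offset))
        events.sort(key=lambda ev: ev.onset)
        out.append(events_to_labels(events, timestamps))
    return out


def simulate_subjects(
    n_subjects: int, cfg: SimConfig
) -> tuple[list[SubjectData], list[SimOutput]]:
    """Simulate a cohort: one recording per subject, seeds split per subject.

    Returns fitting-ready :class:`SubjectData` (kinematics precomputed)
    alongside the raw simulator outputs.
    """
    from dataclasses import replace as _replace

    subjects: list[SubjectData] = []
    outputs: list[SimOutput] = []
    for i in range(n_subjects):
        sub_cfg = _replace(cfg, seed=int(np.random.default_rng([cfg.seed, 77, i])
                                         .integers(0, 2**31 - 1)))
        out = simulate_trace(sub_cfg)
        kin = compute_kinematics(out.trace)
        subjects.append(SubjectData(
            subject=f"S{i + 1:02d}", trace=out.trace, kin=kin,
            rater_labels=out.rater_labels, mask=None, condition=cfg.condition,
        ))
        outputs.append(out)
    return subjects, outputs
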