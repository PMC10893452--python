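"""Shared fixtures: independent oracles and small signal builders."""

from __future__ import annotations

import math

import numpy as np
import pytest

from headmov.classifiers import CwConfig, KinematicSeries, LabelSeries, MovementEvent
from headmov.kinematics import OrientationTrace, ms_to_samples
from scipy.spatial.transform import Rotation

RATE = 90.0


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)

def kappa_bruteforce(a, b) -> tuple[float, float, float]:
    """Cohen's kappa from an explicitly counted 2x2 contingency table."""
    n00 = n01 = n10 = n11 = 0
    for x, y in zip(a, b):
        if x and y:
            n11 += 1
        elif x and not y:
            n10 += 1
        elif y:
            n01 += 1
        else:
            n00 += 1
    n = n00 + n01 + n10 + n11
    po = (n00 + n11) / n
    p_a1 = (n11 + n10) / n
    p_b1 = (n11 + n01) / n
    pe = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    kappa = (po - pe) / (1 - pe) if pe < 1 else math.nan
    return po, pe, kappa


def chen_walton_bruteforce(speed, cfg: CwConfig, rate: float) -> list[tuple[int, int]]:
    """Window-rule re-scan: returns (onset_idx, offset_idx_exclusive_end) pairs.

    Walks every window position explicitly; offset index None-at-end is
    encoded as len(speed).
    """
    speed = list(map(float, speed))
    n = len(speed)
    n_on = ms_to_samples(cfg.onset_window_ms, rate)
    n_off = ms_to_samples(cfg.offset_window_ms, rate)
    need_on = math.ceil(cfg.frac * n_on)
    need_off = math.ceil(cfg.frac * n_off)
    above = [s > cfg.speed_threshold for s in speed]

    def onset_ok(w):
        window = above[w : w + n_on]
        if sum(window) < need_on:
            return False
        consec = best = 0
        for val in window:
            consec = consec + 1 if not val else 0
            best = max(best, consec)
        return best < cfg.max_consecutive_below

    events = []
    pos = 0
    while pos <= n - n_on:
        w = pos
        while w <= n - n_on and not onset_ok(w):
            w += 1
        if w > n - n_on:
            break
        onset = next(i for i in range(w, w + n_on) if above[i])
        w2 = onset + 1
        offset = None
        while w2 <= n - n_off:
            window = above[w2 : w2 + n_off]
            if sum(1 for v in window if not v) >= need_off:
                offset = next(i for i in range(w2, w2 + n_off) if not above[i])
                break
            w2 += 1
        if offset is None:
            events.append((onset, n))
            break
        events.append((onset, offset))
        pos = offset + 1
    return events


@pytest.fixture
def kappa_oracle():
    return kappa_bruteforce


@pytest.fixture
def cw_oracle():
    return chen_walton_bruteforce


# ---------------------------------------------------------------------------
# builders

def make_speed_kin(speed, rate: float = RATE) -> KinematicSeries:
    """KinematicSeries around a given speed series (other channels zeroed)."""
    speed = np.asarray(speed, float)
    n = len(speed)
    t = np.arange(n) / rate
    return KinematicSeries(
        timestamps=t,
        speed=speed,
        vel_xyz=np.zeros((n, 3)),
        accel=np.gradient(speed, 1.0 / rate) if n > 1 else np.zeros(n),
        head_angle=np.zeros(n),
        rate=rate,
    )


def axis_rotation(axis: str, angles_deg) -> Rotation:
    """Single-axis rotation sequence (angles as a 1-D array)."""
    angles = np.atleast_1d(np.asarray(angles_deg, float))
    return Rotation.from_euler(axis, angles[:, None], degrees=True)


def yaw_trace(yaw_deg, rate: float = RATE, **kw) -> OrientationTrace:
    """Trace rotating about the vertical (Y) axis by the given yaw series."""
    yaw = np.asarray(yaw_deg, float)
    t = np.arange(len(yaw)) / rate
    quat = axis_rotation("Y", yaw).as_quat()
    return OrientationTrace(timestamps=t, quat=quat, sample_rate=rate, **kw)


def raised_cosine_speed(peak: float, duration_s: float, rate: float = RATE,
                        pad_s: float = 0.5) -> np.ndarray:
    """Speed series: zeros, one raised-cosine bump, zeros."""
    n_pad = int(round(pad_s * rate))
    n_bump = int(round(duration_s * rate)) + 1
    tau = np.arange(n_bump) / (n_bump - 1)
    bump = peak / 2.0 * (1.0 - np.cos(2.0 * np.pi * tau))
    return np.concatenate([np.zeros(n_pad), bump, np.zeros(n_pad)])


def labels(bits, rate: float = RATE, mask=None) -> LabelSeries:
    bits = np.asarray(bits, bool)
    return LabelSeries(timestamps=np.arange(len(bits)) / rate, moving=bits, mask=mask)


def random_events(rng: np.random.Generator, n: int, t_max: float) -> list[MovementEvent]:
    """Sorted, disjoint random events in [0, t_max]."""
    cuts = np.sort(rng.uniform(0, t_max, size=2 * n))
    return [MovementEvent(onset=float(a), offset=float(b))
            for a, b in zip(cuts[0::2], cuts[1::2]) if b > a]
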