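"""Head-orientation traces and the kinematic signals derived from them.

A head-mounted display reports head orientation once per frame (90 Hz for
the HTC Vive Pro family).  Every classifier in :mod:`headmov.classifiers`
consumes one or more of the derived per-sample signals computed here:

* **angular speed** — geodesic angle between consecutive orientations
  divided by the sample interval (deg/s);
* **per-axis angular velocity** — rotation rate about each of the three
  engine axes (deg/s), by default the time derivative of unwrapped Euler
  angles;
* **angular acceleration** — time derivative of angular speed (deg/s²);
* **head-angle magnitude** — angle between the head's forward vector and
  the world forward vector (deg).

Axis convention (game-engine style): Y is up/down (rotation about Y is a
yaw, i.e. a left/right head turn), X is left/right (rotation about X is a
pitch, an up/down turn), Z points forward (rotation about Z is a roll).
Euler angles use the intrinsic Y-X-Z (yaw, pitch, roll) decomposition.
All angles are degrees, all times seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt, savgol_filter
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "OrientationTrace",
    "KinematicSeries",
    "resample_uniform",
    "angular_speed",
    "per_axis_angular_velocity",
    "head_angle_magnitude",
    "angular_acceleration",
    "savgol_smooth",
    "lowpass",
    "compute_kinematics",
    "ms_to_samples",
    "odd_window_samples",
    "euler_to_quat",
    "quat_to_euler",
]

#: World forward unit vector (+Z in the engine frame).
FORWARD = np.array([0.0, 0.0, 1.0])

#: Euler sequence: intrinsic yaw (Y), pitch (X), roll (Z).
_EULER_SEQ = "YXZ"

#: Pitch magnitude (deg) beyond which Euler rates are flagged as unreliable.
GIMBAL_PITCH_DEG = 89.0


def ms_to_samples(ms: float, rate: float) -> int:
    """Convert a duration in milliseconds to a sample count (floor 1)."""
    return max(1, round(ms * rate / 1000.0))


def odd_window_samples(ms: float, rate: float) -> int:
    """Window length in samples for a duration in ms, forced odd (round up)."""
    n = ms_to_samples(ms, rate)
    return n if n % 2 == 1 else n + 1


def euler_to_quat(rx_deg, ry_deg, rz_deg) -> np.ndarray:
    """Engine Euler angles (pitch, yaw, roll; deg) -> quaternions (x,y,z,w)."""
    ang = np.stack(
        [np.asarray(ry_deg, float), np.asarray(rx_deg, float), np.asarray(rz_deg, float)],
        axis=-1,
    )
    return Rotation.from_euler(_EULER_SEQ, ang, degrees=True).as_quat()


def quat_to_euler(quat: np.ndarray) -> np.ndarray:
    """Quaternions (x,y,z,w) -> engine Euler angles as columns (rx, ry, rz) deg."""
    yxz = Rotation.from_quat(quat).as_euler(_EULER_SEQ, degrees=True)
    return yxz[..., [1, 0, 2]]


def _canonical_quats(quat: np.ndarray) -> np.ndarray:
    """Normalize and sign-align quaternions.

    Unit quaternions double-cover rotations (q and -q are the same
    orientation); consecutive dot products are made non-negative so
    geodesic distances and slerp behave continuously.
    """
    q = np.asarray(quat, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError(f"expected an (n, 4) quaternion array, got shape {q.shape}")
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm quaternion in trace")
    q = q / norms[:, None]
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    flip = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flip[:, None]
    return q


@dataclass
class OrientationTrace:
    """A time series of head orientations with optional trial markers.

    Parameters
    ----------
    timestamps : (n,) float array, seconds, strictly increasing.
    quat : (n, 4) float array of unit quaternions in scalar-last
        (x, y, z, w) order, mapping world to head.
    sample_rate : nominal sampling rate in Hz, or ``None`` for a jittered
        (not yet resampled) stream.
    markers : list of ``(time_s, kind)`` pairs; ``kind`` is one of
        ``trial_start``, ``target_on``, ``response``.
    """

    timestamps: np.ndarray
    quat: np.ndarray
    sample_rate: float | None = None
    markers: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"timestamps must be strictly increasing; first violation at index {i + 1} "
                f"(t[{i}]={self.timestamps[i]:.6f}, t[{i + 1}]={self.timestamps[i + 1]:.6f})"
            )
        self.quat = _canonical_quats(self.quat)
        if len(self.quat) != len(self.timestamps):
            raise ValueError("timestamps and quaternions differ in length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        """Median sample interval in seconds."""
        return float(np.median(np.diff(self.timestamps)))

    @property
    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def is_uniform(self, tol: float = 1e-9) -> bool:
        """True if timestamps deviate from a uniform grid by less than *tol* s."""
        n = len(self.timestamps)
        if n < 2:
            return True
        grid = self.timestamps[0] + np.arange(n) * (
            (self.timestamps[-1] - self.timestamps[0]) / (n - 1)
        )
        return bool(np.max(np.abs(self.timestamps - grid)) < tol)

    @classmethod
    def from_euler(cls, timestamps, rx_deg, ry_deg, rz_deg, **kw) -> "OrientationTrace":
        """Build a trace from engine Euler angle columns (degrees)."""
        return cls(timestamps=np.asarray(timestamps, float),
                   quat=euler_to_quat(rx_deg, ry_deg, rz_deg), **kw)


@dataclass
class KinematicSeries:
    """Derived per-sample kinematic signals, length-aligned with the trace.

    ``vel_xyz`` columns are rotation rates about the X (pitch), Y (yaw) and
    Z (roll) axes.  ``gimbal_mask`` is True where |pitch| exceeds
    ``GIMBAL_PITCH_DEG`` and Euler rates are numerically unreliable.
    """

    timestamps: np.ndarray
    speed: np.ndarray          # deg/s, >= 0
    vel_xyz: np.ndarray        # (n, 3) deg/s
    accel: np.ndarray          # deg/s^2
    head_angle: np.ndarray     # deg, in [0, 180]
    rate: float                # Hz
    gimbal_mask: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def __len__(self) -> int:
        return len(self.timestamps)


def resample_uniform(trace: OrientationTrace, rate: float) -> OrientationTrace:
    """Resample a trace onto a uniform grid by spherical linear interpolation.

    The grid starts at the first timestamp, has spacing ``1/rate`` and spans
    the original time range.  Slerp is angle-linear between neighbouring
    samples, the right interpolant for orientations.  Markers pass through
    unchanged.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to resample")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    grid = np.minimum(grid, t1)  # guard fp overshoot at the end
    slerp = Slerp(trace.timestamps, trace.rotations)
    quat = slerp(grid).as_quat()
    return OrientationTrace(timestamps=grid, quat=quat, sample_rate=rate,
                            markers=list(trace.markers))


def _require_uniform(trace: OrientationTrace) -> float:
    if len(trace) < 2:
        raise ValueError("trace has fewer than 2 samples")
    if not trace.is_uniform(tol=1e-6):
        raise ValueError("trace is not uniformly sampled; call resample_uniform first")
    return float(trace.timestamps[1] - trace.timestamps[0])


def angular_speed(trace: OrientationTrace) -> np.ndarray:
    """Total angular speed in deg/s.

    Geodesic angle between consecutive quaternions divided by the sample
    interval.  The first sample copies the second so the series keeps the
    trace's length.
    """
    dt = _require_uniform(trace)
    rots = trace.rotations
    step = (rots[:-1].inv() * rots[1:]).magnitude()  # radians
    speed = np.empty(len(trace))
    speed[1:] = np.degrees(step) / dt
    speed[0] = speed[1]
    return speed


def per_axis_angular_velocity(
    trace: OrientationTrace, method: str = "euler"
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation rate about each axis, deg/s, plus a gimbal-quality mask.

    ``method='euler'`` (default) differentiates unwrapped engine Euler
    angles — this matches how engine rotation logs are usually analysed.
    ``method='body'`` differentiates the quaternion sequence to obtain
    body-frame angular velocity components instead.

    Returns ``(vel_xyz, gimbal_mask)`` where ``vel_xyz[:, 0]`` is the pitch
    rate (about X), column 1 the yaw rate (about Y), column 2 the roll rate
    (about Z).  ``gimbal_mask`` marks samples with |pitch| > 89° where
    Euler rates blow up; it is all-False for the body method.
    """
    dt = _require_uniform(trace)
    eul = quat_to_euler(trace.quat)  # columns rx, ry, rz
    gimbal = np.abs(eul[:, 0]) > GIMBAL_PITCH_DEG
    if method == "euler":
        unwrapped = np.unwrap(eul, period=360.0, axis=0)
        vel = np.gradient(unwrapped, dt, axis=0)
    elif method == "body":
        rots = trace.rotations
        # finite rotation increment expressed in the body frame
        delta = (rots[:-1].inv() * rots[1:]).as_rotvec(degrees=True) / dt
        vel = np.empty((len(trace), 3))
        vel[1:] = delta
        vel[0] = vel[1]
        gimbal = np.zeros(len(trace), dtype=bool)
    else:
        raise ValueError(f"unknown method {method!r}; use 'euler' or 'body'")
    return vel, gimbal


def head_angle_magnitude(trace: OrientationTrace) -> np.ndarray:
    """Angle (deg) between the head's forward vector and world forward."""
    fwd = trace.rotations.apply(FORWARD)
    cosang = np.clip(fwd @ FORWARD, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def angular_acceleration(speed: np.ndarray, dt: float) -> np.ndarray:
    """Derivative of the speed series: central differences, one-sided ends."""
    return np.gradient(np.asarray(speed, float), dt)


def savgol_smooth(series: np.ndarray, window_samples: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay least-squares polynomial smoothing, length preserved."""
    series = np.asarray(series, float)
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    if polyorder >= window_samples:
        raise ValueError("polyorder must be smaller than the window")
    if window_samples > len(series):
        raise ValueError(
            f"window ({window_samples}) longer than series ({len(series)})"
        )
    return savgol_filter(series, window_samples, polyorder)


def lowpass(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase low-pass filter (4th-order Butterworth, forward-backward).

    Forward-backward filtering cancels the phase delay, so zero crossings of
    the filtered signal are not time-shifted — essential for the zero-crossing
    segmentation in :func:`headmov.classifiers.dizco_classify`.
    """
    series = np.asarray(series, float)
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2} Hz)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(4, cutoff / (rate / 2), btype="low")
    return filtfilt(b, a, series)


def compute_kinematics(
    trace: OrientationTrace, vel_method: str = "euler"
) -> KinematicSeries:
    """Derive all kinematic signals a classifier might need from one trace."""
    dt = _require_uniform(trace)
    rate = 1.0 / dt
    speed = angular_speed(trace)
    vel, gimbal = per_axis_angular_velocity(trace, method=vel_method)
    accel = angular_acceleration(speed, dt)
    head_angle = head_angle_magnitude(trace)
    return KinematicSeries(
        timestamps=trace.timestamps,
        speed=speed,
        vel_xyz=vel,
        accel=accel,
        head_angle=head_angle,
        rate=rate,
        gimbal_mask=gimbal,
    )
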