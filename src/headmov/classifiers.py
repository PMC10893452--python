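"""Five head-movement classification algorithms.

Each algorithm maps kinematic signals to movement events or per-sample
moving/stationary labels:

* **BMAT** (baseline movement adaptive threshold) — an adaptation of the
  Engbert–Kliegl elliptic microsaccade threshold: per-axis velocity
  statistics from a stationary baseline window define a 3-D ellipsoid;
  samples outside it are "moving".
* **SVT** (smoothed velocity threshold) — Savitzky–Golay-smoothed angular
  speed; each speed peak above threshold seeds one event whose onset and
  offset sit at the nearest acceleration zero crossings.
* **Chen & Walton** — sliding-window majority rules on raw angular speed,
  adapted from a macaque head-movement criterion (100 ms onset window with
  a 72% above-threshold vote, 22 ms offset window).
* **DIZCO** (differential IMU-like zero-crossing observation) — low-passed
  horizontal/vertical angular acceleration segmented at zero crossings;
  each segment gets one of eight compass directions or rest.
* **Decision tree** — a supervised per-sample labeler (Gini splits, depth
  ≤ 10) on smoothed speed and head angle, trained on human-rater labels.

Events use half-open ``[onset, offset)`` time semantics on the uniform
sample grid; converting labels to events and back is the identity for
non-adjacent events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks
from sklearn.tree import DecisionTreeClassifier

from .kinematics import (
    KinematicSeries,
    OrientationTrace,
    lowpass,
    ms_to_samples,
    odd_window_samples,
    savgol_smooth,
)

__all__ = [
    "MovementEvent",
    "LabelSeries",
    "BmatConfig",
    "SvtConfig",
    "CwConfig",
    "DizcoConfig",
    "TreeConfig",
    "bmat_baseline",
    "bmat_classify",
    "svt_classify",
    "chen_walton_classify",
    "dizco_classify",
    "dizco_rest_threshold",
    "tree_features",
    "tree_train",
    "tree_classify",
    "tree_cv_accuracy",
    "prune_short_intervals",
    "labels_to_events",
    "events_to_labels",
    "annotate_events",
]

DIRECTIONS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")


@dataclass(frozen=True)
class MovementEvent:
    """One classified head movement, half-open in time.

    ``direction`` is a compass label (DIZCO) or ``None``; ``amplitude`` is
    the net angular displacement between onset and offset orientations in
    degrees; ``peak_velocity`` the maximum angular speed inside the event.
    """

    onset: float
    offset: float
    direction: str | None = None
    amplitude: float | None = None
    peak_velocity: float | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"offset ({self.offset}) must exceed onset ({self.onset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass
class LabelSeries:
    """Binary per-sample moving/stationary labels aligned to a trace.

    ``mask`` marks samples eligible for scoring (e.g. within-trial samples
    only); ``None`` means all samples count.
    """

    timestamps: np.ndarray
    moving: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.moving = np.asarray(self.moving, bool)
        if len(self.moving) != len(self.timestamps):
            raise ValueError("labels and timestamps differ in length")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if len(self.mask) != len(self.timestamps):
                raise ValueError("mask and timestamps differ in length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


# ---------------------------------------------------------------------------
# configurations

@dataclass
class BmatConfig:
    """Elliptic baseline threshold: label moving when the per-axis velocity
    lies outside the ellipsoid of ``n_sd`` baseline standard deviations."""

    n_sd: float = 2.0
    baseline_window_ms: float = 500.0
    use_median_estimator: bool = False   # Engbert–Kliegl robust scale instead of SD
    sigma_floor: float = 1e-6            # deg/s


@dataclass
class SvtConfig:
    speed_threshold: float = 10.0        # deg/s on smoothed speed
    savgol_window_ms: float = 122.0      # ~11 samples at 90 Hz
    savgol_polyorder: int = 3
    accel_zero_tol: float = 1.0          # deg/s^2 accepted as "zero" at plateaus


@dataclass
class CwConfig:
    speed_threshold: float = 6.0         # deg/s
    onset_window_ms: float = 100.0
    offset_window_ms: float = 22.0
    frac: float = 0.72
    max_consecutive_below: int = 3


@dataclass
class DizcoConfig:
    """``accel_magnitude_threshold`` (deg/s²) separates rest from moving
    segments; ``None`` selects the 95th percentile of rest-window |accel|
    (or of the whole series when no markers are available)."""

    accel_magnitude_threshold: float | None = None
    cutoff_hz: float = 10.0
    rest_percentile: float = 95.0


@dataclass
class TreeConfig:
    max_depth: int = 10
    criterion: str = "gini"
    min_interval_fraction: float = 0.5
    smooth_window_ms: float = 122.0
    smooth_polyorder: int = 3
    seed: int = 0


# ---------------------------------------------------------------------------
# BMAT

def bmat_baseline(
    kin: KinematicSeries,
    markers: list[tuple[float, str]],
    window_ms: float = 500.0,
) -> np.ndarray:
    """Collect per-axis velocity samples from the stationary fixation window
    (``window_ms`` after each ``trial_start`` marker), pooled over trials."""
    rows = []
    for t, kind in markers:
        if kind != "trial_start":
            continue
        sel = (kin.timestamps >= t) & (kin.timestamps < t + window_ms / 1000.0)
        rows.append(kin.vel_xyz[sel])
    if not rows:
        raise ValueError("no trial_start markers found for baseline extraction")
    return np.vstack(rows)


def bmat_classify(
    kin: KinematicSeries, baseline: np.ndarray, cfg: BmatConfig
) -> LabelSeries:
    """Label each sample by the elliptic baseline-velocity threshold.

    A sample is moving iff sum over axes of ((v - mu) / (n_sd * sigma))^2
    exceeds 1, with mu and sigma estimated on the baseline window.
    """
    baseline = np.atleast_2d(np.asarray(baseline, float))
    if baseline.shape[0] < 10 or baseline.shape[1] != 3:
        raise ValueError("baseline must provide >= 10 samples of 3-axis velocity")
    if cfg.use_median_estimator:
        center = np.median(baseline, axis=0)
        scale = np.sqrt(
            np.maximum(np.median(baseline**2, axis=0) - np.median(baseline, axis=0) ** 2, 0.0)
        )
    else:
        center = baseline.mean(axis=0)
        scale = baseline.std(axis=0)
    if np.all(scale < cfg.sigma_floor):
        raise ValueError(
            "baseline velocity variance is zero on all axes; the elliptic "
            "threshold is undefined (is the baseline window truly stationary noise?)"
        )
    scale = np.maximum(scale, cfg.sigma_floor)
    radius2 = np.sum(((kin.vel_xyz - center) / (cfg.n_sd * scale)) ** 2, axis=1)
    return LabelSeries(timestamps=kin.timestamps, moving=radius2 > 1.0)


# ---------------------------------------------------------------------------
# SVT

def svt_classify(kin: KinematicSeries, cfg: SvtConfig) -> list[MovementEvent]:
    """Smoothed-velocity-threshold events.

    Each local maximum of the smoothed speed above ``speed_threshold`` seeds
    one event.  From the peak the algorithm walks backward (forward) to the
    nearest sample where the angular acceleration — the derivative of the
    smoothed speed — crosses zero or is smaller than ``accel_zero_tol`` in
    magnitude; overlapping or touching events are merged.
    """
    window = odd_window_samples(cfg.savgol_window_ms, kin.rate)
    smoothed = savgol_smooth(kin.speed, window, cfg.savgol_polyorder)
    n = len(smoothed)
    peaks, _ = find_peaks(smoothed, height=cfg.speed_threshold)
    # The walk is two-phase so that near-zero-acceleration plateaus (a
    # pursuit movement's constant-speed stretch) do not stop it at the
    # peak: first leave the above-threshold region, then continue to the
    # nearest local minimum of the smoothed speed — the discrete
    # acceleration zero crossing (a flat stretch, |accel| below tolerance,
    # shows up as equal samples and also stops the walk).
    raw: list[tuple[int, int]] = []
    prev_offset = 0
    for p in peaks:
        i = p
        while i > prev_offset and smoothed[i] > cfg.speed_threshold:
            i -= 1
        while i > prev_offset and smoothed[i - 1] < smoothed[i]:
            i -= 1
        j = p
        while j < n - 1 and smoothed[j] > cfg.speed_threshold:
            j += 1
        while j < n - 1 and smoothed[j + 1] < smoothed[j]:
            j += 1
        if j > i:
            raw.append((i, j))
            prev_offset = j

    # merge strictly overlapping events (several peaks inside one hump);
    # events that merely touch at a shared valley sample stay distinct
    merged: list[list[int]] = []
    for onset, offset in raw:
        if merged and onset < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    t = kin.timestamps
    return [MovementEvent(onset=float(t[a]), offset=float(t[b])) for a, b in merged]


# ---------------------------------------------------------------------------
# Chen & Walton

def chen_walton_classify(
    speed: np.ndarray,
    cfg: CwConfig,
    rate: float,
    timestamps: np.ndarray | None = None,
) -> list[MovementEvent]:
    """Sliding-window onset/offset scan on raw angular speed.

    Onset: the first window position (100 ms, 9 samples at 90 Hz) where at
    least ceil(frac * window) samples are above threshold AND no run of
    ``max_consecutive_below`` below-threshold samples fits inside the
    window; the onset sample is the first above-threshold sample in that
    window.  Offset: symmetric with the 22 ms window and below-threshold
    counts; the offset sample is the first below-threshold sample in the
    qualifying window.  The scan alternates onset/offset until the series
    ends; an event still open at the end closes at the last sample.
    """
    speed = np.asarray(speed, float)
    n = len(speed)
    dt = 1.0 / rate
    if timestamps is None:
        timestamps = np.arange(n) * dt
    n_on = ms_to_samples(cfg.onset_window_ms, rate)
    n_off = ms_to_samples(cfg.offset_window_ms, rate)
    need_on = math.ceil(cfg.frac * n_on)
    need_off = math.ceil(cfg.frac * n_off)
    if n < n_on:
        return []

    above = speed > cfg.speed_threshold
    below = ~above
    cs_above = np.concatenate([[0], np.cumsum(above)])
    cs_below = np.concatenate([[0], np.cumsum(below)])

    # run[i] = length of the consecutive-below run ending at i
    run = np.zeros(n, dtype=int)
    acc = 0
    for i in range(n):
        acc = acc + 1 if below[i] else 0
        run[i] = acc
    k = cfg.max_consecutive_below
    # long_run[i]: a below-run of length >= k ends at i (hence occupies i-k+1..i)
    long_run = run >= k
    cs_long = np.concatenate([[0], np.cumsum(long_run)])

    def onset_window_ok(w: int) -> bool:
        if cs_above[w + n_on] - cs_above[w] < need_on:
            return False
        # a >= k run fits inside [w, w+n_on) iff some long-run end lies in
        # [w + k - 1, w + n_on)
        lo, hi = w + k - 1, w + n_on
        return (cs_long[hi] - cs_long[lo]) == 0

    def offset_window_ok(w: int) -> bool:
        return cs_below[w + n_off] - cs_below[w] >= need_off

    events: list[MovementEvent] = []
    pos = 0
    while pos <= n - n_on:
        w = pos
        while w <= n - n_on and not onset_window_ok(w):
            w += 1
        if w > n - n_on:
            break
        onset_idx = w + int(np.argmax(above[w : w + n_on]))
        w2 = onset_idx + 1
        offset_idx = None
        while w2 <= n - n_off:
            if offset_window_ok(w2):
                offset_idx = w2 + int(np.argmax(below[w2 : w2 + n_off]))
                break
            w2 += 1
        if offset_idx is None:
            events.append(
                MovementEvent(onset=float(timestamps[onset_idx]),
                              offset=float(timestamps[-1] + dt))
            )
            break
        events.append(
            MovementEvent(onset=float(timestamps[onset_idx]),
                          offset=float(timestamps[offset_idx]))
        )
        pos = offset_idx + 1
    return events


# ---------------------------------------------------------------------------
# DIZCO

def dizco_rest_threshold(
    accel_h: np.ndarray,
    accel_v: np.ndarray,
    timestamps: np.ndarray,
    markers: list[tuple[float, str]],
    window_ms: float = 500.0,
    percentile: float = 95.0,
) -> float:
    """Acceleration-magnitude threshold from marker-defined rest windows.

    Pools |filtered acceleration| on both axes over the ``window_ms`` after
    each ``trial_start`` marker (the instructed-stationary fixation period)
    and returns the requested percentile.  Falls back to the whole-series
    percentile when no markers are present.
    """
    sel = np.zeros(len(timestamps), dtype=bool)
    for t, kind in markers or []:
        if kind == "trial_start":
            sel |= (timestamps >= t) & (timestamps < t + window_ms / 1000.0)
    if not sel.any():
        sel[:] = True
    pooled = np.concatenate([np.abs(accel_h[sel]), np.abs(accel_v[sel])])
    return float(np.percentile(pooled, percentile))


def _segment_boundaries(*series: np.ndarray) -> np.ndarray:
    """Indices where the sign of any series changes (including through 0)."""
    n = len(series[0])
    change = np.zeros(n, dtype=bool)
    for s in series:
        sign = np.sign(s)
        change[1:] |= sign[1:] != sign[:-1]
    return np.concatenate([[0], np.flatnonzero(change), [n]])


_DIR_MAP = {
    (1, 0): "E", (-1, 0): "W", (0, 1): "N", (0, -1): "S",
    (1, 1): "NE", (-1, 1): "NW", (1, -1): "SE", (-1, -1): "SW",
}


def dizco_classify(
    kin: KinematicSeries,
    cfg: DizcoConfig,
    markers: list[tuple[float, str]] | None = None,
) -> list[MovementEvent]:
    """Direction-coding zero-crossing segmentation.

    Horizontal (yaw-rate derivative) and vertical (pitch-rate derivative)
    angular accelerations are low-passed at ``cutoff_hz``; boundaries fall
    at zero crossings of either filtered series.  Each segment gets a
    per-axis state +, - or 0 (0 when the segment's mean |acceleration| on
    that axis is below threshold); the state pair maps to one of eight
    compass directions, or rest when both axes are 0.  Consecutive
    segments with the same direction merge into one event.
    """
    dt = kin.dt
    # horizontal: yaw rate (positive = rightward); vertical: negated pitch
    # rate so positive means upward
    accel_h = lowpass(np.gradient(kin.vel_xyz[:, 1], dt), cfg.cutoff_hz, kin.rate)
    accel_v = lowpass(np.gradient(-kin.vel_xyz[:, 0], dt), cfg.cutoff_hz, kin.rate)
    thr = cfg.accel_magnitude_threshold
    if thr is None:
        thr = dizco_rest_threshold(
            accel_h, accel_v, kin.timestamps, markers or [], percentile=cfg.rest_percentile
        )

    bounds = _segment_boundaries(accel_h, accel_v)
    t = kin.timestamps
    end_time = float(t[-1] + dt)

    segments: list[tuple[int, int, str | None]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        states = []
        for series in (accel_h, accel_v):
            seg = series[a:b]
            if np.mean(np.abs(seg)) < thr:
                states.append(0)
            else:
                states.append(1 if np.mean(seg) >= 0 else -1)
        direction = _DIR_MAP.get(tuple(states))  # None => rest
        segments.append((a, b, direction))

    events: list[MovementEvent] = []
    cur: list | None = None
    for a, b, direction in segments:
        if direction is None:
            if cur is not None:
                events.append(MovementEvent(
                    onset=float(t[cur[0]]),
                    offset=float(t[cur[1]]) if cur[1] < len(t) else end_time,
                    direction=cur[2]))
                cur = None
            continue
        if cur is not None and cur[2] == direction and a == cur[1]:
            cur[1] = b
        else:
            if cur is not None:
                events.append(MovementEvent(
                    onset=float(t[cur[0]]),
                    offset=float(t[cur[1]]) if cur[1] < len(t) else end_time,
                    direction=cur[2]))
            cur = [a, b, direction]
    if cur is not None:
        events.append(MovementEvent(
            onset=float(t[cur[0]]),
            offset=float(t[cur[1]]) if cur[1] < len(t) else end_time,
            direction=cur[2]))
    return events


# ---------------------------------------------------------------------------
# decision tree

def tree_features(kin: KinematicSeries, cfg: TreeConfig) -> np.ndarray:
    """Per-sample feature matrix: smoothed angular speed and head angle."""
    window = odd_window_samples(cfg.smooth_window_ms, kin.rate)
    smoothed = savgol_smooth(kin.speed, window, cfg.smooth_polyorder)
    return np.column_stack([smoothed, kin.head_angle])


def tree_train(
    features: np.ndarray, labels: LabelSeries, cfg: TreeConfig | None = None
) -> DecisionTreeClassifier:
    """Fit the per-sample decision tree (Gini impurity, depth <= max_depth)."""
    cfg = cfg or TreeConfig()
    features = np.asarray(features, float)
    y = np.asarray(labels.moving, bool)
    if len(features) != len(y):
        raise ValueError("features and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    model = DecisionTreeClassifier(
        criterion=cfg.criterion, max_depth=cfg.max_depth, random_state=cfg.seed
    )
    model.fit(features, y)
    return model


def tree_classify(
    model: DecisionTreeClassifier, features: np.ndarray, timestamps: np.ndarray
) -> LabelSeries:
    """Per-sample moving/stationary labels from a trained tree."""
    features = np.asarray(features, float)
    if features.ndim != 2 or features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature matrix has {features.shape[-1] if features.ndim == 2 else '?'} "
            f"columns, model expects {model.n_features_in_}"
        )
    return LabelSeries(timestamps=np.asarray(timestamps, float),
                       moving=model.predict(features).astype(bool))


def tree_cv_accuracy(
    features: np.ndarray,
    labels: LabelSeries,
    cfg: TreeConfig | None = None,
    n_folds: int = 5,
) -> float:
    """Cross-validated per-sample accuracy of the decision tree.

    Folds are contiguous time blocks, not shuffled samples: adjacent
    samples are strongly autocorrelated, and shuffling would leak
    held-out information into training.  Folds whose training split is
    single-class are skipped.
    """
    cfg = cfg or TreeConfig()
    features = np.asarray(features, float)
    y = np.asarray(labels.moving, bool)
    n = len(y)
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    edges = np.linspace(0, n, n_folds + 1, dtype=int)
    accs = []
    for a, b in zip(edges[:-1], edges[1:]):
        test = np.zeros(n, dtype=bool)
        test[a:b] = True
        y_tr = y[~test]
        if y_tr.all() or not y_tr.any():
            continue
        model = DecisionTreeClassifier(
            criterion=cfg.criterion, max_depth=cfg.max_depth, random_state=cfg.seed
        ).fit(features[~test], y_tr)
        accs.append(float(np.mean(model.predict(features[test]) == y[test])))
    if not accs:
        raise ValueError("all folds degenerate (single-class training labels)")
    return float(np.mean(accs))


def prune_short_intervals(
    events: list[MovementEvent],
    reference_mean_duration: float,
    fraction: float = 0.5,
) -> list[MovementEvent]:
    """Drop events strictly shorter than ``fraction`` of a reference mean
    duration (the mean rater-coded interval length), preserving order."""
    if reference_mean_duration <= 0:
        raise ValueError("reference mean duration must be positive")
    cutoff = fraction * reference_mean_duration
    return [e for e in events if not e.duration < cutoff]


# ---------------------------------------------------------------------------
# label/event conversion and annotation

def labels_to_events(labels: LabelSeries) -> list[MovementEvent]:
    """Maximal runs of moving samples become events [t_first, t_last + dt)."""
    moving = labels.moving
    if not moving.any():
        return []
    dt = labels.dt if len(labels) > 1 else 0.0
    padded = np.concatenate([[False], moving, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    t = labels.timestamps
    return [
        MovementEvent(onset=float(t[a]), offset=float(t[b] + dt))
        for a, b in zip(starts, ends)
    ]


def events_to_labels(
    events: list[MovementEvent],
    timestamps: np.ndarray,
    mask: np.ndarray | None = None,
) -> LabelSeries:
    """Sample labels from events: moving iff onset <= t < offset for some event."""
    timestamps = np.asarray(timestamps, float)
    moving = np.zeros(len(timestamps), dtype=bool)
    eps = 1e-9  # absorb float rounding of grid-aligned event boundaries
    for e in events:
        moving |= (timestamps >= e.onset - eps) & (timestamps < e.offset - eps)
    return LabelSeries(timestamps=timestamps, moving=moving, mask=mask)


def annotate_events(
    events: list[MovementEvent],
    trace: OrientationTrace,
    kin: KinematicSeries,
) -> list[MovementEvent]:
    """Fill in amplitude and peak velocity for each event.

    Peak velocity is the maximum angular speed inside [onset, offset);
    amplitude is the net angular displacement — the geodesic angle between
    the orientations at onset and offset (a movement returning to its start
    has amplitude ~0 even though its path length is positive).
    """
    t = trace.timestamps
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    rots = trace.rotations
    out: list[MovementEvent] = []
    for e in events:
        if e.onset < t[0] - dt / 2 or e.offset > t[-1] + 1.5 * dt:
            raise ValueError(f"event [{e.onset:.4f}, {e.offset:.4f}) outside trace span")
        i0 = int(np.clip(np.searchsorted(t, e.onset - dt / 2), 0, len(t) - 1))
        i1 = int(np.clip(np.searchsorted(t, e.offset - dt / 2), i0 + 1, len(t)) - 1)
        sel = kin.speed[i0 : i1 + 1]
        peak = float(np.max(sel)) if len(sel) else 0.0
        amp = float(np.degrees((rots[i0].inv() * rots[i1]).magnitude()))
        out.append(replace(e, amplitude=amp, peak_velocity=peak))
    return out
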