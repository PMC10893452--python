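"""Agreement and bias metrics between two labelers, and the main sequence.

Sample-by-sample agreement between two moving/stationary labelings is
scored with Cohen's kappa, K = (Po - Pe) / (1 - Pe), where Po is the
observed agreement and Pe the agreement expected by chance from the
marginal label frequencies.  Event-level comparison pairs a ground-truth
event with an algorithm event when the truth event's midpoint falls inside
the algorithm's window, keeping only one-to-one pairs; onset/offset/
duration/amplitude biases are then truth-minus-prediction means over
pairs.  The main sequence is the classic amplitude vs. peak-velocity
correlation borrowed from saccade research.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classifiers import LabelSeries, MovementEvent

__all__ = [
    "AgreementReport",
    "BiasReport",
    "cohens_kappa",
    "merge_raters",
    "match_events",
    "bias_metrics",
    "main_sequence",
]


@dataclass(frozen=True)
class AgreementReport:
    """Cohen's kappa with its observed/chance agreement components.

    ``kappa`` is NaN when Pe = 1 (both labelings constant and identical),
    where chance-corrected agreement is undefined.
    """

    kappa: float
    po: float
    pe: float
    n_samples: int


@dataclass(frozen=True)
class BiasReport:
    """Truth-minus-prediction biases over matched event pairs.

    Onset/offset/duration biases are in milliseconds, amplitude bias in
    degrees; each comes with its across-pair standard error.  All fields
    are NaN when ``n_pairs`` is 0 (SEs also when ``n_pairs`` is 1).
    """

    onset_bias_ms: float
    offset_bias_ms: float
    duration_bias_ms: float
    amplitude_bias_deg: float
    onset_se_ms: float
    offset_se_ms: float
    duration_se_ms: float
    amplitude_se_deg: float
    n_pairs: int


def _scoring_mask(a: LabelSeries, b: LabelSeries) -> np.ndarray:
    mask = np.ones(len(a), dtype=bool)
    if a.mask is not None:
        mask &= a.mask
    if b.mask is not None:
        mask &= b.mask
    return mask


def cohens_kappa(a: LabelSeries, b: LabelSeries) -> AgreementReport:
    """Two-category Cohen's kappa over the samples both masks admit.

    Po is the fraction of scored samples with identical labels; Pe is the
    chance agreement from the product of the two labelers' marginal
    moving/stationary rates.
    """
    if len(a) != len(b):
        raise ValueError(f"label series differ in length ({len(a)} vs {len(b)})")
    mask = _scoring_mask(a, b)
    x = a.moving[mask]
    y = b.moving[mask]
    n = len(x)
    if n == 0:
        return AgreementReport(kappa=math.nan, po=math.nan, pe=math.nan, n_samples=0)
    po = float(np.mean(x == y))
    px, py = float(np.mean(x)), float(np.mean(y))
    pe = px * py + (1.0 - px) * (1.0 - py)
    if pe >= 1.0 - 1e-15:
        kappa = math.nan  # both constant with equal marginals: undefined
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementReport(kappa=kappa, po=po, pe=pe, n_samples=n)


def merge_raters(raters: list[LabelSeries]) -> LabelSeries:
    """Per-sample logical OR of several raters — the ground-truth union.

    A sample counts as moving when any rater marked it moving.  Masks are
    intersected.
    """
    if not raters:
        raise ValueError("need at least one rater")
    first = raters[0]
    moving = first.moving.copy()
    mask = None if first.mask is None else first.mask.copy()
    for r in raters[1:]:
        if len(r) != len(first):
            raise ValueError("rater label series differ in length")
        moving |= r.moving
        if r.mask is not None:
            mask = r.mask.copy() if mask is None else (mask & r.mask)
    return LabelSeries(timestamps=first.timestamps.copy(), moving=moving, mask=mask)


def match_events(
    truth: list[MovementEvent], pred: list[MovementEvent]
) -> list[tuple[MovementEvent, MovementEvent]]:
    """One-to-one midpoint matching of ground-truth and predicted events.

    A truth event pairs with the predicted event whose half-open window
    [onset, offset) contains the truth midpoint.  Any predicted event that
    contains two or more truth midpoints has no one-to-one pairing and is
    removed together with all its candidate pairs; unmatched events on
    either side are simply excluded.
    """
    for events, name in ((truth, "truth"), (pred, "pred")):
        for e1, e2 in zip(events, events[1:]):
            if e2.onset < e1.offset:
                raise ValueError(f"{name} events must be sorted and disjoint")
    candidates: dict[int, list[tuple[MovementEvent, MovementEvent]]] = {}
    for t in truth:
        mid = t.midpoint
        for j, p in enumerate(pred):
            if p.onset <= mid < p.offset:
                candidates.setdefault(j, []).append((t, p))
                break  # disjoint pred events: at most one container
    return [pairs[0] for j, pairs in sorted(candidates.items()) if len(pairs) == 1]


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else math.nan
    return mean, se


def bias_metrics(
    pairs: list[tuple[MovementEvent, MovementEvent]],
) -> BiasReport:
    """Truth-minus-prediction bias in onset, offset, duration and amplitude.

    Duration bias equals offset bias minus onset bias by construction.
    Amplitude bias requires both events of a pair to carry annotations
    (see :func:`headmov.classifiers.annotate_events`); pairs without them
    are skipped for that metric only.
    """
    if not pairs:
        nan = math.nan
        return BiasReport(nan, nan, nan, nan, nan, nan, nan, nan, n_pairs=0)
    onset = np.array([(t.onset - p.onset) * 1000.0 for t, p in pairs])
    offset = np.array([(t.offset - p.offset) * 1000.0 for t, p in pairs])
    duration = offset - onset
    amp = np.array(
        [
            t.amplitude - p.amplitude
            for t, p in pairs
            if t.amplitude is not None and p.amplitude is not None
        ]
    )
    on_m, on_se = _mean_se(onset)
    off_m, off_se = _mean_se(offset)
    dur_m, dur_se = _mean_se(duration)
    amp_m, amp_se = _mean_se(amp) if len(amp) else (math.nan, math.nan)
    return BiasReport(
        onset_bias_ms=on_m, offset_bias_ms=off_m, duration_bias_ms=dur_m,
        amplitude_bias_deg=amp_m, onset_se_ms=on_se, offset_se_ms=off_se,
        duration_se_ms=dur_se, amplitude_se_deg=amp_se, n_pairs=len(pairs),
    )


def main_sequence(events: list[MovementEvent]) -> tuple[float, float, int]:
    """Amplitude vs. peak-velocity Pearson correlation (the main sequence).

    Returns ``(r, p_value, n)`` over events carrying both annotations.
    Raises if fewer than 3 annotated events or either variable has zero
    variance (correlation undefined).
    """
    pts = [
        (e.amplitude, e.peak_velocity)
        for e in events
        if e.amplitude is not None and e.peak_velocity is not None
        and math.isfinite(e.amplitude) and math.isfinite(e.peak_velocity)
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 annotated events for the main sequence")
    amp, vel = map(np.asarray, zip(*pts))
    if np.std(amp) == 0 or np.std(vel) == 0:
        raise ValueError("zero variance in amplitude or peak velocity; r undefined")
    r, p = stats.pearsonr(amp, vel)
    return float(r), float(p), len(pts)
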