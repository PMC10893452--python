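"""Threshold selection by grid search with leave-one-subject-out validation.

For each candidate threshold, the classifier runs on every subject's trace
and its labels are scored against each human rater with Cohen's kappa; the
rater kappas are averaged within subject, then across subjects.  Leave-one-
out holds one subject out, picks the threshold maximising the mean kappa of
the rest (ties broken toward the smallest threshold), and evaluates it on
the held-out subject.  The mean and standard error of the held-out kappas
and of the selected thresholds are the reported fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classifiers import (
    BmatConfig,
    CwConfig,
    LabelSeries,
    SvtConfig,
    bmat_baseline,
    bmat_classify,
    chen_walton_classify,
    events_to_labels,
    svt_classify,
)
from .evaluation import cohens_kappa
from .kinematics import KinematicSeries, OrientationTrace

__all__ = [
    "SubjectData",
    "FitResult",
    "Labeler",
    "grid_search",
    "leave_one_out",
    "svt_labeler",
    "bmat_labeler",
    "chen_walton_labeler",
    "default_grid",
]

#: A labeler maps (subject, threshold) to a per-sample label series.
Labeler = Callable[["SubjectData", float], LabelSeries]

#: Default threshold grids per thresholding algorithm.  BMAT's n-SD grid
#: spans 0.2-4.0 in steps of 0.1; the speed grids for SVT and Chen & Walton
#: cover the plausible deg/s range for head movements.
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "bmat": np.round(np.arange(0.2, 4.0 + 1e-9, 0.1), 10),
    "svt": np.round(np.arange(2.0, 40.0 + 1e-9, 0.5), 10),
    "cw": np.round(np.arange(1.0, 15.0 + 1e-9, 0.25), 10),
}


def default_grid(algorithm: str) -> np.ndarray:
    try:
        return DEFAULT_GRIDS[algorithm].copy()
    except KeyError:
        raise ValueError(
            f"no default grid for {algorithm!r}; choose from {sorted(DEFAULT_GRIDS)}"
        ) from None


@dataclass
class SubjectData:
    """One subject's recording: trace, derived kinematics, rater labels.

    ``mask`` restricts kappa scoring to within-trial samples; ``condition``
    tags the trial type (instant/pursuit) so fits can be run per condition.
    """

    subject: str
    trace: OrientationTrace
    kin: KinematicSeries
    rater_labels: list[LabelSeries]
    mask: np.ndarray | None = None
    condition: str | None = None


@dataclass
class FitResult:
    """Leave-one-out output: per-fold selections plus their aggregates."""

    per_fold: list[tuple[str, float, float]]  # (held-out subject, threshold, kappa)
    mean_kappa: float
    se_kappa: float
    mean_threshold: float
    se_threshold: float
    grid: np.ndarray = field(default_factory=lambda: np.array([]))


def _subject_kappa(subject: SubjectData, labels: LabelSeries) -> float:
    """Mean kappa of one labeling against all of the subject's raters."""
    if not subject.rater_labels:
        raise ValueError(f"subject {subject.subject} has no rater labels")
    labels = LabelSeries(labels.timestamps, labels.moving, mask=subject.mask)
    ks = []
    for rater in subject.rater_labels:
        rater = LabelSeries(rater.timestamps, rater.moving, mask=subject.mask)
        ks.append(cohens_kappa(labels, rater).kappa)
    return float(np.mean(ks))


def kappa_matrix(
    subjects: Sequence[SubjectData], labeler: Labeler, grid: Sequence[float]
) -> np.ndarray:
    """(n_subjects, n_thresholds) within-subject mean kappas.

    A classifier failure on one (subject, threshold) cell becomes NaN with
    a warning and is excluded from across-subject averages.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    out = np.full((len(subjects), len(grid)), np.nan)
    for i, subj in enumerate(subjects):
        for j, thr in enumerate(grid):
            try:
                labels = labeler(subj, float(thr))
                out[i, j] = _subject_kappa(subj, labels)
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                warnings.warn(
                    f"classifier failed for subject {subj.subject} at threshold "
                    f"{thr}: {exc}",
                    stacklevel=2,
                )
    return out


def grid_search(
    subjects: Sequence[SubjectData], labeler: Labeler, grid: Sequence[float]
) -> dict[float, float]:
    """Map each threshold to its across-subject mean kappa."""
    grid = np.asarray(grid, float)
    mat = kappa_matrix(subjects, labeler, grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(mat, axis=0)
    return {float(t): float(k) for t, k in zip(grid, means)}


def _argmax_smallest(grid: np.ndarray, means: np.ndarray) -> float:
    finite = np.isfinite(means)
    if not finite.any():
        raise ValueError("kappa undefined at every threshold")
    best = np.nanmax(means)
    idx = int(np.flatnonzero(finite & (means >= best - 1e-12))[0])
    return float(grid[idx])


def leave_one_out(
    subjects: Sequence[SubjectData], labeler: Labeler, grid: Sequence[float]
) -> FitResult:
    """Leave-one-subject-out threshold selection.

    For each held-out subject the threshold maximising the mean kappa over
    the remaining subjects is selected (ties to the smallest threshold) and
    scored on the held-out subject.  Deterministic given data and grid.
    """
    if len(subjects) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    grid = np.asarray(grid, float)
    mat = kappa_matrix(subjects, labeler, grid)
    per_fold: list[tuple[str, float, float]] = []
    for i, subj in enumerate(subjects):
        rest = np.delete(mat, i, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(rest, axis=0)
        thr = _argmax_smallest(grid, means)
        j = int(np.flatnonzero(grid == thr)[0])
        per_fold.append((subj.subject, thr, float(mat[i, j])))
    kappas = np.array([k for _, _, k in per_fold])
    thresholds = np.array([t for _, t, _ in per_fold])
    n = len(per_fold)

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else math.nan

    return FitResult(
        per_fold=per_fold,
        mean_kappa=float(np.mean(kappas)),
        se_kappa=se(kappas),
        mean_threshold=float(np.mean(thresholds)),
        se_threshold=se(thresholds),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# ready-made labelers for the three thresholding algorithms

def svt_labeler(base: SvtConfig | None = None) -> Labeler:
    """SVT labeler: threshold is the smoothed-speed threshold in deg/s."""
    base = base or SvtConfig()

    def run(subject: SubjectData, threshold: float) -> LabelSeries:
        cfg = SvtConfig(
            speed_threshold=threshold,
            savgol_window_ms=base.savgol_window_ms,
            savgol_polyorder=base.savgol_polyorder,
            accel_zero_tol=base.accel_zero_tol,
        )
        events = svt_classify(subject.kin, cfg)
        return events_to_labels(events, subject.kin.timestamps)

    return run


def bmat_labeler(base: BmatConfig | None = None) -> Labeler:
    """BMAT labeler: threshold is n_sd, the ellipse radius in baseline SDs."""
    base = base or BmatConfig()

    def run(subject: SubjectData, threshold: float) -> LabelSeries:
        cfg = BmatConfig(
            n_sd=threshold,
            baseline_window_ms=base.baseline_window_ms,
            use_median_estimator=base.use_median_estimator,
            sigma_floor=base.sigma_floor,
        )
        baseline = bmat_baseline(subject.kin, subject.trace.markers,
                                 window_ms=cfg.baseline_window_ms)
        return bmat_classify(subject.kin, baseline, cfg)

    return run


def chen_walton_labeler(base: CwConfig | None = None) -> Labeler:
    """Chen & Walton labeler: threshold is the speed threshold in deg/s."""
    base = base or CwConfig()

    def run(subject: SubjectData, threshold: float) -> LabelSeries:
        cfg = CwConfig(
            speed_threshold=threshold,
            onset_window_ms=base.onset_window_ms,
            offset_window_ms=base.offset_window_ms,
            frac=base.frac,
            max_consecutive_below=base.max_consecutive_below,
        )
        events = chen_walton_classify(
            subject.kin.speed, cfg, subject.kin.rate, subject.kin.timestamps
        )
        return events_to_labels(events, subject.kin.timestamps)

    return run
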