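"""Apply a trained inverse model to multi-cohort scans.

The empirical-style pipeline per scan is: normalize the amplitude to 1
(one scalar per scan, preserving relative regional amplitudes), cut the
series into non-overlapping windows of the model's window length, average
the windows of the same subject element-wise, then predict the bifurcation
vector from the averaged window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regression import TrainedRegressor, predict_bifurcation
from .sim import BoldTimeSeries
from .synthdata import PseudoCohortSet

__all__ = [
    "CohortPredictions",
    "normalize_amplitude",
    "window_series",
    "average_subject_windows",
    "infer_cohorts",
]


@dataclass(frozen=True)
class CohortPredictions:
    """Inferred bifurcation parameters: cohorts x subjects x nodes."""

    a_hat: np.ndarray
    cohort_labels: tuple
    subject_ids: tuple

    def __post_init__(self):
        a = np.asarray(self.a_hat, dtype=float)
        if a.ndim != 3:
            raise ValueError("a_hat must be C x S x N")
        if not np.all(np.isfinite(a)):
            raise ValueError("a_hat must be finite")
        if len(self.cohort_labels) != a.shape[0]:
            raise ValueError("cohort_labels length must equal C")
        if len(self.subject_ids) != a.shape[1]:
            raise ValueError("subject_ids length must equal S")
        object.__setattr__(self, "a_hat", a)


def normalize_amplitude(ts: BoldTimeSeries) -> BoldTimeSeries:
    """Scale the whole scan so the maximum absolute value equals 1."""
    peak = np.abs(ts.values).max()
    if peak == 0:
        raise ValueError("all-zero scan cannot be normalized")
    return BoldTimeSeries(ts.values / peak, ts.tr)


def window_series(ts: BoldTimeSeries, W: int) -> np.ndarray:
    """Cut into K = floor(T / W) non-overlapping windows; remainder dropped."""
    if W < 1:
        raise ValueError("W must be positive")
    T = ts.n_samples
    if T < W:
        raise ValueError(f"scan shorter than one window (T={T} < W={W})")
    K = T // W
    return ts.values[:, : K * W].reshape(ts.n_regions, K, W).transpose(1, 0, 2)


def average_subject_windows(windows: np.ndarray) -> np.ndarray:
    """Element-wise mean over a subject's K windows, giving one N x W matrix."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[0] < 1:
        raise ValueError("need a nonempty K x N x W window stack")
    return windows.mean(axis=0)


def infer_cohorts(
    model: TrainedRegressor,
    cohorts: PseudoCohortSet | list,
    W: int | None = None,
    cohort_labels: list[str] | None = None,
    average_windows: bool = True,
) -> CohortPredictions:
    """Run the full inference pipeline over every cohort and subject.

    ``cohorts`` is a :class:`PseudoCohortSet` or a list (per cohort) of lists
    of :class:`BoldTimeSeries`.  ``average_windows=False`` switches to
    predict-per-window-then-average, exposed for sensitivity checks only.
    """
    if isinstance(cohorts, PseudoCohortSet):
        scan_lists = cohorts.scans
        labels = list(cohorts.cohort_labels)
    else:
        scan_lists = cohorts
        labels = cohort_labels or [f"cohort{c}" for c in range(len(cohorts))]
    if W is None:
        W = model.window_length
    n_subjects = {len(scans) for scans in scan_lists}
    if len(n_subjects) != 1:
        raise ValueError("every cohort must contain the same subjects")
    S = n_subjects.pop()
    averaged = []
    for c, scans in enumerate(scan_lists):
        for s, ts in enumerate(scans):
            if ts.n_regions != model.n_regions:
                raise ValueError(
                    f"cohort {labels[c]} subject {s}: {ts.n_regions} regions, "
                    f"model expects {model.n_regions}"
                )
            try:
                wins = window_series(normalize_amplitude(ts), W)
            except ValueError as err:
                raise ValueError(f"cohort {labels[c]} subject {s}: {err}") from err
            averaged.append((c, s, wins))
    C = len(scan_lists)
    N = model.n_regions
    a_hat = np.empty((C, S, N))
    if average_windows:
        stack = np.stack([average_subject_windows(w) for _, _, w in averaged])
        preds = predict_bifurcation(model, stack)
        for (c, s, _), p in zip(averaged, preds):
            a_hat[c, s] = p
    else:
        for c, s, wins in averaged:
            a_hat[c, s] = predict_bifurcation(model, wins).mean(axis=0)
    return CohortPredictions(a_hat, tuple(labels), tuple(range(S)))
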