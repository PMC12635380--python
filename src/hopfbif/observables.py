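"""Signal observables for BOLD time series.

Static functional connectivity (Pearson), instantaneous phase-coherence
frames from the Hilbert analytic signal, phase functional connectivity
dynamics (FCD), the two-sample Kolmogorov-Smirnov distance between pooled
FCD distributions, and intrinsic-frequency estimation from narrowband
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .sim import BoldTimeSeries

__all__ = [
    "BandpassSpec",
    "FCDMatrix",
    "bandpass_filter",
    "static_fc",
    "phase_coherence_frames",
    "fcd_matrix",
    "pool_fcd_values",
    "ks_distance",
    "estimate_frequencies",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass specification (Hz).

    Defaults follow standard resting-state fMRI practice: a second-order
    0.008-0.08 Hz band that removes slow scanner drift and high-frequency
    artifacts.  Applied forward-backward (zero phase), which squares the
    magnitude response.
    """

    low: float = 0.008
    high: float = 0.08
    order: int = 2

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class FCDMatrix:
    """Similarity between phase-coherence frames at every pair of times.

    ``values[s, t]`` is the cosine similarity between the strict upper
    triangles of the coherence frames at times ``s`` and ``t``; the matrix is
    symmetric with unit diagonal and entries in [-1, 1].
    """

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.frame_times, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or t.shape != (v.shape[0],):
            raise ValueError("values must be T' x T' with matching frame_times")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "frame_times", t)

    def upper_values(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector (the FCD sample)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def bandpass_filter(ts: BoldTimeSeries, spec: BandpassSpec | None = None) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass, applied per node."""
    if spec is None:
        spec = BandpassSpec()
    nyq = 0.5 / ts.tr
    if spec.high >= nyq:
        raise ValueError(f"high cutoff {spec.high} Hz is at or above Nyquist {nyq:.4f} Hz")
    if ts.n_samples < 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = sps.butter(spec.order, [spec.low, spec.high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    return BoldTimeSeries(sps.sosfiltfilt(sos, ts.values, axis=1), ts.tr)


def static_fc(ts: BoldTimeSeries) -> np.ndarray:
    """Pearson correlation between every pair of node signals (N x N)."""
    var = ts.values.var(axis=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {dead.tolist()}")
    fc = np.corrcoef(ts.values)
    np.fill_diagonal(fc, 1.0)
    return fc


def _phases(ts: BoldTimeSeries) -> np.ndarray:
    if ts.n_samples < 4:
        raise ValueError("need at least 4 samples for the Hilbert transform")
    return np.angle(sps.hilbert(ts.values, axis=1))


def phase_coherence_frames(ts: BoldTimeSeries) -> np.ndarray:
    """Instantaneous phase-coherence matrices, one N x N frame per sample.

    Frame ``t`` has entries ``cos(phi_i(t) - phi_j(t))`` with phases taken
    from the Hilbert analytic signal; the input should already be band-pass
    filtered so the instantaneous phase is meaningful.  Returns an array of
    shape (T, N, N); each frame is symmetric with unit diagonal.
    """
    phi = _phases(ts)  # (N, T)
    diff = phi[:, None, :] - phi[None, :, :]  # (N, N, T)
    return np.cos(diff).transpose(2, 0, 1)


def fcd_matrix(ts: BoldTimeSeries, trim_frames: int = 0) -> FCDMatrix:
    """Phase FCD: cosine similarity between coherence frames over time.

    ``trim_frames`` drops that many frames at each end before comparing,
    which removes Hilbert edge transients if desired (none dropped by
    default).
    """
    frames = phase_coherence_frames(ts)
    if trim_frames:
        if 2 * trim_frames >= frames.shape[0]:
            raise ValueError("trim_frames removes every frame")
        frames = frames[trim_frames:-trim_frames]
    T, N, _ = frames.shape
    iu = np.triu_indices(N, k=1)
    vecs = frames[:, iu[0], iu[1]]  # (T, N(N-1)/2)
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate frame with zero-norm upper triangle")
    unit = vecs / norms[:, None]
    values = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    times = (np.arange(T) + trim_frames) * ts.tr
    return FCDMatrix(values, times)


def pool_fcd_values(fcds) -> np.ndarray:
    """Pool strict-upper-triangle FCD entries from one or many FCD matrices."""
    if isinstance(fcds, FCDMatrix):
        return fcds.upper_values()
    if isinstance(fcds, (list, tuple)) and any(isinstance(f, FCDMatrix) for f in fcds):
        return np.concatenate([pool_fcd_values(f) for f in fcds])
    return np.ravel(np.asarray(fcds, dtype=float))


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic ``sup |ECDF_a - ECDF_b|``.

    Accepts FCD matrices (pooled over their strict upper triangles), lists of
    them (pooled across subjects) or plain value vectors.
    """
    a = pool_fcd_values(sample_a)
    b = pool_fcd_values(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def estimate_frequencies(
    ts_list: list[BoldTimeSeries],
    spec: BandpassSpec | None = None,
) -> np.ndarray:
    """Per-node intrinsic angular frequencies from narrowband spectra.

    For each subject and node, the peak frequency of a Welch-averaged
    periodogram restricted to the pass band is located; peaks are then
    averaged across subjects and converted to rad/s (``omega = 2 pi f``).
    """
    if spec is None:
        spec = BandpassSpec()
    if not ts_list:
        raise ValueError("need at least one time series")
    peaks = []
    for ts in ts_list:
        nyq = 0.5 / ts.tr
        if spec.high >= nyq:
            raise ValueError("band exceeds the Nyquist frequency for this tr")
        nperseg = min(ts.n_samples, 256)
        freqs, pxx = sps.welch(ts.values, fs=1.0 / ts.tr, nperseg=nperseg, noverlap=nperseg // 2, axis=1)
        band = (freqs >= spec.low) & (freqs <= spec.high)
        if not np.any(band):
            raise ValueError("no spectral bins inside the requested band")
        fb = freqs[band]
        peaks.append(fb[np.argmax(pxx[:, band], axis=1)])
    return 2.0 * np.pi * np.mean(peaks, axis=0)
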