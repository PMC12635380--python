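"""Synthetic data generation for training and validating inverse models.

Training windows are produced by simulating the Hopf network with node
parameters drawn from the training priors: ``a_j ~ U(-1, 1)`` and
``omega_j ~ U(0.05, 0.25)`` rad/s, initial states uniform in [-1, 1].  Each
sample is integrated for ``n_discard + W`` saved steps and the first
``n_discard`` are dropped, so only post-transient dynamics enter the window
(with the defaults, a 50-step window requires a 150-step simulation).

Pseudo-cohorts emulate a multi-condition empirical study: each cohort has a
characteristic mean bifurcation level, subjects scatter around it, and scan
lengths vary per subject.  The generating truth is returned so recovery can
be quantified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .sim import BoldTimeSeries, SimulationConfig, StructuralConnectome, simulate_batch

__all__ = [
    "random_connectome",
    "TrainingSet",
    "PseudoCohortSet",
    "PaletteImage",
    "generate_training_set",
    "generate_pseudo_cohorts",
    "to_image",
    "load_palette",
    "save_training_set",
    "load_training_set",
]

_BATCH = 1024  # samples integrated per vectorized pass


def random_connectome(N: int, seed: int = 0, density: float = 0.6) -> "StructuralConnectome":
    """A random symmetric nonnegative connectome, normalized to max 0.2.

    Off-diagonal weights are drawn lognormally (heavy-tailed like empirical
    fiber densities) and a fraction ``1 - density`` of edges is removed.
    Intended for demos and desk-scale studies where no tractography-derived
    matrix is available.
    """
    from .sim import connectome_from_matrix

    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=1.0, size=(N, N))
    mask = rng.uniform(size=(N, N)) < density
    m = np.where(mask, w, 0.0)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    if m.max() == 0:  # pathological draw at tiny N/density; fall back to dense
        m = 0.5 * (w + w.T)
        np.fill_diagonal(m, 0.0)
    return connectome_from_matrix(m)


@dataclass(frozen=True)
class TrainingSet:
    """Windows plus generating labels: the supervised inverse-problem data.

    ``windows`` has shape (S, N, W); ``labels_a`` and ``omegas`` are (S, N).
    """

    windows: np.ndarray
    labels_a: np.ndarray
    omegas: np.ndarray
    meta: dict

    def __post_init__(self):
        if self.windows.ndim != 3:
            raise ValueError("windows must be S x N x W")
        S, N, _ = self.windows.shape
        if self.labels_a.shape != (S, N) or self.omegas.shape != (S, N):
            raise ValueError("labels_a and omegas must be S x N")

    @property
    def n_samples(self) -> int:
        return self.windows.shape[0]


@dataclass(frozen=True)
class PseudoCohortSet:
    """Simulated multi-cohort scans with per-subject generating truth.

    ``scans[c][s]`` is the BOLD series of subject ``s`` in cohort ``c``
    (lengths may differ); ``truth[c, s]`` is that subject's generating
    bifurcation vector.
    """

    scans: list
    cohort_labels: tuple
    truth: np.ndarray

    @property
    def n_cohorts(self) -> int:
        return len(self.scans)

    @property
    def n_subjects(self) -> int:
        return len(self.scans[0])


@dataclass(frozen=True)
class PaletteImage:
    """An N x W window rendered through a fixed 256-color palette."""

    pixels: np.ndarray  # (N, W, 3) uint8
    palette_id: str


@lru_cache(maxsize=4)
def load_palette(palette_id: str = "viridis256") -> np.ndarray:
    """Load a frozen 256 x 3 uint8 palette shipped with the package."""
    ref = resources.files("hopfbif.data") / f"{palette_id}.csv"
    try:
        text = ref.read_text()
    except FileNotFoundError as err:
        raise ValueError(f"unknown palette {palette_id!r}") from err
    rows = [line.split(",") for line in text.strip().splitlines()[1:]]
    pal = np.array([[int(r), int(g), int(b)] for _, r, g, b in rows], dtype=np.uint8)
    if pal.shape != (256, 3):
        raise ValueError(f"palette {palette_id!r} must have 256 RGB entries")
    return pal


def generate_training_set(
    S: int,
    W: int,
    connectome: StructuralConnectome,
    G: float,
    config: SimulationConfig | None = None,
    a_range: tuple[float, float] = (-1.0, 1.0),
    omega_range: tuple[float, float] = (0.05, 0.25),
) -> TrainingSet:
    """Simulate ``S`` training windows of ``W`` post-transient samples each."""
    if S < 1 or W < 1:
        raise ValueError("S and W must be positive")
    if a_range[0] >= a_range[1] or omega_range[0] >= omega_range[1]:
        raise ValueError("ranges must satisfy min < max")
    if config is None:
        config = SimulationConfig()
    N = connectome.n_regions
    rng = np.random.default_rng(config.seed)
    windows = np.empty((S, N, W))
    labels = np.empty((S, N))
    omegas = np.empty((S, N))
    for start in range(0, S, _BATCH):
        stop = min(start + _BATCH, S)
        B = stop - start
        a = rng.uniform(*a_range, size=(B, N))
        om = rng.uniform(*omega_range, size=(B, N))
        try:
            runs = simulate_batch(connectome, a, om, G, W, config, rng)
        except RuntimeError as err:
            raise RuntimeError(f"generation failed in samples [{start}, {stop}): {err}") from err
        windows[start:stop] = runs
        labels[start:stop] = a
        omegas[start:stop] = om
    meta = {
        "S": S, "W": W, "N": N, "G": G,
        "n_saved": config.n_discard + W,
        "a_range": list(a_range), "omega_range": list(omega_range),
        "tr": config.tr, "n_substeps": config.n_substeps,
        "sigma": config.sigma, "n_discard": config.n_discard, "seed": config.seed,
    }
    return TrainingSet(windows, labels, omegas, meta)


def generate_pseudo_cohorts(
    C: int,
    S_subjects: int,
    connectome: StructuralConnectome,
    G: float,
    config: SimulationConfig | None = None,
    cohort_a_means: np.ndarray | None = None,
    a_spread: float = 0.05,
    T_range: tuple[int, int] = (120, 240),
    omega_range: tuple[float, float] = (0.05, 0.25),
    cohort_labels: list[str] | None = None,
) -> PseudoCohortSet:
    """Simulate a multi-cohort study with known per-subject truth.

    Cohort ``c`` draws each subject's bifurcation vector i.i.d. per node from
    ``N(cohort_a_means[c], a_spread^2)`` truncated to [-1, 1]; intrinsic
    frequencies are uniform in ``omega_range`` and scan length uniform on
    ``T_range`` (inclusive), so downstream windowing is exercised the way
    variable-length empirical scans would.
    """
    if C < 2:
        raise ValueError("need at least 2 cohorts")
    if S_subjects < 1:
        raise ValueError("need at least 1 subject per cohort")
    if a_spread < 0:
        raise ValueError("a_spread must be nonnegative")
    if T_range[0] > T_range[1] or T_range[0] < 1:
        raise ValueError("invalid T_range")
    if config is None:
        config = SimulationConfig()
    if cohort_a_means is None:
        cohort_a_means = np.linspace(-0.2, 0.1, C)
    cohort_a_means = np.asarray(cohort_a_means, dtype=float)
    if cohort_a_means.shape != (C,):
        raise ValueError("cohort_a_means must have length C")
    if np.any(np.abs(cohort_a_means) >= 1):
        raise ValueError("cohort means must lie inside (-1, 1)")
    if cohort_labels is None:
        cohort_labels = [f"cohort{c}" for c in range(C)]
    N = connectome.n_regions
    rng = np.random.default_rng(config.seed)
    T_max = int(T_range[1])
    scans: list[list[BoldTimeSeries]] = []
    truth = np.empty((C, S_subjects, N))
    for c in range(C):
        a = np.clip(
            rng.normal(cohort_a_means[c], a_spread, size=(S_subjects, N)), -1.0, 1.0
        )
        om = rng.uniform(*omega_range, size=(S_subjects, N))
        lengths = rng.integers(T_range[0], T_range[1] + 1, size=S_subjects)
        runs = simulate_batch(connectome, a, om, G, T_max, config, rng)
        scans.append(
            [BoldTimeSeries(runs[s, :, : lengths[s]], config.tr) for s in range(S_subjects)]
        )
        truth[c] = a
    return PseudoCohortSet(scans, tuple(cohort_labels), truth)


def to_image(
    window: np.ndarray,
    palette_id: str = "viridis256",
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> PaletteImage:
    """Render a window as a palette image of height N and width W.

    Values are clipped to ``value_range`` and mapped linearly onto palette
    indices 0..255; the lookup is deterministic and invertible up to the
    (max - min)/255 quantization step.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.size == 0:
        raise ValueError("window must be a nonempty N x W matrix")
    if not np.all(np.isfinite(w)):
        raise ValueError("window must be finite")
    lo, hi = value_range
    if not lo < hi:
        raise ValueError("value_range min must be below max")
    pal = load_palette(palette_id)
    idx = np.rint((np.clip(w, lo, hi) - lo) / (hi - lo) * 255).astype(np.intp)
    return PaletteImage(pal[idx], palette_id)


def save_training_set(ts: TrainingSet, path: str | Path) -> None:
    """Persist a training set as an .npz container with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, windows=ts.windows, labels_a=ts.labels_a, omegas=ts.omegas)
    path.with_suffix(".json").write_text(json.dumps(ts.meta, indent=2))


def load_training_set(path: str | Path) -> TrainingSet:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in ("windows", "labels_a", "omegas")}
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TrainingSet(arrays["windows"], arrays["labels_a"], arrays["omegas"], meta)
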