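"""Stochastic Hopf whole-brain network model.

Each brain region (node) follows the normal form of a supercritical Hopf
bifurcation in Cartesian coordinates; nodes are coupled through a structural
connectome with a linear difference scheme scaled by a global coupling
factor ``G``.  For node ``j``:

    dx_j/dt = (a_j - x_j^2 - y_j^2) x_j - w_j y_j + G * sum_i C_ij (x_i - x_j) + noise
    dy_j/dt = (a_j - x_j^2 - y_j^2) y_j + w_j x_j + G * sum_i C_ij (y_i - y_j) + noise

For ``a_j < 0`` the node relaxes to a stable fixed point at the origin
(noise-driven, asynchronous activity); for ``a_j > 0`` it settles on a limit
cycle of radius ``sqrt(a_j)`` and frequency ``f = w_j / (2*pi)``.  The BOLD
signal of region ``j`` is the ``x_j`` coordinate.

Integration uses the Euler-Maruyama scheme with additive Gaussian noise:
``state += dt * drift + sigma * sqrt(dt) * N(0, 1)`` per substep, with
``n_substeps`` substeps per saved sample so the saved-sample interval equals
the scan repetition time (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StructuralConnectome",
    "HopfParams",
    "SimulationConfig",
    "BoldTimeSeries",
    "SimulationDiverged",
    "load_connectome",
    "connectome_from_matrix",
    "simulate",
    "simulate_batch",
]

_DIVERGENCE_LIMIT = 1e6


class SimulationDiverged(RuntimeError):
    """Raised when the state leaves the divergence guard radius."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(
            f"simulation diverged (|state| > {_DIVERGENCE_LIMIT:g}) at substep {step}"
        )


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric nonnegative region-to-region weight matrix.

    Weights are fiber-density-like and dimensionless; after construction the
    maximum entry equals the normalization target (0.2 by convention, so the
    global coupling ``G`` is the single knob controlling network influence).
    """

    weights: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if len(self.region_names) != w.shape[0]:
            raise ValueError("region_names length must match matrix size")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class HopfParams:
    """Node-level Hopf parameters plus global coupling.

    Parameters
    ----------
    a : (N,) array
        Bifurcation parameters, dimensionless.  Negative values give a
        noise-driven fixed point, positive values a limit cycle of amplitude
        ``sqrt(a)``.
    omega : (N,) array
        Intrinsic angular frequencies in rad/s (``f = omega / 2 pi``).
    G : float
        Nonnegative global coupling factor scaling all connections.
    beta : float
        Model-level additive noise standard deviation (default 0.02).  The
        amplitude actually injected per run is ``SimulationConfig.sigma``
        unless that is None, in which case ``beta`` is used.
    """

    a: np.ndarray
    omega: np.ndarray
    G: float
    beta: float = 0.02

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if a.shape != om.shape or a.ndim != 1:
            raise ValueError("a and omega must be 1-D vectors of equal length")
        if self.G < 0:
            raise ValueError("G must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "omega", om)

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``tr`` is the saved-sample interval in seconds (HCP repetition time by
    default); each saved sample is integrated with ``n_substeps`` Euler
    substeps of size ``tr / n_substeps``.  The first ``n_discard`` saved
    samples are treated as transient and dropped.  ``sigma`` is the noise
    amplitude injected per substep (``None`` defers to ``HopfParams.beta``).
    """

    tr: float = 0.72
    n_substeps: int = 10
    sigma: float | None = 0.01
    n_discard: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be a positive integer")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_discard < 0:
            raise ValueError("n_discard must be nonnegative")

    @property
    def dt(self) -> float:
        return self.tr / self.n_substeps


@dataclass(frozen=True)
class BoldTimeSeries:
    """An N x T multichannel signal with its sampling interval in seconds."""

    values: np.ndarray
    tr: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be an N x T matrix")
        if v.shape[1] < 1:
            raise ValueError("need at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def connectome_from_matrix(
    matrix: np.ndarray,
    region_names: list[str] | None = None,
    normalize_to: float = 0.2,
) -> StructuralConnectome:
    """Symmetrize, zero the diagonal and rescale a raw weight matrix.

    The matrix is symmetrized as ``(M + M.T) / 2``, the diagonal is zeroed
    (no self-coupling in the difference scheme) and the result is rescaled so
    its maximum entry equals ``normalize_to``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectome matrix must be square, got shape {m.shape}")
    if np.any(m < 0):
        raise ValueError("connectome weights must be nonnegative")
    if normalize_to <= 0:
        raise ValueError("normalize_to must be positive")
    w = 0.5 * (m + m.T)
    np.fill_diagonal(w, 0.0)
    peak = w.max()
    if peak <= 0:
        raise ValueError("connectome has no off-diagonal weight; cannot normalize")
    w *= normalize_to / peak
    n = m.shape[0]
    if region_names is None:
        region_names = [f"region{i:03d}" for i in range(n)]
    return StructuralConnectome(w, tuple(region_names))


def load_connectome(path: str | Path, normalize_to: float = 0.2) -> StructuralConnectome:
    """Read a connectome from delimited text (comma or whitespace).

    An optional first row of non-numeric tokens is taken as region names.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    names = None
    skip = 0
    tokens = [t for t in first.replace(",", " ").split() if t]
    try:
        [float(t) for t in tokens]
    except ValueError:
        names = tokens
        skip = 1
    m = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
    if names is not None and len(names) != m.shape[1]:
        raise ValueError("header length does not match matrix width")
    return connectome_from_matrix(m, names, normalize_to=normalize_to)


def _integrate(
    C: np.ndarray,
    a: np.ndarray,
    omega: np.ndarray,
    G: float,
    sigma: float,
    init: np.ndarray,
    n_saved: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Batched Euler-Maruyama core.

    ``a``/``omega`` have shape (B, N), ``init`` shape (B, 2, N).  Returns the
    saved ``x`` trajectory of shape (B, N, n_saved), transient included.
    The coupling term ``sum_i C_ij (x_i - x_j)`` vanishes identically for a
    synchronized network, so uncoupled behaviour is recovered exactly.
    """
    B, N = a.shape
    dt = config.dt
    sqdt = np.sqrt(dt)
    col_strength = C.sum(axis=0)  # (N,) total afferent weight per node
    x = init[:, 0, :].copy()
    y = init[:, 1, :].copy()
    out = np.empty((B, N, n_saved))
    step = 0
    for s in range(n_saved):
        for _ in range(config.n_substeps):
            r2 = x * x + y * y
            lin = a - r2
            # sum_i C_ij (x_i - x_j) = (x @ C)_j - x_j * colsum_j
            cx = x @ C - x * col_strength
            cy = y @ C - y * col_strength
            dx = lin * x - omega * y + G * cx
            dy = lin * y + omega * x + G * cy
            if sigma > 0:
                noise = rng.standard_normal((2, B, N))
                x = x + dt * dx + sigma * sqdt * noise[0]
                y = y + dt * dy + sigma * sqdt * noise[1]
            else:
                x = x + dt * dx
                y = y + dt * dy
            step += 1
            if not (np.abs(x).max() < _DIVERGENCE_LIMIT and np.abs(y).max() < _DIVERGENCE_LIMIT):
                raise SimulationDiverged(step)
        out[:, :, s] = x
    return out


def simulate(
    connectome: StructuralConnectome,
    params: HopfParams,
    n_samples: int,
    config: SimulationConfig | None = None,
    initial_state: np.ndarray | None = None,
) -> BoldTimeSeries:
    """Integrate the coupled Hopf network and return ``n_samples`` BOLD samples.

    The first ``config.n_discard`` saved samples are discarded as transient.
    If ``initial_state`` (a 2 x N array of ``x`` and ``y`` rows) is absent,
    initial values are drawn uniformly from [-1, 1].  Randomness (initial
    state first, then per-substep noise) comes from one generator seeded with
    ``config.seed``, so runs are bit-reproducible.
    """
    if config is None:
        config = SimulationConfig()
    N = connectome.n_regions
    if params.n_regions != N:
        raise ValueError(
            f"parameter length {params.n_regions} does not match connectome size {N}"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        init = rng.uniform(-1.0, 1.0, size=(1, 2, N))
    else:
        init = np.asarray(initial_state, dtype=float).reshape(1, 2, N)
    sigma = params.beta if config.sigma is None else config.sigma
    n_saved = config.n_discard + n_samples
    traj = _integrate(
        connectome.weights,
        params.a[None, :],
        params.omega[None, :],
        params.G,
        sigma,
        init,
        n_saved,
        config,
        rng,
    )
    return BoldTimeSeries(traj[0, :, config.n_discard :], config.tr)


def simulate_batch(
    connectome: StructuralConnectome,
    a: np.ndarray,
    omega: np.ndarray,
    G: float,
    n_samples: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integrate B independent runs sharing one connectome and coupling.

    ``a`` and ``omega`` have shape (B, N); each run gets its own uniform
    [-1, 1] initial state.  Returns an array of shape (B, N, n_samples) with
    the transient removed.  This is the workhorse behind synthetic training
    sets and coupling sweeps, where thousands of short runs share all global
    settings.
    """
    a = np.asarray(a, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if a.shape != omega.shape or a.ndim != 2:
        raise ValueError("a and omega must both have shape (B, N)")
    if a.shape[1] != connectome.n_regions:
        raise ValueError("parameter width does not match connectome size")
    B, N = a.shape
    init = rng.uniform(-1.0, 1.0, size=(B, 2, N))
    sigma = 0.01 if config.sigma is None else config.sigma
    n_saved = config.n_discard + n_samples
    traj = _integrate(connectome.weights, a, omega, G, sigma, init, n_saved, config, rng)
    return traj[:, :, config.n_discard :]
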