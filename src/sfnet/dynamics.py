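"""Stochastic Wilson-Cowan network dynamics integrated by Euler-Maruyama.

Each cortical region ``i`` holds an excitatory population ``u_i`` and an
inhibitory population ``v_i`` evolving as

    du_i/dt = -u_i + f(c1 u_i - c2 v_i + P + eps * sum_j b_ij u_j)
    dv_i/dt = -v_i + f(c3 u_i - c4 v_i + Q)

with the logistic firing rate ``f(x) = 1 / (1 + exp(-x))``.  ``b_ij`` is one
of the cortical connectivity representations, ``P`` and ``Q`` are basal
inputs to the two populations (the control parameters swept by the pipeline)
and ``eps`` scales between-node coupling; ``eps = 0`` decouples the network
into ``N`` independent two-dimensional nodes.  Default within-node constants
``c1 = c2 = c3 = 10``, ``c4 = -2`` place oscillatory rhythms in biophysical
frequency ranges.

White noise of amplitude ``sigma`` is added to the ``u`` variable of every
node: by default ``sigma`` is read as the diffusion coefficient of the SDE,
so the Euler-Maruyama update adds ``sigma * sqrt(dt) * xi`` per step with
``xi`` i.i.d. standard normal (``noise_convention='per-step-sd'``).  The
alternative reading of ``sigma`` as a variance *rate* (increment
``sqrt(sigma * dt) * xi``) is available via ``noise_convention='intensity'``.
At the default ``sigma = 0.01`` the two differ tenfold in increment size;
only the default preserves the near-critical synchronisation phenomena the
pipeline studies (see the methods note), which is why it is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._compat import njit
from .connectome import ConnectomeVariant
from .netmodel import LayerMatrix, strength

_CLIP = 500.0  # sigmoid argument clip; f(+-500) is 1/0 to double precision


class SimulationError(RuntimeError):
    """Raised when the integration produces non-finite state."""

    def __init__(self, step: int) -> None:
        super().__init__(
            f"non-finite state encountered at integration step {step}"
        )
        self.step = step


@dataclass
class WCParameters:
    """Wilson-Cowan constants, basal inputs and global coupling strength."""

    c1: float = 10.0
    c2: float = 10.0
    c3: float = 10.0
    c4: float = -2.0
    P: float = 0.0
    Q: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4", "P", "Q", "epsilon"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"parameter {name} must be finite, got {val}")
        if self.epsilon < 0.0:
            raise ValueError("epsilon must be non-negative")

    def replace(self, **kwargs) -> "WCParameters":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class SimulationConfig:
    """Integration settings for one stochastic run."""

    total_time: float = 2000.0
    dt: float = 0.01
    noise_sigma: float = 0.01
    burn_in: float = 1000.0
    seed: int = 0
    stride: int = 10
    initial_state: Optional[np.ndarray] = None
    noise_convention: str = "per-step-sd"

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.burn_in < self.total_time):
            raise ValueError("burn_in must satisfy 0 <= burn_in < total_time")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be non-negative")
        if self.stride < 1 or int(self.stride) != self.stride:
            raise ValueError("stride must be a positive integer")
        if self.noise_convention not in ("intensity", "per-step-sd"):
            raise ValueError(
                "noise_convention must be 'intensity' or 'per-step-sd'"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def noise_amplitude(self) -> float:
        if self.noise_convention == "intensity":
            return float(np.sqrt(self.noise_sigma * self.dt))
        return float(self.noise_sigma * np.sqrt(self.dt))


@dataclass
class Trajectory:
    """Recorded per-node excitatory/inhibitory time series."""

    times: np.ndarray  # (T_samples,)
    u: np.ndarray  # (N, T_samples)
    v: np.ndarray  # (N, T_samples)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]

    def after(self, t: float) -> "Trajectory":
        """Sub-trajectory restricted to sample times ``>= t``."""
        keep = self.times >= t
        return Trajectory(self.times[keep], self.u[:, keep], self.v[:, keep],
                          dict(self.metadata))


def firing_rate(x):
    """Logistic firing-rate function ``1 / (1 + exp(-x))``, overflow-safe."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


def coupling_strength(variant: ConnectomeVariant) -> float:
    """Global coupling for a cortical representation.

    Unity for the two weighted representations; ``1 / <k>`` (inverse mean
    degree) for the binary one, so the total input per node is of the same
    order across representations.
    """
    if variant.kind in ("weighted", "weighted-topological"):
        return 1.0
    mean_degree = float(strength(variant.matrix).mean())
    if mean_degree <= 0.0:
        raise ValueError("binary network has zero mean degree")
    return 1.0 / mean_degree


@njit(cache=True)
def _em_chunk(u, v, b, c1, c2, c3, c4, p, q, eps, dt, amp, noise,
              offset, stride, u_rec, v_rec):  # pragma: no cover - numba
    n = u.shape[0]
    du = np.empty(n)
    dv = np.empty(n)
    for s in range(noise.shape[0]):
        if eps != 0.0:
            bu = b @ u
        else:
            bu = np.zeros(n)
        for i in range(n):
            x = c1 * u[i] - c2 * v[i] + p + eps * bu[i]
            if x > _CLIP:
                x = _CLIP
            elif x < -_CLIP:
                x = -_CLIP
            y = c3 * u[i] - c4 * v[i] + q
            if y > _CLIP:
                y = _CLIP
            elif y < -_CLIP:
                y = -_CLIP
            fu = 1.0 / (1.0 + np.exp(-x))
            fv = 1.0 / (1.0 + np.exp(-y))
            du[i] = dt * (fu - u[i]) + amp * noise[s, i]
            dv[i] = dt * (fv - v[i])
        bad = False
        for i in range(n):
            u[i] += du[i]
            v[i] += dv[i]
            if not np.isfinite(u[i]) or not np.isfinite(v[i]):
                bad = True
        g = offset + s + 1
        if bad:
            return g
        if g % stride == 0:
            r = g // stride
            for i in range(n):
                u_rec[r, i] = u[i]
                v_rec[r, i] = v[i]
    return -1


_CHUNK_STEPS = 50_000


def simulate(
    connectivity: LayerMatrix | np.ndarray,
    params: WCParameters,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the stochastic Wilson-Cowan network.

    One shared random stream (seeded by ``config.seed``) supplies, in order,
    the initial conditions (``u`` then ``v``, i.i.d. uniform on (0, 1), used
    only when ``config.initial_state`` is None) and then the per-step noise
    increments in step-major, node-minor order.  Runs are bitwise
    reproducible for identical seeds and inputs.

    Raises
    ------
    SimulationError
        If the state becomes non-finite (reports the offending step index).
    """
    b = connectivity.weights if isinstance(connectivity, LayerMatrix) else np.asarray(
        connectivity, dtype=float
    )
    n = b.shape[0]
    rng = np.random.default_rng(config.seed)
    if config.initial_state is not None:
        state = np.asarray(config.initial_state, dtype=float)
        if state.shape != (2 * n,):
            raise ValueError(
                f"initial_state must have shape ({2 * n},), got {state.shape}"
            )
        u = state[:n].copy()
        v = state[n:].copy()
    else:
        u = rng.random(n)
        v = rng.random(n)

    steps = config.n_steps
    stride = int(config.stride)
    n_rec = steps // stride + 1
    u_rec = np.empty((n_rec, n))
    v_rec = np.empty((n_rec, n))
    u_rec[0] = u
    v_rec[0] = v
    amp = config.noise_amplitude

    b = np.ascontiguousarray(b)
    offset = 0
    while offset < steps:
        chunk = min(_CHUNK_STEPS, steps - offset)
        if amp > 0.0:
            noise = rng.standard_normal((chunk, n))
        else:
            noise = np.zeros((chunk, n))
        bad_step = _em_chunk(
            u, v, b,
            params.c1, params.c2, params.c3, params.c4,
            params.P, params.Q, params.epsilon,
            config.dt, amp, noise, offset, stride, u_rec, v_rec,
        )
        if bad_step >= 0:
            raise SimulationError(int(bad_step))
        offset += chunk

    times = np.arange(n_rec) * (stride * config.dt)
    meta = {
        "params": params,
        "config": config,
        "seed": config.seed,
        "n_nodes": n,
    }
    return Trajectory(times, np.ascontiguousarray(u_rec.T),
                      np.ascontiguousarray(v_rec.T), meta)
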