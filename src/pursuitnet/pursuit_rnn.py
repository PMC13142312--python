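"""The recurrent pursuit agent.

A leaky discrete-time RNN whose recurrent weight matrix is a rank-r factor
product ``W = M @ Q.T / N``. The network receives the initial positions of
both agents (a pulse at t = 0) and the target's allocentric velocity at
unmasked steps, and outputs a 2-vector read as movement direction (its
angle) and speed (a squashed norm). The agent's own position is never fed
back: the network must path-integrate internally.

State update (nonlinearity on the state, leak outside):

    h' = (1 - alpha) * h + alpha * (W tanh(h) + B u + b)

With zero initial state the hidden trajectory stays in the span of the
columns of M and B plus b, which is what bounds the latent dimensionality
of a rank-r network by r + n_in (+1 for the bias direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .arena_targets import ArenaConfig, Trial, displacement, geodesic_distance, resolve_boundary

__all__ = [
    "N_INPUTS",
    "RNNParams",
    "RolloutResult",
    "init_rnn",
    "build_inputs",
    "step",
    "rollout",
    "rollout_batch",
    "effective_weight",
    "squash_velocity",
    "save_params",
    "load_params",
]

N_INPUTS = 6
EPS_SPEED = 1e-3  # m/s; below this the heading is frozen

# Asymptotic top singular value of (1/N) * M @ Q.T with square standard
# Gaussian factors: the Fuss-Catalan edge sqrt(27/4) for a product of two
# Ginibre matrices. Used to normalize the full-rank spectral scale.
_PRODUCT_EDGE = np.sqrt(27.0 / 4.0)


@dataclass
class RNNParams:
    """Network parameters with rank-r recurrent factorization."""

    N: int
    rank: int
    M: np.ndarray  # (N, rank)
    Q: np.ndarray  # (N, rank)
    B: np.ndarray  # (N, n_in)
    b: np.ndarray  # (N,)
    W_out: np.ndarray  # (2, N)
    alpha: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.N):
            raise ValueError("rank must satisfy 1 <= rank <= N")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        for name in ("M", "Q", "B", "b", "W_out"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
        if self.M.shape != (self.N, self.rank) or self.Q.shape != (self.N, self.rank):
            raise ValueError("M and Q must be (N, rank)")

    @property
    def n_in(self) -> int:
        return self.B.shape[1]

    def copy(self) -> "RNNParams":
        return RNNParams(self.N, self.rank, self.M.copy(), self.Q.copy(),
                         self.B.copy(), self.b.copy(), self.W_out.copy(),
                         self.alpha, self.seed)


@dataclass
class RolloutResult:
    """One simulated episode of the RNN-agent."""

    activations: np.ndarray  # (T, N), tanh of the hidden state
    out_velocities: np.ndarray  # (T, 2) m/s
    positions: np.ndarray  # (T, 2) m
    headings: np.ndarray  # (T,) rad, last valid movement direction
    heading_valid: np.ndarray  # (T,) bool
    end_distance: float  # m, geodesic at the final step

    @property
    def T(self) -> int:
        return self.positions.shape[0]

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.out_velocities, axis=-1)


def init_rnn(
    N: int,
    rank: int,
    n_in: int = N_INPUTS,
    seed: int = 0,
    gain: float = 1.0,
    alpha: float = 0.5,
) -> RNNParams:
    """Initialize a rank-r network deterministically from ``seed``.

    Factor entries are i.i.d. Gaussian with a variance chosen so that at
    full rank the spectral norm of ``W = M Q.T / N`` is approximately
    ``gain``.
    """
    if rank > N:
        raise ValueError("rank must not exceed N")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(gain / _PRODUCT_EDGE)
    M = rng.normal(0.0, sigma, size=(N, rank))
    Q = rng.normal(0.0, sigma, size=(N, rank))
    B = rng.normal(0.0, 1.0, size=(N, n_in))
    b = np.zeros(N)
    W_out = rng.normal(0.0, 1.0 / np.sqrt(N), size=(2, N))
    return RNNParams(N=N, rank=rank, M=M, Q=Q, B=B, b=b, W_out=W_out,
                     alpha=alpha, seed=seed)


def effective_weight(params: RNNParams) -> np.ndarray:
    """Dense recurrent matrix ``M @ Q.T / N`` (rank <= r by construction)."""
    return params.M @ params.Q.T / params.N


def build_inputs(trial: Trial) -> np.ndarray:
    """Input sequence (T, 6) for one trial.

    Channels 0-3 carry the initial positions (agent x, y, target x, y) at
    t = 0 only; channels 4-5 carry the target's allocentric velocity at
    unmasked steps and zero otherwise.
    """
    T = trial.T
    u = np.zeros((T, N_INPUTS))
    u[0, 0:2] = trial.rnn_start
    u[0, 2:4] = trial.target.positions[0]
    u[:, 4:6] = trial.target.velocities * trial.mask[:, None]
    return u


def step(params: RNNParams, h: np.ndarray, u_t: np.ndarray) -> np.ndarray:
    """One state update; ``h`` and ``u_t`` may carry a leading batch axis."""
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(u_t))):
        raise FloatingPointError("non-finite state or input")
    a = params.alpha
    r = np.tanh(h)
    rec = (r @ params.Q) @ params.M.T / params.N
    return (1.0 - a) * h + a * (rec + u_t @ params.B.T + params.b)


def squash_velocity(z: np.ndarray, v_max: float) -> np.ndarray:
    """Readout-to-velocity map: direction = angle(z), speed = v_max*|z|/(1+|z|)."""
    n = np.linalg.norm(z, axis=-1, keepdims=True)
    return v_max * z / (1.0 + n)


def rollout_batch(
    params: RNNParams,
    trials: list,
    arena: ArenaConfig,
) -> list:
    """Roll out many same-length trials in one vectorized pass."""
    T = trials[0].T
    if any(tr.T != T for tr in trials):
        raise ValueError("all trials in a batch must share T")
    U = np.stack([build_inputs(tr) for tr in trials])  # (B, T, 6)
    P0 = np.stack([tr.rnn_start for tr in trials])  # (B, 2)
    acts, vels, pos = _forward_dynamics(params, U, P0, arena)
    results = []
    for i, tr in enumerate(trials):
        headings, valid = _headings_from_velocities(vels[i])
        end_d = float(geodesic_distance(pos[i, -1], tr.target.positions[-1], arena))
        results.append(RolloutResult(
            activations=acts[i], out_velocities=vels[i], positions=pos[i],
            headings=headings, heading_valid=valid, end_distance=end_d,
        ))
    return results


def rollout(params: RNNParams, trial: Trial, arena: ArenaConfig) -> RolloutResult:
    """Simulate one full episode (see :func:`rollout_batch` for many)."""
    return rollout_batch(params, [trial], arena)[0]


def _forward_dynamics(params, U, P0, arena):
    """Core loop shared by rollout and training: returns (acts, vels, pos)."""
    Bsz, T, _ = U.shape
    N = params.N
    x = np.zeros((Bsz, N))
    acts = np.empty((Bsz, T, N))
    vels = np.empty((Bsz, T, 2))
    pos = np.empty((Bsz, T, 2))
    pos[:, 0] = P0
    a = params.alpha
    for t in range(T):
        r = np.tanh(x)
        acts[:, t] = r
        z = r @ params.W_out.T
        v = squash_velocity(z, arena.v_max_agent)
        vels[:, t] = v
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite hidden state at step {t}")
        if t < T - 1:
            pos[:, t + 1] = resolve_boundary(pos[:, t] + v * arena.dt, arena)
            rec = (r @ params.Q) @ params.M.T / N
            x = (1.0 - a) * x + a * (rec + U[:, t] @ params.B.T + params.b)
    return acts, vels, pos


def _headings_from_velocities(vels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Heading at t = direction of the last applied movement with speed > eps.

    The movement applied between t-1 and t is ``vels[t-1]``; until the first
    such movement the heading is undefined (valid = False).
    """
    T = vels.shape[0]
    headings = np.zeros(T)
    valid = np.zeros(T, dtype=bool)
    current = 0.0
    have = False
    for t in range(1, T):
        v = vels[t - 1]
        if np.hypot(v[0], v[1]) > EPS_SPEED:
            current = float(np.arctan2(v[1], v[0]))
            have = True
        headings[t] = current
        valid[t] = have
    return headings, valid


# ---------------------------------------------------------------------------
# checkpoints


def save_params(params: RNNParams, path: str | Path) -> None:
    """Write a bit-exact HDF5 checkpoint."""
    with h5py.File(path, "w") as f:
        for name in ("M", "Q", "B", "b", "W_out"):
            f.create_dataset(name, data=getattr(params, name))
        f.attrs["N"] = params.N
        f.attrs["rank"] = params.rank
        f.attrs["alpha"] = params.alpha
        f.attrs["seed"] = -1 if params.seed is None else params.seed


def load_params(path: str | Path) -> RNNParams:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        return RNNParams(
            N=int(f.attrs["N"]), rank=int(f.attrs["rank"]),
            M=f["M"][...], Q=f["Q"][...], B=f["B"][...], b=f["b"][...],
            W_out=f["W_out"][...], alpha=float(f.attrs["alpha"]),
            seed=None if seed < 0 else seed,
        )
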