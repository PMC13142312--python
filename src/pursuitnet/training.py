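"""Supervised training of the pursuit RNN, and unit-ablation machinery.

Gradients are computed by exact backpropagation through time through the
full closed loop: state update, readout, velocity squashing, position
integration (including the boundary map) and the geodesic distance loss.
Two loss variants are supported: the distance between the agents at the
final step of the trial (the default, which permits anticipatory detours)
and the average distance over all steps (which rewards staying on the
target's tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .arena_targets import (
    ArenaConfig,
    CTParams,
    RTParams,
    Trial,
    displacement,
    geodesic_distance,
    make_dataset,
)
from .pursuit_rnn import RNNParams, RolloutResult, build_inputs, rollout_batch

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "loss_final",
    "loss_mean",
    "loss_and_grads",
    "train",
    "ablate_units",
    "ablation_curve",
    "AblationCurve",
]

_TRAINABLE = ("M", "Q", "B", "b", "W_out")


@dataclass(frozen=True)
class TrainConfig:
    loss_kind: str = "final_distance"  # or "mean_distance"
    epochs: int = 20
    trials_per_epoch: int = 512
    batch_size: int = 64
    learning_rate: float = 1e-3
    grad_clip: float = 1.0
    ct_fraction: float = 0.25
    mask_fraction: float = 0.0
    seed: int = 0
    eval_trials_per_kind: int = 32
    squared: bool = False  # optional squared-distance variant

    def __post_init__(self) -> None:
        if self.loss_kind not in ("final_distance", "mean_distance"):
            raise ValueError("loss_kind must be final_distance or mean_distance")
        if self.epochs < 1 or self.trials_per_epoch < 1 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.ct_fraction < 1) and self.ct_fraction != 1.0:
            raise ValueError("ct_fraction must be in [0, 1]")
        if not (0 <= self.mask_fraction < 1):
            raise ValueError("mask_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch training loss and evaluation snapshots."""

    epoch_loss: list = field(default_factory=list)  # mean batch loss (m)
    rt_median: list = field(default_factory=list)  # median eval end distance (m)
    ct_median: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# losses


def loss_final(rollout: RolloutResult, trial: Trial, arena: ArenaConfig) -> float:
    """Geodesic inter-agent distance at the last step of the trial."""
    return float(geodesic_distance(rollout.positions[-1], trial.target.positions[-1], arena))


def loss_mean(rollout: RolloutResult, trial: Trial, arena: ArenaConfig) -> float:
    """Mean over time of the geodesic inter-agent distance."""
    d = geodesic_distance(rollout.positions, trial.target.positions, arena)
    return float(np.mean(d))


# ---------------------------------------------------------------------------
# forward/backward


def _squash_backward(z, g_v, v_max):
    """Backprop through v = v_max * z / (1 + |z|)."""
    n = np.linalg.norm(z, axis=-1, keepdims=True)
    n_safe = np.maximum(n, 1e-300)
    zg = np.sum(z * g_v, axis=-1, keepdims=True)
    return v_max * (g_v / (1.0 + n) - z * zg / (n_safe * (1.0 + n) ** 2))


def loss_and_grads(
    params: RNNParams,
    trials: list,
    arena: ArenaConfig,
    loss_kind: str = "final_distance",
    squared: bool = False,
) -> tuple[float, dict]:
    """Mean loss over a batch of trials and its exact parameter gradients.

    Returns ``(loss, grads)`` with grads keyed by parameter name
    (M, Q, B, b, W_out).
    """
    a = params.alpha
    N = params.N
    dt = arena.dt
    Bsz = len(trials)
    T = trials[0].T
    U = np.stack([build_inputs(tr) for tr in trials])
    P0 = np.stack([tr.rnn_start for tr in trials])
    TGT = np.stack([tr.target.positions for tr in trials])  # (B, T, 2)
    L = arena.side_length
    periodic = arena.boundary == "periodic"

    # ---- forward with caches
    x = np.zeros((Bsz, N))
    acts = np.empty((Bsz, T, N))
    zs = np.empty((Bsz, T, 2))
    pos = np.empty((Bsz, T, 2))
    interior = np.ones((Bsz, T, 2), dtype=bool)  # d(resolve)/d(raw) mask
    pos[:, 0] = P0
    for t in range(T):
        r = np.tanh(x)
        acts[:, t] = r
        z = r @ params.W_out.T
        zs[:, t] = z
        n = np.linalg.norm(z, axis=-1, keepdims=True)
        v = arena.v_max_agent * z / (1.0 + n)
        if t < T - 1:
            raw = pos[:, t] + v * dt
            if periodic:
                pos[:, t + 1] = np.mod(raw, L)
            else:
                pos[:, t + 1] = np.clip(raw, 0.0, L)
                interior[:, t + 1] = (raw > 0.0) & (raw < L)
            rec = (r @ params.Q) @ params.M.T / N
            x = (1.0 - a) * x + a * (rec + U[:, t] @ params.B.T + params.b)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(f"non-finite hidden state at step {t}")

    # ---- loss and d(loss)/d(pos)
    diff = pos - TGT
    if periodic:
        diff = diff - L * np.round(diff / L)
    dist = np.linalg.norm(diff, axis=-1)  # (B, T)
    unit = diff / np.maximum(dist, 1e-12)[..., None]
    g_pos = np.zeros((Bsz, T, 2))
    if loss_kind == "final_distance":
        if squared:
            loss = float(np.mean(dist[:, -1] ** 2))
            g_pos[:, -1] = 2.0 * diff[:, -1] / Bsz
        else:
            loss = float(np.mean(dist[:, -1]))
            g_pos[:, -1] = unit[:, -1] / Bsz
    elif loss_kind == "mean_distance":
        if squared:
            loss = float(np.mean(dist**2))
            g_pos[:] = 2.0 * diff / (Bsz * T)
        else:
            loss = float(np.mean(dist))
            g_pos[:] = unit / (Bsz * T)
    else:
        raise ValueError(f"unknown loss_kind {loss_kind!r}")

    # ---- backward through time
    G_x = np.zeros((Bsz, T, N))
    G_z = np.zeros((Bsz, T, 2))
    g_pos_total = g_pos.copy()  # accumulated gradient wrt pos[t]
    for t in range(T - 1, -1, -1):
        if t < T - 1:
            g_applied = g_pos_total[:, t + 1] * interior[:, t + 1]
            g_pos_total[:, t] += g_applied
            g_v = g_applied * dt
            g_z = _squash_backward(zs[:, t], g_v, arena.v_max_agent)
        else:
            g_z = np.zeros((Bsz, 2))  # v at the last step is never applied
        G_z[:, t] = g_z
        g_r = g_z @ params.W_out
        if t < T - 1:
            g_r += a * ((G_x[:, t + 1] @ params.M) @ params.Q.T) / N
        g_x = g_r * (1.0 - acts[:, t] ** 2)
        if t < T - 1:
            g_x += (1.0 - a) * G_x[:, t + 1]
        G_x[:, t] = g_x

    G_next = G_x[:, 1:]  # pairs with r_t, u_t for t = 0..T-2
    R = acts[:, : T - 1]
    grads = {
        "M": a / N * np.einsum("btn,btr->nr", G_next, R @ params.Q),
        "Q": a / N * np.einsum("btn,btr->nr", R, G_next @ params.M),
        "B": a * np.einsum("btn,btk->nk", G_next, U[:, : T - 1]),
        "b": a * G_next.sum(axis=(0, 1)),
        "W_out": np.einsum("btk,btn->kn", G_z, acts),
    }
    return loss, grads


# ---------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, params: RNNParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(params, k)) for k in _TRAINABLE}
        self.v = {k: np.zeros_like(getattr(params, k)) for k in _TRAINABLE}

    def update(self, params: RNNParams, grads: dict) -> None:
        self.t += 1
        for k in _TRAINABLE:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            getattr(params, k)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# training loop


def train(
    params: RNNParams,
    arena: ArenaConfig,
    rt_params: RTParams,
    ct_params: CTParams,
    cfg: TrainConfig,
) -> tuple[RNNParams, TrainHistory]:
    """Train a copy of ``params`` with Adam on freshly sampled trials.

    Each epoch draws ``trials_per_epoch`` new trials (mixing RTs and CTs by
    ``ct_fraction``), iterates over minibatches, and records the mean batch
    loss plus median end distances on a fixed evaluation set (sampled once
    at the start). Fully reproducible from ``cfg.seed``.
    """
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(params, cfg.learning_rate)
    history = TrainHistory()

    n_eval = cfg.eval_trials_per_kind
    eval_rt = make_dataset(n_eval, 0.0, cfg.mask_fraction, arena, rt_params, ct_params, rng).trials
    eval_ct = make_dataset(n_eval, 1.0, cfg.mask_fraction, arena, rt_params, ct_params, rng).trials

    n_batches = max(1, cfg.trials_per_epoch // cfg.batch_size)
    for epoch in range(cfg.epochs):
        data = make_dataset(n_batches * cfg.batch_size, cfg.ct_fraction,
                            cfg.mask_fraction, arena, rt_params, ct_params, rng).trials
        order = rng.permutation(len(data))
        epoch_losses = []
        for ib in range(n_batches):
            batch = [data[j] for j in order[ib * cfg.batch_size:(ib + 1) * cfg.batch_size]]
            loss, grads = loss_and_grads(params, batch, arena,
                                         loss_kind=cfg.loss_kind, squared=cfg.squared)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            _clip_grads(grads, cfg.grad_clip)
            opt.update(params, grads)
            epoch_losses.append(loss)
        history.epoch_loss.append(float(np.mean(epoch_losses)))
        rt_end = [r.end_distance for r in rollout_batch(params, eval_rt, arena)]
        ct_end = [r.end_distance for r in rollout_batch(params, eval_ct, arena)]
        history.rt_median.append(float(np.median(rt_end)))
        history.ct_median.append(float(np.median(ct_end)))
    return params, history


# ---------------------------------------------------------------------------
# ablation


def ablate_units(params: RNNParams, unit_ids) -> RNNParams:
    """Structurally silence the given units.

    Their rows in M, Q and B, their readout columns, and their biases are
    zeroed, so the unit's state stays at zero and is invisible downstream.
    The recurrent rank bound is preserved. Duplicate ids are deduplicated.
    """
    ids = np.unique(np.asarray(list(unit_ids), dtype=int)) if len(list(unit_ids)) else np.array([], dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= params.N):
        raise ValueError("unit ids out of range")
    out = params.copy()
    if ids.size:
        out.M[ids, :] = 0.0
        out.Q[ids, :] = 0.0
        out.B[ids, :] = 0.0
        out.b[ids] = 0.0
        out.W_out[:, ids] = 0.0
    return out


@dataclass
class AblationCurve:
    """Result of an ablation sweep at a list of ablated fractions."""

    fractions: list
    end_distances: dict  # fraction -> (n_trials,) targeted-ordering distances
    random_end_distances: dict  # fraction -> (n_repeats, n_trials)
    ks_p: dict  # fraction -> KS p-value, targeted vs pooled random


def ablation_curve(
    params: RNNParams,
    ordering: str,
    fractions,
    eval_trials: list,
    arena: ArenaConfig,
    mrl_values: np.ndarray | None = None,
    n_random_repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> AblationCurve:
    """Evaluate pursuit performance while ablating growing unit fractions.

    ``ordering`` selects which units go first: ``highest_mrl`` /
    ``lowest_mrl`` (requires ``mrl_values``) or ``random``. Random-ordering
    controls are always evaluated (``n_random_repeats`` distinct orderings)
    and each fraction's targeted end-distance distribution is compared to
    the pooled random one with a two-sample Kolmogorov-Smirnov test.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fractions = list(fractions)
    if any(not (0 <= f < 1) for f in fractions):
        raise ValueError("fractions must be in [0, 1)")
    if ordering in ("highest_mrl", "lowest_mrl"):
        if mrl_values is None:
            raise ValueError(f"ordering {ordering!r} requires mrl_values")
        order = np.argsort(-np.asarray(mrl_values)) if ordering == "highest_mrl" \
            else np.argsort(np.asarray(mrl_values))
    elif ordering == "random":
        order = rng.permutation(params.N)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    random_orders = [rng.permutation(params.N) for _ in range(n_random_repeats)]

    def _eval(p):
        return np.array([r.end_distance for r in rollout_batch(p, eval_trials, arena)])

    end_distances, random_end, ks_p = {}, {}, {}
    for f in fractions:
        k = int(round(f * params.N))
        end_distances[f] = _eval(ablate_units(params, order[:k]))
        rand = np.stack([_eval(ablate_units(params, ro[:k])) for ro in random_orders])
        random_end[f] = rand
        if k == 0:
            ks_p[f] = 1.0
        else:
            ks_p[f] = float(stats.ks_2samp(end_distances[f], rand.ravel()).pvalue)
    return AblationCurve(fractions, end_distances, random_end, ks_p)
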