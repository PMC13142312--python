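"""Arena geometry and target-agent trajectory generation.

This module defines the task world for the pursuit simulations: a square
arena (reflective walls or a periodic torus), smooth pseudo-random target
trajectories (RTs) with wall avoidance, stereotyped characteristic
trajectories (CTs) from four start locations, and trial datasets with
optional temporal masking of the velocity input.

Conventions: the arena origin is the lower-left corner, coordinates are in
meters, time is discretized in steps of ``dt`` seconds, and a trial lasts
``T`` steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "RTParams",
    "CTParams",
    "TargetTrajectory",
    "Trial",
    "TrialSet",
    "default_ct_params",
    "resolve_boundary",
    "displacement",
    "sample_rt",
    "sample_ct",
    "make_mask",
    "make_dataset",
    "save_trialset",
    "load_trialset",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Square arena geometry and time discretization.

    Parameters
    ----------
    side_length : float
        Arena side in meters (1 m x 1 m by default).
    boundary : {"reflective", "periodic"}
        Wall behavior. ``periodic`` wraps positions torus-style; agents can
        pass through a wall and reappear on the opposite side.
    dt : float
        Seconds per simulation time-step.
    T : int
        Time-steps per trial.
    v_max_target, v_max_agent : float
        Speed caps (m/s) for the target-agent and the pursuing agent.
    """

    side_length: float = 1.0
    boundary: str = "reflective"
    dt: float = 0.05
    T: int = 100
    v_max_target: float = 0.4
    v_max_agent: float = 0.3

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.boundary not in ("reflective", "periodic"):
            raise ValueError(f"unknown boundary type {self.boundary!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.v_max_target <= 0 or self.v_max_agent <= 0:
            raise ValueError("speed caps must be positive")
        # With periodic boundaries a single step must stay below half the
        # side length, so the minimal-image displacement is unambiguous.
        if self.v_max_target * self.dt >= self.side_length / 2:
            raise ValueError("v_max_target*dt must be < side_length/2")

    @property
    def duration(self) -> float:
        return self.T * self.dt

    @property
    def max_distance(self) -> float:
        """Largest possible inter-point distance under the arena metric."""
        if self.boundary == "periodic":
            return self.side_length * np.sqrt(2.0) / 2.0
        return self.side_length * np.sqrt(2.0)


@dataclass(frozen=True)
class RTParams:
    """Random-trajectory (RT) generator parameters.

    The target performs a smooth random walk: heading evolves as a Gaussian
    random walk with standard deviation ``heading_noise_sd * sqrt(dt)`` per
    step, speed follows an autoregressive process around ``speed_mean``, and
    near walls the heading is deflected toward the arena interior and speed
    is reduced (a smooth forager in the style of open-field trajectory
    models).
    """

    speed_mean: float = 0.2
    speed_std: float = 0.05
    heading_noise_sd: float = 2.0  # rad / sqrt(s)
    wall_avoid_dist: float = 0.12  # m
    wall_avoid_turn: float = 8.0  # rad / s
    speed_smoothing: float = 0.8  # AR(1) coefficient in [0, 1)
    wall_speed_factor: float = 0.5

    def validate(self, arena: ArenaConfig) -> None:
        if self.speed_mean < 0:
            raise ValueError("speed_mean must be non-negative")
        if not (0 <= self.speed_smoothing < 1):
            raise ValueError("speed_smoothing must be in [0, 1)")
        if self.wall_avoid_dist >= arena.side_length / 2:
            raise ValueError("wall_avoid_dist must be < side_length/2")


@dataclass(frozen=True)
class CTParams:
    """Characteristic-trajectory (CT) generator parameters.

    A CT starts from one of exactly four start locations and steers through
    a fixed ordered list of waypoints (the route skeleton), with small
    per-trial jitter in speed and heading. ``route_waypoints[i]`` lists the
    waypoints (excluding the start) for start location ``i``. Waypoints may
    lie outside the arena only for periodic arenas, where they encode
    through-the-wall routes in unwrapped coordinates.
    """

    start_locations: tuple = ()
    route_waypoints: tuple = ()
    speed_mean: float = 0.25
    speed_jitter_sd: float = 0.02
    heading_jitter_sd: float = 0.1  # rad

    def validate(self, arena: ArenaConfig) -> None:
        if len(self.start_locations) != 4 or len(self.route_waypoints) != 4:
            raise ValueError("exactly four start locations / routes required")
        if arena.boundary == "reflective":
            for route in self.route_waypoints:
                for w in route:
                    if not (0 <= w[0] <= arena.side_length and 0 <= w[1] <= arena.side_length):
                        raise ValueError("waypoints must lie inside a reflective arena")
        for i in range(4):
            length = self.route_length(i)
            if length > self.speed_mean * arena.duration:
                raise ValueError(
                    f"CT route {i} (length {length:.3f} m) is infeasible within "
                    f"T={arena.T} steps at speed_mean={self.speed_mean} m/s"
                )

    def route_length(self, start_index: int) -> float:
        pts = np.vstack(
            [np.asarray(self.start_locations[start_index], float)[None, :],
             np.asarray(self.route_waypoints[start_index], float)]
        )
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def default_ct_params(arena: ArenaConfig) -> CTParams:
    """Default CT geometry for an arena.

    Reflective arena: each route starts at a wall midpoint offset 0.1 m
    toward the lower-left corner, crosses straight to the opposite wall,
    then moves along that wall to its midpoint.

    Periodic arena: each route heads from the arena interior straight
    through the nearest wall and continues on the far side (expressed in
    unwrapped coordinates), so the target disappears at one boundary and
    reappears at the opposite one.
    """
    L = arena.side_length
    off = 0.1 * L
    if arena.boundary == "reflective":
        starts = (
            (L / 2 - off, 0.0),  # bottom wall
            (L / 2 - off, L),  # top wall
            (0.0, L / 2 - off),  # left wall
            (L, L / 2 - off),  # right wall
        )
        routes = (
            ((L / 2 - off, L), (L / 2, L)),
            ((L / 2 - off, 0.0), (L / 2, 0.0)),
            ((L, L / 2 - off), (L, L / 2)),
            ((0.0, L / 2 - off), (0.0, L / 2)),
        )
    else:
        starts = (
            (0.5 * L, 0.7 * L),
            (0.5 * L, 0.3 * L),
            (0.7 * L, 0.5 * L),
            (0.3 * L, 0.5 * L),
        )
        routes = (
            ((0.5 * L, 1.4 * L),),  # exits top, reappears at bottom
            ((0.5 * L, -0.4 * L),),
            ((1.4 * L, 0.5 * L),),
            ((-0.4 * L, 0.5 * L),),
        )
    return CTParams(start_locations=starts, route_waypoints=routes)


@dataclass
class TargetTrajectory:
    """A target-agent path: positions (T, 2) and velocities (T, 2).

    ``positions[t + 1] == resolve_boundary(positions[t] + velocities[t]*dt)``
    holds for every step; ``velocities[T-1]`` is generated by the same
    process but never applied (it only serves as the final input sample).
    """

    positions: np.ndarray
    velocities: np.ndarray
    kind: str  # "RT" or "CT"
    ct_start_index: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions/velocities must both be (T, 2)")
        if self.kind not in ("RT", "CT"):
            raise ValueError("kind must be 'RT' or 'CT'")

    @property
    def T(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trial:
    """One pursuit trial: agent start, target path, and input mask.

    ``mask[t]`` is True when the target velocity is delivered to the network
    at step t (False entries are replaced by zero input).
    """

    rnn_start: np.ndarray
    target: TargetTrajectory
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.rnn_start = np.asarray(self.rnn_start, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.target.T,):
            raise ValueError("mask must have length T")
        if not self.mask[0]:
            raise ValueError("mask[0] must be True")

    @property
    def T(self) -> int:
        return self.target.T

    @property
    def kind(self) -> str:
        return self.target.kind


@dataclass
class TrialSet:
    """An ordered collection of trials with its generating configuration."""

    trials: list
    arena: ArenaConfig
    ct_fraction: float
    mask_fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def of_kind(self, kind: str) -> list:
        return [tr for tr in self.trials if tr.kind == kind]


# ---------------------------------------------------------------------------
# geometry


def resolve_boundary(p: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Map a raw position back into the arena.

    Periodic arenas wrap coordinate-wise (modulo side length); reflective
    arenas clip to the walls (the trajectory generators steer away from
    walls, so the clip is only a safety net).
    """
    p = np.asarray(p, dtype=float)
    L = arena.side_length
    if arena.boundary == "periodic":
        return np.mod(p, L)
    return np.clip(p, 0.0, L)


def displacement(p: np.ndarray, q: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Displacement vector from ``q`` to ``p`` under the arena metric.

    Reflective: plain ``p - q``. Periodic: coordinate-wise minimal-image
    difference, so each component has magnitude <= side_length/2 and the
    norm is the geodesic (through-the-wall) distance.
    """
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    if arena.boundary == "periodic":
        L = arena.side_length
        d = d - L * np.round(d / L)
    return d


def geodesic_distance(p: np.ndarray, q: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Norm of :func:`displacement`, broadcasting over leading axes."""
    return np.linalg.norm(displacement(p, q, arena), axis=-1)


# ---------------------------------------------------------------------------
# trajectory generators


def _wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2 * np.pi)


def sample_rt(
    arena: ArenaConfig,
    params: RTParams,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
) -> TargetTrajectory:
    """Sample one smooth pseudo-random target trajectory.

    Heading performs a Gaussian random walk (sd ``heading_noise_sd*sqrt(dt)``
    per step); speed is an AR(1) process around ``speed_mean`` clipped to
    ``[0, v_max_target]``. Within ``wall_avoid_dist`` of a wall while
    approaching it (reflective arenas only), the heading rotates toward the
    arena interior at ``wall_avoid_turn`` rad/s and speed is scaled down.
    """
    params.validate(arena)
    L, dt, T = arena.side_length, arena.dt, arena.T
    if start is None:
        p = rng.uniform(0.0, L, size=2)
    else:
        p = np.asarray(start, dtype=float).copy()
    heading = rng.uniform(-np.pi, np.pi)
    speed = float(np.clip(rng.normal(params.speed_mean, params.speed_std),
                          0.0, arena.v_max_target))
    rho = params.speed_smoothing
    innov_sd = params.speed_std * np.sqrt(max(1.0 - rho**2, 0.0))

    positions = np.empty((T, 2))
    velocities = np.empty((T, 2))
    positions[0] = p
    max_turn = params.wall_avoid_turn * dt
    for t in range(T):
        if t > 0:
            heading = heading + params.heading_noise_sd * np.sqrt(dt) * rng.normal()
            speed = params.speed_mean + rho * (speed - params.speed_mean) + innov_sd * rng.normal()
            speed = float(np.clip(speed, 0.0, arena.v_max_target))
        eff_speed = speed
        if arena.boundary == "reflective":
            # steer toward the interior when close to a wall and approaching it
            hx, hy = np.cos(heading), np.sin(heading)
            near_low_x = p[0] < params.wall_avoid_dist and hx < 0
            near_high_x = p[0] > L - params.wall_avoid_dist and hx > 0
            near_low_y = p[1] < params.wall_avoid_dist and hy < 0
            near_high_y = p[1] > L - params.wall_avoid_dist and hy > 0
            if near_low_x or near_high_x or near_low_y or near_high_y:
                interior = np.array([L / 2, L / 2]) - p
                target_angle = np.arctan2(interior[1], interior[0])
                dtheta = _wrap_angle(target_angle - heading)
                heading = heading + float(np.clip(dtheta, -max_turn, max_turn))
                eff_speed = speed * params.wall_speed_factor
        v = eff_speed * np.array([np.cos(heading), np.sin(heading)])
        velocities[t] = v
        if t < T - 1:
            p = resolve_boundary(p + v * dt, arena)
            positions[t + 1] = p
    return TargetTrajectory(positions, velocities, kind="RT")


def sample_ct(
    arena: ArenaConfig,
    params: CTParams,
    start_index: int,
    rng: np.random.Generator,
) -> TargetTrajectory:
    """Sample one characteristic trajectory from ``start_index`` in 0..3.

    The target steers through the route waypoints at jittered speed and
    heading, stopping once the final waypoint is reached. Steering runs in
    unwrapped coordinates (relevant for periodic through-the-wall routes);
    stored positions are boundary-resolved.
    """
    if start_index not in (0, 1, 2, 3):
        raise ValueError("start_index must be in {0, 1, 2, 3}")
    params.validate(arena)
    dt, T = arena.dt, arena.T
    p = np.asarray(params.start_locations[start_index], dtype=float).copy()
    waypoints = [np.asarray(w, dtype=float) for w in params.route_waypoints[start_index]]
    wp_i = 0
    reach_tol = 1e-9

    positions = np.empty((T, 2))
    velocities = np.empty((T, 2))
    positions[0] = resolve_boundary(p, arena)
    for t in range(T):
        # advance past any waypoint already reached
        while wp_i < len(waypoints) - 1 and np.linalg.norm(waypoints[wp_i] - p) <= reach_tol:
            wp_i += 1
        to_wp = waypoints[wp_i] - p
        dist = float(np.linalg.norm(to_wp))
        if wp_i == len(waypoints) - 1 and dist <= reach_tol:
            v = np.zeros(2)  # route complete: hold position
        else:
            speed = float(np.clip(params.speed_mean + params.speed_jitter_sd * rng.normal(),
                                  0.0, arena.v_max_target))
            if dist <= speed * dt:
                v = to_wp / dt  # land exactly on the waypoint this step
            else:
                heading = np.arctan2(to_wp[1], to_wp[0])
                heading = heading + params.heading_jitter_sd * rng.normal()
                v = speed * np.array([np.cos(heading), np.sin(heading)])
        velocities[t] = v
        if t < T - 1:
            p = p + v * dt
            positions[t + 1] = resolve_boundary(p, arena)
    return TargetTrajectory(positions, velocities, kind="CT", ct_start_index=start_index)


# ---------------------------------------------------------------------------
# datasets


def make_mask(T: int, mask_fraction: float) -> np.ndarray:
    """Regular-subsampling input mask keeping a ``1 - mask_fraction`` share.

    Kept steps are evenly spaced in time (increasing the mask fraction
    increases the temporal spacing between delivered inputs); step 0 is
    always kept.
    """
    if not (0 <= mask_fraction < 1):
        raise ValueError("mask_fraction must be in [0, 1)")
    q = 1.0 - mask_fraction
    t = np.arange(T)
    mask = np.floor(q * t) != np.floor(q * (t - 1))
    mask[0] = True
    return mask


def make_dataset(
    n_trials: int,
    ct_fraction: float,
    mask_fraction: float,
    arena: ArenaConfig,
    rt_params: RTParams,
    ct_params: CTParams,
    rng: np.random.Generator,
    min_start_separation: float = 0.1,
) -> TrialSet:
    """Build a trial dataset mixing RTs and CTs.

    Trial kinds are drawn i.i.d. with probability ``ct_fraction`` of CT; CT
    start indices are uniform over the four locations. The pursuer start is
    uniform over the arena, resampled until at least ``min_start_separation``
    meters (geodesic) from the target start.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= ct_fraction <= 1):
        raise ValueError("ct_fraction must be in [0, 1]")
    seed = int(rng.integers(0, 2**31 - 1))  # recorded for the manifest
    mask = make_mask(arena.T, mask_fraction)
    trials = []
    for _ in range(n_trials):
        if rng.uniform() < ct_fraction:
            idx = int(rng.integers(0, 4))
            target = sample_ct(arena, ct_params, idx, rng)
        else:
            target = sample_rt(arena, rt_params, rng)
        while True:
            start = rng.uniform(0.0, arena.side_length, size=2)
            if geodesic_distance(start, target.positions[0], arena) >= min_start_separation:
                break
        trials.append(Trial(rnn_start=start, target=target, mask=mask.copy()))
    return TrialSet(trials=trials, arena=arena, ct_fraction=ct_fraction,
                    mask_fraction=mask_fraction, seed=seed)


# ---------------------------------------------------------------------------
# serialization: one directory per dataset, JSON manifest + per-trial CSVs


def _dataclass_dict(obj) -> dict:
    out = {}
    for k, v in obj.__dict__.items():
        if isinstance(v, tuple):
            v = _to_jsonable(v)
        out[k] = v
    return out


def _to_jsonable(v):
    if isinstance(v, (tuple, list)):
        return [_to_jsonable(x) for x in v]
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def save_trialset(ts: TrialSet, path: str | Path,
                  rt_params: RTParams | None = None,
                  ct_params: CTParams | None = None) -> None:
    """Write a TrialSet to ``path`` (JSON manifest + CSVs, meters, 0-based t)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "arena": _dataclass_dict(ts.arena),
        "ct_fraction": ts.ct_fraction,
        "mask_fraction": ts.mask_fraction,
        "seed": ts.seed,
        "n_trials": len(ts),
    }
    if rt_params is not None:
        manifest["rt_params"] = _dataclass_dict(rt_params)
    if ct_params is not None:
        manifest["ct_params"] = _dataclass_dict(ct_params)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    index_rows = []
    for i, tr in enumerate(ts):
        index_rows.append({
            "trial_id": i,
            "kind": tr.kind,
            "ct_start_index": -1 if tr.target.ct_start_index is None else tr.target.ct_start_index,
            "rnn_start_x": tr.rnn_start[0],
            "rnn_start_y": tr.rnn_start[1],
        })
        df = pd.DataFrame({
            "t": np.arange(tr.T),
            "target_x": tr.target.positions[:, 0],
            "target_y": tr.target.positions[:, 1],
            "target_vx": tr.target.velocities[:, 0],
            "target_vy": tr.target.velocities[:, 1],
            "mask": tr.mask.astype(int),
        })
        df.to_csv(path / f"trial_{i:05d}.csv", index=False, float_format="%.17g")
    pd.DataFrame(index_rows).to_csv(path / "trials.csv", index=False, float_format="%.17g")


def load_trialset(path: str | Path) -> TrialSet:
    """Load a TrialSet written by :func:`save_trialset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    arena = ArenaConfig(**manifest["arena"])
    index = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    trials = []
    for row in index.itertuples():
        df = pd.read_csv(path / f"trial_{row.trial_id:05d}.csv",
                         float_precision="round_trip")
        kind = row.kind
        target = TargetTrajectory(
            positions=df[["target_x", "target_y"]].to_numpy(),
            velocities=df[["target_vx", "target_vy"]].to_numpy(),
            kind=kind,
            ct_start_index=None if row.ct_start_index < 0 else int(row.ct_start_index),
        )
        trials.append(Trial(
            rnn_start=np.array([row.rnn_start_x, row.rnn_start_y]),
            target=target,
            mask=df["mask"].to_numpy().astype(bool),
        ))
    return TrialSet(trials=trials, arena=arena,
                    ct_fraction=manifest["ct_fraction"],
                    mask_fraction=manifest["mask_fraction"],
                    seed=manifest["seed"])
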