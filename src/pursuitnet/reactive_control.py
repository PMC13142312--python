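"""The non-predictive (reactive) control pursuer.

At every step the control agent moves straight toward the target's current
position, using the same instantaneous speed as the paired RNN rollout. It
ignores the target's history and the arena boundaries, so deviations of the
RNN trajectory from this baseline quantify non-reactive (predictive)
strategy. In a periodic arena the chase direction is the minimal-image one
(through the wall when that is shorter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena_targets import ArenaConfig, Trial, displacement, geodesic_distance, resolve_boundary

__all__ = ["ControlRollout", "reactive_rollout"]


@dataclass
class ControlRollout:
    positions: np.ndarray  # (T, 2) m
    end_distance: float  # m

    @property
    def T(self) -> int:
        return self.positions.shape[0]


def reactive_rollout(trial: Trial, speed_series: np.ndarray, arena: ArenaConfig) -> ControlRollout:
    """Roll out the reactive pursuer on one trial.

    ``speed_series`` are the per-step speeds of the paired RNN rollout
    (length T; the last entry, like the RNN's, is never applied). The step
    length is capped at the current inter-agent distance so the control
    never overshoots a nearly-captured target.
    """
    speed_series = np.asarray(speed_series, dtype=float)
    T = trial.T
    if speed_series.shape != (T,):
        raise ValueError(f"speed_series must have length T={T}")
    pos = np.empty((T, 2))
    pos[0] = trial.rnn_start
    for t in range(T - 1):
        d = displacement(trial.target.positions[t], pos[t], arena)
        dist = float(np.linalg.norm(d))
        if dist > 0:
            step_len = min(speed_series[t] * arena.dt, dist)
            pos[t + 1] = resolve_boundary(pos[t] + d / dist * step_len, arena)
        else:
            pos[t + 1] = pos[t]
    end_d = float(geodesic_distance(pos[-1], trial.target.positions[-1], arena))
    return ControlRollout(positions=pos, end_distance=end_d)
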