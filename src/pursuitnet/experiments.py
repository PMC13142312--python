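"""Config-driven experiment orchestration.

Each experiment reproduces one of the study's analyses at a configurable
scale: train networks on the pursuit task, evaluate them against the paired
reactive control, and run the behavioral and representational analyses.
Every run writes a JSON manifest sufficient to reproduce it, tidy CSVs, and
a JSON summary whose numbers are recomputable from the CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena_targets import (
    ArenaConfig,
    CTParams,
    RTParams,
    default_ct_params,
    geodesic_distance,
    make_dataset,
)
from .behavior_metrics import (
    detect_waiting,
    distance_to_endpoint_curves,
    ks_two_sample,
    normalized_deviation,
    shortcut_metric,
    wasserstein_1d,
)
from .pursuit_rnn import RNNParams, init_rnn, rollout_batch, save_params
from .reactive_control import reactive_rollout
from .representation_analysis import (
    classify_etus,
    latent_series,
    linear_decode,
    participation_ratio,
    pca95,
    pool_population,
    time_shift_profile,
)
from .training import TrainConfig, ablation_curve, train

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "run_experiment",
    "paired_evaluation",
    "condition_stats",
]

EXPERIMENT_NAMES = (
    "pursuit_basic",
    "etu_analysis",
    "predictivity",
    "masking_sweep",
    "ct_fraction_sweep",
    "rank_sweep",
    "periodic_ct",
    "decoding_sweep",
    "unit_count_sweep",
)

# Scale presets: problem sizes for a quick smoke check, a single-workstation
# ("desk") run, and the full-size study configuration.
_PRESETS = {
    # dt=0.1 halves the step count for the same trial duration; the desk
    # preset keeps 6-second trials (T=60) so the characteristic routes
    # (4.4 s at nominal speed) remain feasible.
    "smoke": dict(N=32, rank=32, T=50, dt=0.1, epochs=2, trials_per_epoch=32,
                  batch_size=16, learning_rate=5e-3, eval_trials=8, ranks=(4, 32),
                  masks=(0.0, 0.5), ct_fractions=(0.0, 0.25),
                  unit_counts=(16, 32), n_shuffles=20, seeds=(0,)),
    "desk": dict(N=256, rank=256, T=60, dt=0.1, epochs=40, trials_per_epoch=512,
                 batch_size=64, learning_rate=5e-3, eval_trials=250,
                 ranks=(4, 16, 64, 128), masks=(0.0, 0.1, 0.3, 0.5, 0.7),
                 ct_fractions=(0.0, 0.1, 0.25, 0.5), unit_counts=(64, 128, 256),
                 n_shuffles=100, seeds=(0, 1, 2)),
    "full": dict(N=1000, rank=1000, T=100, dt=0.05, epochs=200, trials_per_epoch=2048,
                 batch_size=64, learning_rate=1e-3, eval_trials=1000,
                 ranks=(10, 20, 50, 100, 200, 500, 900, 1000),
                 masks=(0.0, 0.1, 0.3, 0.5, 0.7), ct_fractions=(0.0, 0.1, 0.25, 0.5, 0.75),
                 unit_counts=(250, 500, 1000), n_shuffles=200,
                 seeds=tuple(range(5))),
}


@dataclass
class ExperimentConfig:
    """What to run and at which scale.

    ``overrides`` may replace any preset entry (N, rank, T, epochs, ...).
    """

    name: str
    scale: str = "desk"
    seeds: tuple | None = None
    out_dir: str = "results"
    figures: bool = False
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}")
        if self.scale not in _PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")

    def preset(self) -> dict:
        p = dict(_PRESETS[self.scale])
        p.update(self.overrides)
        if self.seeds is not None:
            p["seeds"] = tuple(self.seeds)
        return p


# ---------------------------------------------------------------------------
# shared helpers


def _setup(p: dict, boundary: str = "reflective"):
    arena = ArenaConfig(boundary=boundary, T=int(p["T"]), dt=float(p.get("dt", 0.05)))
    rt = RTParams()
    ct = default_ct_params(arena)
    return arena, rt, ct


def _train_network(p: dict, arena, rt, ct, seed: int, rank: int | None = None,
                   N: int | None = None, mask_fraction: float = 0.0,
                   ct_fraction: float = 0.25, loss_kind: str = "final_distance"):
    N = int(N if N is not None else p["N"])
    rank = int(rank if rank is not None else p["rank"])
    params = init_rnn(N=N, rank=rank, seed=seed)
    cfg = TrainConfig(loss_kind=loss_kind, epochs=int(p["epochs"]),
                      trials_per_epoch=int(p["trials_per_epoch"]),
                      batch_size=int(p["batch_size"]),
                      learning_rate=float(p.get("learning_rate", 1e-3)),
                      ct_fraction=ct_fraction,
                      mask_fraction=mask_fraction, seed=seed)
    return train(params, arena, rt, ct, cfg)


def _eval_sets(p: dict, arena, rt, ct, seed: int, mask_fraction: float = 0.0):
    rng = np.random.default_rng(seed + 990_001)
    n = int(p["eval_trials"])
    rts = make_dataset(n, 0.0, mask_fraction, arena, rt, ct, rng).trials
    cts = make_dataset(n, 1.0, mask_fraction, arena, rt, ct, rng).trials
    return rts, cts


def paired_evaluation(params: RNNParams, trials: list, arena: ArenaConfig):
    """Roll out the RNN and its paired reactive control on each trial.

    Returns ``(rnn_rollouts, control_rollouts, metrics_df)`` where the tidy
    metrics frame has one row per (trial, model).
    """
    rollouts = rollout_batch(params, trials, arena)
    controls, rows = [], []
    for i, (tr, ro) in enumerate(zip(trials, rollouts)):
        ctrl = reactive_rollout(tr, ro.speeds, arena)
        controls.append(ctrl)
        ref_start, tgt_end = tr.rnn_start, tr.target.positions[-1]
        dev = normalized_deviation(ro.positions, ctrl.positions, arena)
        for model, traj, end_d in (("rnn", ro.positions, ro.end_distance),
                                   ("control", ctrl.positions, ctrl.end_distance)):
            rows.append({
                "trial_id": i,
                "kind": tr.kind,
                "model": model,
                "end_distance": end_d,
                "shortcut": shortcut_metric(traj, ref_start, tgt_end, arena),
                "normalized_deviation": dev,
            })
    return rollouts, controls, pd.DataFrame(rows)


def condition_stats(df: pd.DataFrame) -> dict:
    """Condition-level comparison of RNN vs control from a tidy metrics frame."""
    out = {}
    for kind, g in df.groupby("kind"):
        rnn = g[g.model == "rnn"]
        ctrl = g[g.model == "control"]
        D, pval = ks_two_sample(rnn.shortcut, ctrl.shortcut)
        out[kind] = {
            "n_trials": int(len(rnn)),
            "rnn_median_end_distance": float(rnn.end_distance.median()),
            "control_median_end_distance": float(ctrl.end_distance.median()),
            "rnn_median_shortcut": float(rnn.shortcut.median()),
            "control_median_shortcut": float(ctrl.shortcut.median()),
            "mean_normalized_deviation": float(rnn.normalized_deviation.mean()),
            "ks_D": D,
            "ks_p": pval,
            "wasserstein": wasserstein_1d(rnn.shortcut, ctrl.shortcut),
        }
    return out


def _write_manifest(out: Path, cfg: ExperimentConfig, p: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": cfg.name,
        "scale": cfg.scale,
        "package_version": __version__,
        "preset": {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _write_summary(out: Path, summary: dict) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def _history_frame(history) -> pd.DataFrame:
    return pd.DataFrame({
        "epoch": np.arange(len(history.epoch_loss)),
        "loss": history.epoch_loss,
        "rt_median": history.rt_median,
        "ct_median": history.ct_median,
    })


# ---------------------------------------------------------------------------
# experiment implementations


def _exp_pursuit_basic(cfg, out, p):
    arena, rt, ct = _setup(p)
    summary = {"seeds": {}}
    frames = []
    for seed in p["seeds"]:
        params, hist = _train_network(p, arena, rt, ct, seed)
        save_params(params, out / f"checkpoint_seed{seed}.h5")
        h = _history_frame(hist)
        h["seed"] = seed
        frames.append(h)
        rts, cts = _eval_sets(p, arena, rt, ct, seed)
        rt_end = [r.end_distance for r in rollout_batch(params, rts, arena)]
        ct_end = [r.end_distance for r in rollout_batch(params, cts, arena)]
        summary["seeds"][seed] = {
            "rt_median_end_distance": float(np.median(rt_end)),
            "ct_median_end_distance": float(np.median(ct_end)),
        }
    pd.concat(frames).to_csv(out / "history.csv", index=False)
    return summary


def _exp_predictivity(cfg, out, p):
    arena, rt, ct = _setup(p)
    summary = {"seeds": {}}
    frames = []
    for seed in p["seeds"]:
        params, _ = _train_network(p, arena, rt, ct, seed)
        rts, cts = _eval_sets(p, arena, rt, ct, seed)
        _, _, df = paired_evaluation(params, rts + cts, arena)
        df["seed"] = seed
        frames.append(df)
        summary["seeds"][seed] = condition_stats(df)
    pd.concat(frames).to_csv(out / "metrics.csv", index=False)
    return summary


def _exp_etu_analysis(cfg, out, p):
    arena, rt, ct = _setup(p)
    rng = np.random.default_rng(p["seeds"][0] + 17)
    params, _ = _train_network(p, arena, rt, ct, p["seeds"][0])
    rts, _ = _eval_sets(p, arena, rt, ct, p["seeds"][0])
    rollouts = rollout_batch(params, rts, arena)
    acts, ego = pool_population(rollouts, rts, arena)
    half = len(rts) // 2
    T = arena.T
    split_a = np.zeros(len(ego), bool)
    split_a[: half * T] = True
    res = classify_etus(acts, ego, split=(split_a, ~split_a),
                        n_shuffles=int(p["n_shuffles"]), rng=rng)
    pd.DataFrame({"unit": np.arange(params.N), "mrl": res.mrl,
                  "threshold": res.threshold, "is_etu": res.is_etu}).to_csv(
        out / "mrl.csv", index=False)
    fracs = [0.0, 0.1, 0.2, 0.4]
    curves = {}
    for ordering in ("highest_mrl", "lowest_mrl", "random"):
        curves[ordering] = ablation_curve(params, ordering, fracs, rts[:min(64, len(rts))],
                                          arena, mrl_values=res.mrl, rng=rng)
    rows = []
    for ordering, c in curves.items():
        for f in c.fractions:
            rows.append({"ordering": ordering, "fraction": f,
                         "mean_end_distance": float(np.mean(c.end_distances[f])),
                         "ks_p_vs_random": c.ks_p[f]})
    pd.DataFrame(rows).to_csv(out / "ablation.csv", index=False)
    shifts = list(range(-8, 9, 2))
    prof = time_shift_profile(rollouts, rts, arena, shifts,
                              n_shuffles=max(20, int(p["n_shuffles"]) // 2), rng=rng)
    pd.DataFrame({"shift": prof["shifts"], "mean_mrl": prof["mean_mrl"],
                  "etu_fraction": prof["etu_fraction"]}).to_csv(
        out / "time_shift.csv", index=False)
    return {"etu_fraction": res.etu_fraction,
            "peak_shift": int(prof["shifts"][int(np.argmax(prof["etu_fraction"]))])}


def _exp_masking_sweep(cfg, out, p):
    arena, rt, ct = _setup(p)
    rows, summary = [], {}
    for mask in p["masks"]:
        for seed in p["seeds"]:
            params, _ = _train_network(p, arena, rt, ct, seed, mask_fraction=mask)
            rts, cts = _eval_sets(p, arena, rt, ct, seed, mask_fraction=mask)
            _, _, df = paired_evaluation(params, rts + cts, arena)
            stats = condition_stats(df)
            for kind in stats:
                rows.append({"mask_fraction": mask, "seed": seed, "kind": kind, **stats[kind]})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "masking.csv", index=False)
    summary["by_mask"] = {
        str(m): g.groupby("kind")["rnn_median_end_distance"].mean().to_dict()
        for m, g in frame.groupby("mask_fraction")
    }
    return summary


def _exp_ct_fraction_sweep(cfg, out, p):
    arena, rt, ct = _setup(p)
    rows = []
    for frac in p["ct_fractions"]:
        for seed in p["seeds"]:
            params, _ = _train_network(p, arena, rt, ct, seed, ct_fraction=frac)
            _, cts = _eval_sets(p, arena, rt, ct, seed)
            _, _, df = paired_evaluation(params, cts, arena)
            stats = condition_stats(df)["CT"]
            rows.append({"ct_fraction_trained": frac, "seed": seed, **stats})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "ct_fraction.csv", index=False)
    slope = np.polyfit(frame.ct_fraction_trained, frame.wasserstein, 1)[0] \
        if frame.ct_fraction_trained.nunique() > 1 else float("nan")
    return {"wasserstein_vs_ct_fraction_slope": float(slope)}


def _exp_rank_sweep(cfg, out, p, loss_kind: str = "final_distance"):
    arena, rt, ct = _setup(p)
    rows, trial_rows = [], []
    for rank in p["ranks"]:
        for seed in p["seeds"]:
            params, _ = _train_network(p, arena, rt, ct, seed, rank=rank, loss_kind=loss_kind)
            rts, cts = _eval_sets(p, arena, rt, ct, seed)
            rollouts, _, df = paired_evaluation(params, rts + cts, arena)
            stats = condition_stats(df)
            acts = np.concatenate([r.activations for r in rollouts], axis=0)
            lat = latent_series(params, acts)
            for kind in stats:
                rows.append({
                    "rank": rank, "seed": seed, "kind": kind, **stats[kind],
                    "pca95_activations": pca95(acts),
                    "pca95_latents": pca95(lat),
                    "participation_ratio_activations": participation_ratio(acts),
                })
            sub = df[df.model == "rnn"]
            for _, r in sub.iterrows():
                trial_rows.append({"rank": rank, "seed": seed, "kind": r.kind,
                                   "shortcut": r.shortcut,
                                   "end_distance": r.end_distance,
                                   "normalized_deviation": r.normalized_deviation})
    pd.DataFrame(rows).to_csv(out / "rank_sweep.csv", index=False)
    pd.DataFrame(trial_rows).to_csv(out / "rank_sweep_trials.csv", index=False)
    frame = pd.DataFrame(rows)
    return {
        "ranks": list(p["ranks"]),
        "median_shortcut_by_rank": frame.groupby("rank")["rnn_median_shortcut"].mean().to_dict(),
        "wasserstein_by_rank": frame.groupby("rank")["wasserstein"].mean().to_dict(),
        "pca95_by_rank": frame.groupby("rank")["pca95_activations"].mean().to_dict(),
    }


def _exp_periodic_ct(cfg, out, p):
    arena, rt, ct = _setup(p, boundary="periodic")
    seed = p["seeds"][0]
    params, hist = _train_network(p, arena, rt, ct, seed, ct_fraction=0.5)
    rts, cts = _eval_sets(p, arena, rt, ct, seed)
    rt_roll = rollout_batch(params, rts, arena)
    ct_roll = rollout_batch(params, cts, arena)
    curves = distance_to_endpoint_curves(ct_roll, cts, arena)
    rows = []
    for k, c in curves.items():
        for t, v in enumerate(c):
            rows.append({"ct_start_index": k, "t": t, "mean_distance_to_endpoint": v})
    pd.DataFrame(rows).to_csv(out / "endpoint_curves.csv", index=False)
    waiting = []
    for ro, tr in zip(ct_roll, cts):
        dist = geodesic_distance(ro.positions, tr.target.positions[-1][None, :], arena)
        waiting.append(detect_waiting(dist, eps=arena.v_max_agent * arena.dt * 0.2,
                                      min_len=max(3, arena.T // 10)))
    frac_waiting = float(np.mean([len(w) > 0 for w in waiting]))
    _history_frame(hist).to_csv(out / "history.csv", index=False)
    return {
        "rt_median_end_distance": float(np.median([r.end_distance for r in rt_roll])),
        "ct_median_end_distance": float(np.median([r.end_distance for r in ct_roll])),
        "fraction_ct_trials_with_waiting": frac_waiting,
    }


def _exp_decoding_sweep(cfg, out, p):
    arena, rt, ct = _setup(p)
    shifts = p.get("decode_shifts", (-8, -4, 0, 4, 8))
    rows = []
    for rank in p["ranks"]:
        for seed in p["seeds"]:
            params, _ = _train_network(p, arena, rt, ct, seed, rank=rank)
            rts, cts = _eval_sets(p, arena, rt, ct, seed)
            for kind, trials in (("RT", rts), ("CT", cts)):
                trials = trials[:min(len(trials), 60)]
                rollouts = rollout_batch(params, trials, arena)
                acts = np.concatenate([r.activations for r in rollouts], axis=0)
                gids = np.repeat(np.arange(len(trials)), arena.T)
                feats = {
                    "ego_distance": np.concatenate(
                        [np.linalg.norm(tr.target.positions - ro.positions, axis=-1)
                         for ro, tr in zip(rollouts, trials)]),
                    "target_position": np.concatenate(
                        [tr.target.positions for tr in trials], axis=0),
                    "self_position": np.concatenate(
                        [ro.positions for ro in rollouts], axis=0),
                }
                for fname, f in feats.items():
                    for s in shifts:
                        res = linear_decode(acts, f, gids, shift=int(s),
                                            rng=np.random.default_rng(seed + 7),
                                            feature_name=fname)
                        rows.append({"rank": rank, "seed": seed, "kind": kind,
                                     "feature": fname, "shift": s, "error": res.error,
                                     "r2": res.r2, "shuffle_error": res.shuffle_error})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "decoding.csv", index=False)
    shift0 = frame[frame["shift"] == 0]
    return {
        "median_error_by_rank_feature": {
            f"{f}_rank{r}": float(g.error.median())
            for (f, r), g in shift0.groupby(["feature", "rank"])
        }
    }


def _exp_unit_count_sweep(cfg, out, p):
    arena, rt, ct = _setup(p)
    rank = int(p.get("sweep_rank", min(p["ranks"])))
    rows = []
    for N in p["unit_counts"]:
        for seed in p["seeds"]:
            params, _ = _train_network(p, arena, rt, ct, seed, rank=min(rank, N), N=N)
            rts, cts = _eval_sets(p, arena, rt, ct, seed)
            _, _, df = paired_evaluation(params, rts + cts, arena)
            for kind, s in condition_stats(df).items():
                rows.append({"N": N, "seed": seed, "kind": kind, **s})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "unit_count.csv", index=False)
    return {"median_shortcut_by_N": frame.groupby("N")["rnn_median_shortcut"].mean().to_dict()}


_RUNNERS = {
    "pursuit_basic": _exp_pursuit_basic,
    "predictivity": _exp_predictivity,
    "etu_analysis": _exp_etu_analysis,
    "masking_sweep": _exp_masking_sweep,
    "ct_fraction_sweep": _exp_ct_fraction_sweep,
    "rank_sweep": _exp_rank_sweep,
    "periodic_ct": _exp_periodic_ct,
    "decoding_sweep": _exp_decoding_sweep,
    "unit_count_sweep": _exp_unit_count_sweep,
}

EXPERIMENTS = tuple(_RUNNERS)


def _write_figures(out: Path) -> None:
    """Render quick-look figures from whatever CSVs the run produced."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def save(fig, name):
        fig.tight_layout()
        fig.savefig(out / name, dpi=120)
        plt.close(fig)

    if (out / "history.csv").exists():
        h = pd.read_csv(out / "history.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for seed, g in (h.groupby("seed") if "seed" in h else ((0, h),)):
            ax.plot(g.epoch, g.loss, label=f"seed {seed}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss (m)")
        ax.legend(frameon=False)
        save(fig, "training_loss.png")
    if (out / "metrics.csv").exists():
        m = pd.read_csv(out / "metrics.csv")
        fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharey=True)
        for ax, kind in zip(axes, ("RT", "CT")):
            g = m[m.kind == kind]
            for model, sub in g.groupby("model"):
                ax.hist(sub.shortcut, bins=30, alpha=0.6, label=model)
            ax.set_title(kind)
            ax.set_xlabel("shortcut metric (m)")
            ax.legend(frameon=False)
        save(fig, "shortcut_distributions.png")
    if (out / "rank_sweep.csv").exists():
        r = pd.read_csv(out / "rank_sweep.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        med = r.groupby("rank")["rnn_median_shortcut"].mean()
        ax.plot(med.index, med.values, marker="o")
        ax.set_xscale("log", base=2)
        ax.set_xlabel("recurrent rank")
        ax.set_ylabel("median shortcut metric (m)")
        save(fig, "shortcut_vs_rank.png")
    if (out / "decoding.csv").exists():
        d = pd.read_csv(out / "decoding.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for feat, g in d.groupby("feature"):
            prof = g.groupby("shift")["error"].median()
            ax.plot(prof.index, prof.values, marker="o", label=feat)
        ax.set_xlabel("time shift (steps)")
        ax.set_ylabel("median decode error (m)")
        ax.legend(frameon=False)
        save(fig, "decoding_vs_shift.png")
    if (out / "time_shift.csv").exists():
        t = pd.read_csv(out / "time_shift.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(t["shift"], t["mean_mrl"], marker="o")
        ax.set_xlabel("time shift (steps)")
        ax.set_ylabel("mean MRL")
        save(fig, "mrl_vs_shift.png")


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Execute the named experiment; returns the results directory."""
    p = cfg.preset()
    out = Path(cfg.out_dir) / cfg.name
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(out, cfg, p)
    summary = _RUNNERS[cfg.name](cfg, out, p)
    _write_summary(out, summary)
    if cfg.figures:
        _write_figures(out)
    return out
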