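"""Representational analyses of trained pursuit networks.

Covers: egocentric target coordinates (distance and bearing relative to the
agent's heading), bearing/distance ratemaps, the mean resultant length
(MRL) of a unit's bearing tuning with a time-shuffle null, classification
of egocentric target units (ETUs), prospective/retrospective time-shift
profiles, dimensionality estimates (PCA-95 count and participation ratio),
and ridge-regression decoding of task features from population activity.

The MRL of a bearing tuning curve w(theta) is |sum w e^{i theta}| / sum w.
Because unit activations are signed (tanh), the occupancy-normalized tuning
curve is shifted by its minimum before the circular average, making the
weights non-negative as they would be for biological firing rates. The
statistic is 0 for flat tuning and 1 for a single-bin delta, and is
invariant to adding a constant to, or positively rescaling, the
activations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeCV
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold

from .arena_targets import ArenaConfig, Trial, displacement
from .pursuit_rnn import RNNParams, RolloutResult

__all__ = [
    "EgoSamples",
    "Ratemap",
    "MRLResult",
    "DimensionalityResult",
    "DecodeResult",
    "egocentric_coords",
    "pool_population",
    "ego_ratemap",
    "mrl",
    "shuffle_mrl",
    "classify_etus",
    "time_shift_profile",
    "pca95",
    "participation_ratio",
    "latent_series",
    "linear_decode",
]


def _wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2 * np.pi)


@dataclass
class EgoSamples:
    """Egocentric target coordinates of each time sample.

    ``bearing`` is counterclockwise in (-pi, pi], 0 = straight ahead of the
    agent's heading (so +pi/2 is to the agent's left). Samples taken before
    the agent first moves have no defined heading (``valid`` False).
    """

    distance: np.ndarray
    bearing: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return self.distance.shape[0]

    @staticmethod
    def concatenate(parts: list) -> "EgoSamples":
        return EgoSamples(
            distance=np.concatenate([p.distance for p in parts]),
            bearing=np.concatenate([p.bearing for p in parts]),
            valid=np.concatenate([p.valid for p in parts]),
        )


@dataclass
class Ratemap:
    """Mean activation binned by egocentric (bearing, distance)."""

    rates: np.ndarray  # (n_bearing, n_dist); NaN where masked
    occupancy: np.ndarray  # (n_bearing, n_dist) sample counts
    mask: np.ndarray  # True where occupancy >= min_occ
    bearing_edges: np.ndarray
    distance_edges: np.ndarray


@dataclass
class MRLResult:
    """Per-unit MRL statistics and ETU classification."""

    mrl: np.ndarray  # (N,)
    threshold: np.ndarray  # (N,) 99th percentile of the per-unit null
    split_mrls: np.ndarray  # (2, N)
    split_thresholds: np.ndarray  # (2, N)
    is_etu: np.ndarray  # (N,) bool
    null: np.ndarray  # (n_shuffles, N) full-data shuffle MRLs

    @property
    def etu_fraction(self) -> float:
        return float(np.mean(self.is_etu))


@dataclass
class DimensionalityResult:
    pca95: int
    participation_ratio: float
    applied_to: str  # "activations" or "latents"


@dataclass
class DecodeResult:
    feature: str
    shift: int
    error: float  # median absolute (Euclidean for 2-D features) error, held out
    r2: float  # NaN when undefined (constant feature)
    shuffle_error: float


# ---------------------------------------------------------------------------
# egocentric coordinates


def egocentric_coords(rollout: RolloutResult, trial: Trial, arena: ArenaConfig) -> EgoSamples:
    """Target position in the agent's egocentric frame at every step."""
    d = displacement(trial.target.positions, rollout.positions, arena)
    distance = np.linalg.norm(d, axis=-1)
    bearing = _wrap_angle(np.arctan2(d[:, 1], d[:, 0]) - rollout.headings)
    return EgoSamples(distance=distance, bearing=bearing, valid=rollout.heading_valid.copy())


def pool_population(rollouts: list, trials: list, arena: ArenaConfig) -> tuple[np.ndarray, EgoSamples]:
    """Stack activations and egocentric samples across trials.

    Returns ``(activations (n_samples, N), EgoSamples)``.
    """
    acts = np.concatenate([r.activations for r in rollouts], axis=0)
    ego = EgoSamples.concatenate([egocentric_coords(r, t, arena) for r, t in zip(rollouts, trials)])
    return acts, ego


# ---------------------------------------------------------------------------
# ratemaps and MRL


def _bearing_bin_index(bearing: np.ndarray, n_bearing: int) -> np.ndarray:
    width = 2 * np.pi / n_bearing
    idx = np.floor((bearing + np.pi) / width).astype(int)
    return np.clip(idx, 0, n_bearing - 1)


def ego_ratemap(
    unit_activations: np.ndarray,
    ego: EgoSamples,
    n_bearing: int = 36,
    n_dist: int = 10,
    min_occ: int = 20,
) -> Ratemap:
    """Average a unit's activation on an egocentric (bearing, distance) grid."""
    act = np.asarray(unit_activations, float)
    if act.shape[0] != len(ego):
        raise ValueError("activations and ego samples must align")
    v = ego.valid
    if not np.any(v):
        raise ValueError("no valid egocentric samples")
    bearing, dist, act = ego.bearing[v], ego.distance[v], act[v]
    b_edges = np.linspace(-np.pi, np.pi, n_bearing + 1)
    d_max = float(dist.max()) if dist.max() > 0 else 1.0
    d_edges = np.linspace(0.0, d_max * (1 + 1e-12), n_dist + 1)
    bi = _bearing_bin_index(bearing, n_bearing)
    di = np.clip(np.searchsorted(d_edges, dist, side="right") - 1, 0, n_dist - 1)
    flat = bi * n_dist + di
    occ = np.bincount(flat, minlength=n_bearing * n_dist).astype(float)
    sums = np.bincount(flat, weights=act, minlength=n_bearing * n_dist)
    with np.errstate(invalid="ignore"):
        rates = sums / occ
    occ = occ.reshape(n_bearing, n_dist)
    rates = rates.reshape(n_bearing, n_dist)
    mask = occ >= min_occ
    rates[~mask] = np.nan
    return Ratemap(rates=rates, occupancy=occ, mask=mask,
                   bearing_edges=b_edges, distance_edges=d_edges)


def _mrl_from_bin_means(means: np.ndarray, occupied: np.ndarray, n_bearing: int) -> np.ndarray:
    """MRL per unit from bearing-bin mean activations.

    ``means``: (n_bearing, N); ``occupied``: (n_bearing,) bool.
    """
    centers = (np.arange(n_bearing) + 0.5) * 2 * np.pi / n_bearing - np.pi
    occ_idx = np.flatnonzero(occupied)
    if occ_idx.size == 0:
        raise ValueError("no occupied bearing bins")
    if occ_idx.size == 1:
        warnings.warn("single occupied bearing bin: MRL degenerate (=1)")
        return np.ones(means.shape[1])
    w = means[occ_idx]  # (n_occ, N)
    scale = np.abs(w).max(axis=0)
    w = w - w.min(axis=0, keepdims=True)
    denom = w.sum(axis=0)
    # constant tuning leaves only floating-point residue after min
    # subtraction; treat it as flat rather than amplifying the noise
    denom[denom <= 1e-9 * np.maximum(scale, 1e-300)] = 0.0
    phase = np.exp(1j * centers[occ_idx])
    num = np.abs(phase @ w)
    out = np.zeros(means.shape[1])
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return np.clip(out, 0.0, 1.0)


def mrl(unit_activations: np.ndarray, ego: EgoSamples, n_bearing: int = 36) -> float:
    """Mean resultant length of one unit's bearing tuning (0 flat, 1 delta)."""
    act = np.asarray(unit_activations, float)[ego.valid]
    bi = _bearing_bin_index(ego.bearing[ego.valid], n_bearing)
    counts = np.bincount(bi, minlength=n_bearing)
    sums = np.bincount(bi, weights=act, minlength=n_bearing)
    means = np.zeros((n_bearing, 1))
    occ = counts > 0
    means[occ, 0] = sums[occ] / counts[occ]
    return float(_mrl_from_bin_means(means, occ, n_bearing)[0])


def _population_mrl(acts2d: np.ndarray, bins: np.ndarray, n_bearing: int) -> np.ndarray:
    """MRL for every unit at once; ``acts2d`` (n, N) over valid samples."""
    counts = np.bincount(bins, minlength=n_bearing)
    occ = counts > 0
    means = np.zeros((n_bearing, acts2d.shape[1]))
    order = np.argsort(bins, kind="stable")
    boundaries = np.searchsorted(bins[order], np.arange(n_bearing))
    boundaries = np.minimum(boundaries, bins.shape[0] - 1)  # reduceat bound
    sums = np.add.reduceat(acts2d[order], boundaries, axis=0)
    # reduceat repeats the row where a bin is empty; zero those out
    sums[~occ] = 0.0
    means[occ] = sums[occ] / counts[occ, None]
    return _mrl_from_bin_means(means, occ, n_bearing)


def shuffle_mrl(
    unit_activations: np.ndarray,
    ego: EgoSamples,
    n_bearing: int = 36,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null MRL distribution from time-shuffled activations (one unit)."""
    if rng is None:
        rng = np.random.default_rng(0)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    act = np.asarray(unit_activations, float)[ego.valid]
    bins = _bearing_bin_index(ego.bearing[ego.valid], n_bearing)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(act.shape[0])
        out[s] = _population_mrl(act[perm, None], bins, n_bearing)[0]
    return out


def classify_etus(
    activations: np.ndarray,
    ego: EgoSamples,
    split: tuple | None = None,
    n_bearing: int = 36,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> MRLResult:
    """Classify egocentric target units across a population.

    A unit is an ETU when its full-data MRL exceeds the 99th percentile of
    its time-shuffle null AND each of the two data splits independently
    exceeds the corresponding split null's 99th percentile (the consistency
    requirement). ``split`` gives two boolean sample masks; by default the
    first and second halves of the samples (a split by trial when samples
    are concatenated trial-by-trial).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    acts = np.asarray(activations, float)
    v = ego.valid
    acts_v = acts[v]
    bins_v = _bearing_bin_index(ego.bearing[v], n_bearing)
    n = acts_v.shape[0]
    if split is None:
        half = np.zeros(len(ego), dtype=bool)
        half[: len(ego) // 2] = True
        split = (half, ~half)
    m_a, m_b = (np.asarray(s, bool)[v] for s in split)
    if not (np.any(m_a) and np.any(m_b)):
        raise ValueError("both split halves must contain valid samples")

    def _null(sub_acts, sub_bins):
        out = np.empty((n_shuffles, acts.shape[1]))
        for s in range(n_shuffles):
            perm = rng.permutation(sub_acts.shape[0])
            out[s] = _population_mrl(sub_acts[perm], sub_bins, n_bearing)
        return out

    full_mrl = _population_mrl(acts_v, bins_v, n_bearing)
    null = _null(acts_v, bins_v)
    thr = np.percentile(null, 99, axis=0)
    split_mrls = np.empty((2, acts.shape[1]))
    split_thr = np.empty((2, acts.shape[1]))
    for i, m in enumerate((m_a, m_b)):
        split_mrls[i] = _population_mrl(acts_v[m], bins_v[m], n_bearing)
        split_thr[i] = np.percentile(_null(acts_v[m], bins_v[m]), 99, axis=0)
    is_etu = (full_mrl > thr) & np.all(split_mrls > split_thr, axis=0)
    return MRLResult(mrl=full_mrl, threshold=thr, split_mrls=split_mrls,
                     split_thresholds=split_thr, is_etu=is_etu, null=null)


# ---------------------------------------------------------------------------
# time-shift (prospective/retrospective) analysis


def _shifted_ego(rollout, trial, arena, shift: int) -> tuple[np.ndarray, EgoSamples]:
    """Pair activations at t with the target's position at t + shift."""
    T = trial.T
    if abs(shift) >= T:
        raise ValueError("|shift| must be < T")
    t0, t1 = max(0, -shift), min(T, T - shift)
    idx = np.arange(t0, t1)
    d = displacement(trial.target.positions[idx + shift], rollout.positions[idx], arena)
    bearing = _wrap_angle(np.arctan2(d[:, 1], d[:, 0]) - rollout.headings[idx])
    ego = EgoSamples(distance=np.linalg.norm(d, axis=-1), bearing=bearing,
                     valid=rollout.heading_valid[idx].copy())
    return rollout.activations[idx], ego


def time_shift_profile(
    rollouts,
    trials,
    arena: ArenaConfig,
    shifts,
    n_bearing: int = 36,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean MRL and ETU fraction when re-pairing activity with shifted targets.

    Positive shifts are prospective (activity at t vs target at t + k).
    Accepts a single rollout/trial or aligned lists; samples are pooled.
    Returns a dict with keys ``shifts``, ``mean_mrl``, ``etu_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not isinstance(rollouts, (list, tuple)):
        rollouts, trials = [rollouts], [trials]
    shifts = list(shifts)
    mean_mrl, etu_frac = [], []
    for s in shifts:
        parts = [_shifted_ego(r, t, arena, s) for r, t in zip(rollouts, trials)]
        acts = np.concatenate([p[0] for p in parts], axis=0)
        ego = EgoSamples.concatenate([p[1] for p in parts])
        res = classify_etus(acts, ego, n_bearing=n_bearing, n_shuffles=n_shuffles,
                            rng=np.random.default_rng(rng.integers(2**31 - 1)))
        mean_mrl.append(float(np.mean(res.mrl)))
        etu_frac.append(res.etu_fraction)
    return {"shifts": shifts, "mean_mrl": np.array(mean_mrl), "etu_fraction": np.array(etu_frac)}


# ---------------------------------------------------------------------------
# dimensionality


def _cov_eigenvalues(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    return s**2 / (X.shape[0] - 1)


def pca95(X: np.ndarray) -> int:
    """Number of principal components explaining 95% of the variance."""
    lam = _cov_eigenvalues(X)
    total = lam.sum()
    if total <= 0:
        warnings.warn("zero-variance data: pca95 undefined (returning 0)")
        return 0
    frac = np.cumsum(lam) / total
    return int(np.searchsorted(frac, 0.95 - 1e-12) + 1)


def participation_ratio(X: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 over covariance eigenvalues."""
    lam = _cov_eigenvalues(X)
    denom = np.sum(lam**2)
    if denom <= 0:
        warnings.warn("zero-variance data: participation ratio undefined")
        return float("nan")
    return float(lam.sum() ** 2 / denom)


def latent_series(params: RNNParams, activations: np.ndarray) -> np.ndarray:
    """Rank-dimensional latent projection kappa = Q.T tanh(h) / N.

    These are the coordinates that drive the recurrent dynamics of a
    low-rank network; their covariance measures the dimensionality of the
    latent code.
    """
    return np.asarray(activations, float) @ params.Q / params.N


# ---------------------------------------------------------------------------
# linear decoding


def linear_decode(
    activations: np.ndarray,
    feature_series: np.ndarray,
    trial_ids: np.ndarray,
    shift: int = 0,
    alphas=(1e-3, 1e-1, 1e1, 1e3),
    cv_folds: int = 5,
    rng: np.random.Generator | None = None,
    n_shuffle_repeats: int = 3,
    feature_name: str = "feature",
) -> DecodeResult:
    """Cross-validated ridge decoding of a task feature from population activity.

    Activations at time t are regressed onto the feature at t + shift
    (within trial; overhanging samples dropped). Folds are split by trial,
    never by time sample, to avoid within-trial leakage; the ridge penalty
    is selected among ``alphas`` on the training folds. The error is the
    median absolute error on held-out trials (Euclidean norm for 2-D
    features). The shuffle baseline runs the same pipeline with features
    permuted across whole trials.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(activations, float)
    y = np.asarray(feature_series, float)
    gids = np.asarray(trial_ids)
    if y.ndim == 1:
        y = y[:, None]
    uniq = np.unique(gids)
    if uniq.size < cv_folds:
        raise ValueError("fewer trials than folds")

    # apply the time shift within each trial
    keep_X, keep_y, keep_g = [], [], []
    for g in uniq:
        m = np.flatnonzero(gids == g)
        T = m.size
        t0, t1 = max(0, -shift), min(T, T - shift)
        keep_X.append(X[m[t0:t1]])
        keep_y.append(y[m[np.arange(t0, t1) + shift]])
        keep_g.append(np.full(t1 - t0, g))
    Xs = np.concatenate(keep_X)
    ys = np.concatenate(keep_y)
    gs = np.concatenate(keep_g)

    def _run(yy):
        errs, preds, trues = [], [], []
        for tr_idx, te_idx in GroupKFold(n_splits=cv_folds).split(Xs, yy, gs):
            model = RidgeCV(alphas=list(alphas))
            model.fit(Xs[tr_idx], yy[tr_idx])
            p = model.predict(Xs[te_idx])
            if p.ndim == 1:
                p = p[:, None]
            e = np.linalg.norm(p - yy[te_idx], axis=-1) if yy.shape[1] == 2 \
                else np.abs(p - yy[te_idx]).ravel()
            errs.append(e)
            preds.append(p)
            trues.append(yy[te_idx])
        preds = np.concatenate(preds)
        trues = np.concatenate(trues)
        err = float(np.median(np.concatenate(errs)))
        if np.all(np.var(trues, axis=0) < 1e-30):
            r2 = float("nan")
        else:
            r2 = float(r2_score(trues, preds))
        return err, r2

    error, r2 = _run(ys)

    # shuffle baseline: permute features across whole trials
    shuffle_errs = []
    lengths = {g: np.sum(gs == g) for g in uniq}
    for _ in range(n_shuffle_repeats):
        perm = rng.permutation(uniq)
        mapping = dict(zip(uniq, perm))
        y_shuf = np.empty_like(ys)
        for g in uniq:
            src = mapping[g]
            n_g, n_s = lengths[g], lengths[src]
            block = ys[gs == src]
            if n_s < n_g:  # pad by repeating the last sample (unequal shifts)
                block = np.vstack([block, np.repeat(block[-1:], n_g - n_s, axis=0)])
            y_shuf[gs == g] = block[:n_g]
        shuffle_errs.append(_run(y_shuf)[0])
    return DecodeResult(feature=feature_name, shift=shift, error=error, r2=r2,
                       shuffle_error=float(np.median(shuffle_errs)))
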