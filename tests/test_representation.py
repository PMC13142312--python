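"""Egocentric coordinates, MRL/ETU statistics, dimensionality, decoding."""

import numpy as np
import pytest

import pursuitnet as pn
from pursuitnet.arena_targets import TargetTrajectory, Trial
from pursuitnet.pursuit_rnn import RolloutResult
from pursuitnet.representation_analysis import (
    EgoSamples,
    ego_ratemap,
    latent_series,
    linear_decode,
    mrl,
    shuffle_mrl,
    time_shift_profile,
)


def make_rollout(positions, headings, activations=None, heading_valid=None):
    positions = np.asarray(positions, float)
    T = positions.shape[0]
    if activations is None:
        activations = np.zeros((T, 1))
    if heading_valid is None:
        heading_valid = np.ones(T, bool)
    return RolloutResult(
        activations=np.asarray(activations, float),
        out_velocities=np.zeros((T, 2)),
        positions=positions,
        headings=np.asarray(headings, float),
        heading_valid=np.asarray(heading_valid, bool),
        end_distance=0.0,
    )


def make_trial(target_positions, arena, kind="RT"):
    target_positions = np.asarray(target_positions, float)
    traj = TargetTrajectory(positions=target_positions,
                            velocities=np.zeros_like(target_positions),
                            kind=kind, ct_start_index=None)
    return Trial(target=traj, rnn_start=target_positions[0].copy(),
                 mask=np.ones(target_positions.shape[0], bool))


def uniform_bearing_ego(n, rng=None, distance=0.3):
    """EgoSamples with bearings uniform on (-pi, pi]."""
    if rng is None:
        bearing = -np.pi + (np.arange(n) + 0.5) * 2 * np.pi / n
    else:
        bearing = rng.uniform(-np.pi, np.pi, n)
    return EgoSamples(distance=np.full(n, distance), bearing=bearing,
                      valid=np.ones(n, bool))


class TestEgocentricCoords:
    def test_target_ahead_and_left(self, arena):
        ro = make_rollout([[0.5, 0.5]] * 2, [0.0, np.pi / 2])
        tr = make_trial([[0.7, 0.5], [0.7, 0.5]], arena)
        ego = pn.egocentric_coords(ro, tr, arena)
        np.testing.assert_allclose(ego.distance, 0.2)
        # heading east: target ahead (bearing 0); heading north: target right
        assert ego.bearing[0] == pytest.approx(0.0, abs=1e-12)
        assert ego.bearing[1] == pytest.approx(-np.pi / 2, abs=1e-12)

    def test_bearing_counterclockwise_positive_left(self, arena):
        ro = make_rollout([[0.5, 0.5]], [0.0])
        tr = make_trial([[0.5, 0.7]], arena)
        ego = pn.egocentric_coords(ro, tr, arena)
        assert ego.bearing[0] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_periodic_through_wall_bearing_zero(self, periodic_arena):
        """Agent near one wall heading east; target just past the opposite
        wall is 'ahead through the wall' under the minimal image."""
        ro = make_rollout([[0.95, 0.5]], [0.0])
        tr = make_trial([[0.05, 0.5]], periodic_arena)
        ego = pn.egocentric_coords(ro, tr, periodic_arena)
        assert ego.distance[0] == pytest.approx(0.1, abs=1e-12)
        assert ego.bearing[0] == pytest.approx(0.0, abs=1e-12)

    def test_prestart_samples_marked_invalid(self, arena):
        ro = make_rollout([[0.5, 0.5]] * 3, [0.0] * 3,
                          heading_valid=[False, True, True])
        tr = make_trial([[0.7, 0.5]] * 3, arena)
        ego = pn.egocentric_coords(ro, tr, arena)
        np.testing.assert_array_equal(ego.valid, [False, True, True])


class TestRatemap:
    def test_recovers_bin_means(self):
        rng = np.random.default_rng(0)
        n = 20_000
        ego = uniform_bearing_ego(n, rng)
        ego.distance[:] = rng.uniform(0, 1, n)
        act = np.cos(ego.bearing)
        rm = ego_ratemap(act, ego, n_bearing=12, n_dist=4, min_occ=20)
        centers = (rm.bearing_edges[:-1] + rm.bearing_edges[1:]) / 2
        for i, c in enumerate(centers):
            got = rm.rates[i][rm.mask[i]]
            assert np.all(np.abs(got - np.cos(c)) < 0.05)

    def test_low_occupancy_bins_masked_nan(self):
        ego = uniform_bearing_ego(100)
        rm = ego_ratemap(np.ones(100), ego, n_bearing=36, n_dist=10, min_occ=20)
        assert not rm.mask.any()
        assert np.isnan(rm.rates).all()

    def test_occupancy_counts_sum(self):
        ego = uniform_bearing_ego(500, np.random.default_rng(1))
        rm = ego_ratemap(np.zeros(500), ego, n_bearing=8, n_dist=3, min_occ=1)
        assert rm.occupancy.sum() == 500


class TestMRL:
    def test_flat_tuning_zero(self):
        ego = uniform_bearing_ego(3600)
        assert mrl(np.ones(3600), ego) == 0.0

    def test_single_bin_degenerate_one(self):
        n = 100
        ego = EgoSamples(distance=np.full(n, 0.2), bearing=np.zeros(n),
                         valid=np.ones(n, bool))
        with pytest.warns(UserWarning, match="single occupied"):
            assert mrl(np.random.default_rng(0).normal(size=n), ego) == 1.0

    def test_one_plus_cosine_half(self):
        """w(theta) = 1 + cos(theta) on fine uniform bins has MRL 1/2."""
        n_bins = 720
        ego = uniform_bearing_ego(n_bins)
        act = 1 + np.cos(ego.bearing)
        assert mrl(act, ego, n_bearing=n_bins) == pytest.approx(0.5, abs=1e-3)
        # numerical-integration oracle |int w e^{i theta}| / int w on the bins
        w = act - act.min()
        oracle = np.abs(np.sum(w * np.exp(1j * ego.bearing))) / np.sum(w)
        assert mrl(act, ego, n_bearing=n_bins) == pytest.approx(oracle, abs=1e-12)

    def test_invariance_to_offset_and_positive_scale(self):
        rng = np.random.default_rng(2)
        ego = uniform_bearing_ego(5000, rng)
        act = np.tanh(rng.normal(size=5000) + np.cos(ego.bearing))
        base = mrl(act, ego)
        assert mrl(act + 3.7, ego) == pytest.approx(base, abs=1e-12)
        assert mrl(act * 0.21, ego) == pytest.approx(base, abs=1e-12)

    def test_range(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ego = uniform_bearing_ego(500, rng)
            val = mrl(rng.normal(size=500), ego)
            assert 0.0 <= val <= 1.0


class TestShuffleNull:
    def test_constant_unit_all_zero(self):
        ego = uniform_bearing_ego(2000, np.random.default_rng(0))
        null = shuffle_mrl(np.full(2000, 0.4), ego, n_shuffles=20)
        np.testing.assert_array_equal(null, 0.0)

    def test_iid_noise_null_concentrated_low(self):
        rng = np.random.default_rng(1)
        n = 10_000
        ego = uniform_bearing_ego(n, rng)
        act = rng.normal(size=n)
        null = shuffle_mrl(act, ego, n_shuffles=100, rng=rng)
        assert np.percentile(null, 99) < 0.2

    def test_tuned_unit_beats_own_null(self):
        rng = np.random.default_rng(2)
        n = 10_000
        ego = uniform_bearing_ego(n, rng)
        act = np.cos(ego.bearing) + 0.3 * rng.normal(size=n)
        null = shuffle_mrl(act, ego, n_shuffles=100, rng=rng)
        assert mrl(act, ego) > np.percentile(null, 99)


class TestETUClassification:
    def test_planted_units_recovered(self):
        """30 von Mises-tuned units among 70 noise units: >=90% hits, <=2-3 FP."""
        rng = np.random.default_rng(7)
        n, n_tuned, n_units = 12_000, 30, 100
        ego = uniform_bearing_ego(n, rng)
        acts = rng.normal(0, 1, size=(n, n_units))
        kappa = 2.0
        mus = rng.uniform(-np.pi, np.pi, n_tuned)
        for j in range(n_tuned):
            acts[:, j] += np.exp(kappa * np.cos(ego.bearing - mus[j]))
        res = pn.classify_etus(acts, ego, n_shuffles=100, rng=rng)
        assert res.is_etu[:n_tuned].sum() >= 27
        assert res.is_etu[n_tuned:].sum() <= 3
        assert 0.0 <= res.etu_fraction <= 1.0
        # invariant: flagged implies exceeding all three thresholds
        flagged = np.flatnonzero(res.is_etu)
        assert np.all(res.mrl[flagged] > res.threshold[flagged])
        assert np.all(res.split_mrls[:, flagged] > res.split_thresholds[:, flagged])

    def test_inconsistent_unit_rejected(self):
        """A unit tuned in one half but not the other fails the split check."""
        rng = np.random.default_rng(8)
        n = 8000
        ego = uniform_bearing_ego(n, rng)
        act = rng.normal(0, 0.2, size=(n, 1))
        act[: n // 2, 0] += 2 * np.cos(ego.bearing[: n // 2])
        res = pn.classify_etus(act, ego, n_shuffles=100, rng=rng)
        assert not res.is_etu[0]


class TestTimeShiftProfile:
    def _pursuit_rollout(self, arena, rng, lag, noise=0.05, n_units=8):
        """A fixed-pose agent whose units encode the bearing of the target's
        position at t + lag, seen from the agent's pose at t."""
        T = arena.T
        pos = np.tile(rng.uniform(0.3, 0.7, 2), (T, 1))
        heading = rng.uniform(-np.pi, np.pi)
        tgt = np.full((T, 2), 0.5) + 0.03 * rng.standard_normal((T, 2)).cumsum(0)
        tgt = np.clip(tgt, 0.05, 0.95)
        trial = make_trial(tgt, arena)
        future = np.minimum(np.arange(T) + lag, T - 1)
        d = tgt[future] - pos
        bearing = np.arctan2(d[:, 1], d[:, 0]) - heading
        acts = np.column_stack([
            np.cos(bearing - mu) + noise * rng.standard_normal(T)
            for mu in np.linspace(0, 2 * np.pi, n_units, endpoint=False)
        ])
        return make_rollout(pos, np.full(T, heading), acts), trial

    def test_shift_zero_matches_base_classification(self, arena):
        rng = np.random.default_rng(0)
        ro, tr = self._pursuit_rollout(arena, rng, lag=0)
        prof = time_shift_profile(ro, tr, arena, shifts=[0], n_shuffles=50,
                                  rng=np.random.default_rng(1))
        ego = pn.egocentric_coords(ro, tr, arena)
        base = np.mean([mrl(ro.activations[:, j], ego)
                        for j in range(ro.activations.shape[1])])
        assert prof["mean_mrl"][0] == pytest.approx(base, abs=1e-12)

    def test_planted_lag_peaks_at_plus_five(self, arena):
        rng = np.random.default_rng(3)
        pairs = [self._pursuit_rollout(arena, rng, lag=5) for _ in range(20)]
        rollouts = [p[0] for p in pairs]
        trials = [p[1] for p in pairs]
        shifts = [-10, -5, 0, 5, 10]
        prof = time_shift_profile(rollouts, trials, arena, shifts, n_shuffles=20,
                                  rng=np.random.default_rng(4))
        assert shifts[int(np.argmax(prof["mean_mrl"]))] == 5

    def test_white_noise_profile_flat_and_low(self, arena):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0.2, 0.8, (arena.T, 2))
        ro = make_rollout(pos, rng.uniform(-np.pi, np.pi, arena.T),
                          activations=rng.normal(size=(arena.T, 5)))
        tr = make_trial(rng.uniform(0.2, 0.8, (arena.T, 2)), arena)
        prof = time_shift_profile(ro, tr, arena, shifts=[-5, 0, 5], n_shuffles=30,
                                  rng=np.random.default_rng(6))
        assert np.all(prof["etu_fraction"] == 0.0)


class TestDimensionality:
    def test_pr_eigenvalues_three_one(self):
        """Sample covariance diag(3, 1) gives PR (3+1)^2/(9+1) = 1.6."""
        s1, s2 = np.sqrt(4.5), np.sqrt(1.5)
        X = np.array([[s1, 0.0], [-s1, 0.0], [0.0, s2], [0.0, -s2]])
        assert pn.participation_ratio(X) == pytest.approx(1.6, abs=1e-12)

    def test_pr_isotropic_equals_dim(self):
        X = np.vstack([np.eye(4), -np.eye(4)])
        assert pn.participation_ratio(X) == pytest.approx(4.0, abs=1e-12)

    def test_pca95_planted_subspace(self):
        rng = np.random.default_rng(0)
        k, N = 6, 40
        X = rng.normal(size=(3000, k)) @ rng.normal(size=(k, N))
        assert pn.pca95(X) <= k
        assert pn.pca95(X) >= k - 1

    def test_brute_force_covariance_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 7))
        lam = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        pr_oracle = lam.sum() ** 2 / np.sum(lam**2)
        frac = np.cumsum(lam) / lam.sum()
        pca_oracle = int(np.searchsorted(frac, 0.95 - 1e-12) + 1)
        assert pn.participation_ratio(X) == pytest.approx(pr_oracle, abs=1e-10)
        assert pn.pca95(X) == pca_oracle

    def test_latent_series_projection(self):
        params = pn.init_rnn(30, 4, seed=0)
        acts = np.random.default_rng(0).uniform(-1, 1, (50, 30))
        lat = latent_series(params, acts)
        assert lat.shape == (50, 4)
        np.testing.assert_allclose(lat, acts @ params.Q / 30)

    def test_rollout_latent_dim_bounded_by_rank(self, arena, rt_params, ct_params):
        """The trained quantity of interest: latent PR never exceeds rank."""
        rng = np.random.default_rng(2)
        ts = pn.make_dataset(6, 0.5, 0.0, arena, rt_params, ct_params, rng)
        params = pn.init_rnn(64, 3, seed=1)
        lat = np.concatenate([latent_series(params, pn.rollout(params, t, arena).activations)
                              for t in ts])
        assert pn.participation_ratio(lat) <= 3.0 + 1e-9
        assert pn.pca95(lat) <= 3


class TestLinearDecode:
    def _make_data(self, rng, n_trials=10, T=60, N=30):
        W = rng.normal(size=(N, 2))
        feats, acts, gids = [], [], []
        for g in range(n_trials):
            f = rng.uniform(0, 1, (T, 2))
            feats.append(f)
            acts.append(f @ W.T)
            gids.append(np.full(T, g))
        return (np.concatenate(acts), np.concatenate(feats),
                np.concatenate(gids))

    def test_linearly_recoverable_feature(self):
        rng = np.random.default_rng(0)
        X, y, g = self._make_data(rng)
        res = linear_decode(X, y, g, rng=rng, feature_name="target_pos")
        assert res.error < 1e-2
        assert res.r2 > 0.99
        assert res.shuffle_error > 10 * res.error
        assert res.feature == "target_pos" and res.shift == 0

    def test_shift_pairs_activity_with_future_feature(self):
        rng = np.random.default_rng(1)
        n_trials, T, N, lag = 10, 60, 30, 4
        W = rng.normal(size=(N, 1))
        acts, feats, gids = [], [], []
        for g in range(n_trials):
            f = rng.uniform(0, 1, (T + lag, 1))
            feats.append(f[:T])
            acts.append(f[lag: T + lag] @ W.T)  # activity encodes t + lag
            gids.append(np.full(T, g))
        X = np.concatenate(acts)
        y = np.concatenate(feats)
        g = np.concatenate(gids)
        # decoding at the planted lag is near perfect, at 0 it is not
        res_lag = linear_decode(X, y, g, shift=lag, rng=rng)
        res_0 = linear_decode(X, y, g, shift=0, rng=rng)
        assert res_lag.error < 1e-6
        assert res_0.error > 100 * max(res_lag.error, 1e-12)

    def test_no_leakage_unrelated_feature(self):
        """iid activations cannot decode a random-walk feature better than
        the trial-permutation baseline."""
        rng = np.random.default_rng(2)
        n_trials, T = 10, 60
        X = rng.normal(size=(n_trials * T, 20))
        y = np.concatenate([np.cumsum(rng.normal(size=T)) for _ in range(n_trials)])
        g = np.repeat(np.arange(n_trials), T)
        res = linear_decode(X, y, g, rng=rng)
        assert res.error > 0.5 * res.shuffle_error
        assert res.r2 < 0.1

    def test_constant_feature_r2_nan(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 10))
        y = np.full(300, 0.7)
        g = np.repeat(np.arange(6), 50)
        res = linear_decode(X, y, g, rng=rng)
        assert np.isnan(res.r2)
        assert res.error < 1e-6

    def test_fewer_trials_than_folds_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        g = np.repeat(np.arange(2), 20)
        with pytest.raises(ValueError, match="fewer trials"):
            linear_decode(X, y, g, cv_folds=5)
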