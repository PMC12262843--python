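import numpy as np
import pytest
import scipy.linalg
from scipy.spatial.transform import Rotation

import tmrkit as tk
from tmrkit.landscape import feature_residues, model_features, trajectory_features


@pytest.fixture(scope="module")
def two_state(submap):
    spec = tk.SyntheticSpec(
        architectures=("TM2-TM3", "separated"), switch_rate=0.02,
        sigma=0.8, n_frames=800, seed=5,
    )
    traj, _, truth = tk.simulate_trajectory(spec, submap)
    feat = feature_residues(submap)
    ref = trajectory_features(traj, feat)[0].reshape(-1, 3)
    aligned = tk.align_trajectory(traj, ref, feat)
    features = trajectory_features(aligned, feat)
    return features, truth


class TestAlignTrajectory:
    def _rigid_trajectory(self, submap, n_frames=20, seed=0):
        model, _, _ = tk.build_bundle(tk.SyntheticSpec(sigma=0.0, seed=seed), submap)
        rng = np.random.default_rng(seed)
        frames = []
        for f in range(n_frames):
            rot = Rotation.random(random_state=seed * 100 + f).as_matrix()
            frames.append(model.coord @ rot.T + rng.normal(size=3) * 10)
        return tk.Trajectory(
            res_id=model.res_id,
            atom_name=np.full(model.n_atoms, "BB"),
            frames=np.array(frames),
        )

    def test_rigid_motion_removed(self, submap):
        traj = self._rigid_trajectory(submap)
        feat = feature_residues(submap)
        ref = trajectory_features(traj, feat)[0].reshape(-1, 3)
        aligned = tk.align_trajectory(traj, ref, feat)
        for f in range(traj.n_frames):
            assert tk.rmsd(aligned.frames[f], aligned.frames[0], superpose=False) < 1e-6

    def test_idempotent(self, submap):
        traj, _, _ = tk.simulate_trajectory(tk.SyntheticSpec(n_frames=20, seed=1), submap)
        feat = feature_residues(submap)
        ref = trajectory_features(traj, feat)[0].reshape(-1, 3)
        once = tk.align_trajectory(traj, ref, feat)
        twice = tk.align_trajectory(once, ref, feat)
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-8)

    def test_per_frame_rmsd_matches_kabsch_oracle(self, submap):
        traj, _, _ = tk.simulate_trajectory(
            tk.SyntheticSpec(sigma=1.0, n_frames=15, seed=2), submap
        )
        feat = feature_residues(submap)
        idx_coords = trajectory_features(traj, feat)
        ref = idx_coords[0].reshape(-1, 3)
        aligned = tk.align_trajectory(traj, ref, feat)
        aligned_feat = trajectory_features(aligned, feat)
        for f in range(traj.n_frames):
            oracle = tk.kabsch_superpose(idx_coords[f].reshape(-1, 3), ref)[2]
            fitted = tk.rmsd(aligned_feat[f].reshape(-1, 3), ref, superpose=False)
            assert fitted == pytest.approx(oracle, abs=1e-9)

    def test_rigid_trajectory_variance_vanishes(self, submap):
        traj = self._rigid_trajectory(submap)
        feat = feature_residues(submap)
        ref = trajectory_features(traj, feat)[0].reshape(-1, 3)
        aligned = tk.align_trajectory(traj, ref, feat)
        x = trajectory_features(aligned, feat)
        assert np.var(x - x.mean(axis=0), axis=0).sum() < 1e-10

    def test_degenerate_selection_rejected(self, submap):
        traj, _, _ = tk.simulate_trajectory(tk.SyntheticSpec(n_frames=5, seed=0), submap)
        with pytest.raises(ValueError):
            tk.align_trajectory(traj, np.zeros((2, 3)), traj.res_id[:2])


class TestFitPCA:
    def test_planar_variance(self, rng):
        x = np.zeros((100, 3))
        x[:, 0] = rng.normal(size=100)
        pca = tk.fit_pca(x)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_fractions(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10_000, 3))
        pca = tk.fit_pca(x)
        np.testing.assert_allclose(pca.explained_variance_ratio, 1 / 3, atol=0.02)

    def test_against_dense_eigensolver_oracle(self, rng):
        x = rng.normal(size=(50, 8)) @ rng.normal(size=(8, 8))
        pca = tk.fit_pca(x)
        cov = np.cov(x, rowvar=False)
        vals, vecs = scipy.linalg.eig(cov)  # independent non-symmetric route
        order = np.argsort(vals.real)[::-1]
        vals = vals.real[order]
        vecs = vecs.real[:, order]
        np.testing.assert_allclose(pca.eigenvalues, vals, atol=1e-8)
        for k in range(8):
            dot = abs(vecs[:, k] @ pca.components[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_fractions_sum_to_one(self, two_state):
        features, _ = two_state
        pca = tk.fit_pca(features)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_orthonormal(self, two_state):
        features, _ = two_state
        pca = tk.fit_pca(features)
        gram = pca.components.T @ pca.components
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(size=(40, 5))
        a = tk.fit_pca(x)
        b = tk.fit_pca(x.copy())
        np.testing.assert_array_equal(a.components, b.components)
        for k in range(5):
            j = np.argmax(np.abs(a.components[:, k]))
            assert a.components[j, k] > 0

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            tk.fit_pca(np.zeros((1, 4)))


class TestProject:
    def test_mean_maps_to_origin(self, two_state):
        features, _ = two_state
        pca = tk.fit_pca(features)
        np.testing.assert_allclose(tk.project(pca, pca.mean), 0.0, atol=1e-9)

    def test_full_reconstruction_lossless(self, rng):
        x = rng.normal(size=(30, 6))
        pca = tk.fit_pca(x)
        y = tk.project(pca, x)
        back = y @ pca.components.T + pca.mean
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_static_models_land_in_their_basin(self, submap, two_state):
        features, truth = two_state
        pca = tk.fit_pca(features, feature_residues(submap))
        proj = tk.project(pca, features, n_components=2)
        state = truth["state_per_frame"]
        centers = {s: proj[state == s].mean(axis=0) for s in (0, 1)}
        # held-out static models of both planted architectures
        for arch, state_idx in (("TM2-TM3", 0), ("separated", 1)):
            for seed in (101, 202, 303):
                model, _, _ = tk.build_bundle(
                    tk.SyntheticSpec(architecture=arch, sigma=0.5, seed=seed), submap
                )
                # superpose onto the PCA mean structure before projecting
                feats = model_features(model, feature_residues(submap))
                fitted = tk.superpose_coords(
                    feats.reshape(-1, 3), pca.mean.reshape(-1, 3)
                )
                p = tk.project(pca, fitted.reshape(-1), n_components=2)
                nearest = min(centers, key=lambda s: np.linalg.norm(p - centers[s]))
                assert nearest == state_idx

    def test_unmappable_particles_error(self, submap, two_state):
        features, _ = two_state
        pca = tk.fit_pca(features, feature_residues(submap))
        model, _, _ = tk.build_bundle(tk.SyntheticSpec(seed=0), submap)
        chopped = model.select(model.res_id != 620)
        with pytest.raises(ValueError, match="620"):
            tk.project(pca, chopped)


class TestFitTICA:
    def test_white_noise_timescales_below_lag(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5000, 4))
        tica = tk.fit_tica(x, lag=20)
        assert np.all(tica.timescales < 20)

    def test_two_state_markov_analytic_eigenvalue(self):
        # symmetric two-state jump process: lambda_1 = (1-2p)^lag
        p = 0.01
        lag = 10
        n = 100_000
        rng = np.random.default_rng(7)
        flips = rng.random(n) < p
        state = np.cumsum(flips) % 2
        x = np.column_stack([
            np.where(state == 0, -1.0, 1.0),
            rng.normal(scale=0.1, size=n),
        ])
        tica = tk.fit_tica(x, lag=lag)
        expected = (1 - 2 * p) ** lag
        assert tica.eigenvalues[0] == pytest.approx(expected, rel=0.1)

    def test_two_basin_separation(self, two_state):
        features, truth = two_state
        tica = tk.fit_tica(features, lag=5, n_components=2)
        ic1 = tica.transform(features)[:, 0]
        labels = tk.kmedoids(ic1[:, None], 2, seed=0).labels
        state = truth["state_per_frame"]
        purity = max(np.mean(labels == state), np.mean(labels != state))
        assert purity > 0.9

    def test_time_reversal_symmetry(self, two_state):
        features, _ = two_state
        fwd = tk.fit_tica(features, lag=5)
        rev = tk.fit_tica(features[::-1].copy(), lag=5)
        np.testing.assert_allclose(fwd.eigenvalues, rev.eigenvalues, atol=1e-8)

    def test_eigenvalue_bound(self, two_state):
        features, _ = two_state
        tica = tk.fit_tica(features, lag=10)
        assert np.all(np.abs(tica.eigenvalues) <= 1 + 1e-6)

    def test_segments_never_lagged_across_boundaries(self):
        # each segment is [v, v] with lag 1: every legal lagged pair is
        # perfectly autocorrelated (all eigenvalues 1); any cross-boundary
        # pairing of independent v's would pull eigenvalues below 1
        rng = np.random.default_rng(3)
        segments = [np.tile(rng.normal(size=(1, 3)), (2, 1)) for _ in range(60)]
        tica = tk.fit_tica(segments, lag=1)
        np.testing.assert_allclose(tica.eigenvalues, 1.0, atol=1e-8)

    def test_lag_too_long_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            tk.fit_tica(np.zeros((10, 2)), lag=10)


class TestDCC:
    def test_self_correlation_one(self, submap):
        traj, _, _ = tk.simulate_trajectory(
            tk.SyntheticSpec(sigma=1.0, n_frames=50, seed=4), submap
        )
        corr = tk.dcc(traj)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_identical_and_opposite_motion(self):
        rng = np.random.default_rng(0)
        motion = rng.normal(size=(100, 3))
        frames = np.stack(
            [np.stack([m, m, -m]) for m in motion]
        )  # particles: identical, identical, opposite
        traj = tk.Trajectory(
            res_id=np.array([1, 2, 3]),
            atom_name=np.array(["BB", "BB", "BB"]),
            frames=frames,
        )
        corr = tk.dcc(traj)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_coherent_hairpin_blocks(self, submap):
        traj, _, _ = tk.simulate_trajectory(
            tk.SyntheticSpec(sigma=1.0, tau=10.0, n_frames=2000, seed=8), submap
        )
        corr = tk.dcc(traj)
        # within-helix motion is rigid -> strong positive intra-helix blocks
        tm1 = np.isin(traj.res_id, submap.residues("TM1"))
        tm2 = np.isin(traj.res_id, submap.residues("TM2"))
        intra_tm1 = corr[np.ix_(tm1, tm1)]
        cross = corr[np.ix_(tm1, tm2)]
        assert intra_tm1.mean() > 0.9
        assert intra_tm1.mean() > abs(cross.mean()) + 0.3

    def test_zero_variance_particle_warns(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(50, 3, 3))
        frames[:, 2, :] = 5.0  # frozen particle
        traj = tk.Trajectory(
            res_id=np.array([1, 2, 3]),
            atom_name=np.array(["BB"] * 3),
            frames=frames,
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = tk.dcc(traj)
        assert np.all(corr[2, :] == 0) and np.all(corr[:, 2] == 0)

    def test_range_bound(self, submap):
        traj, _, _ = tk.simulate_trajectory(
            tk.SyntheticSpec(sigma=1.0, n_frames=60, seed=9), submap
        )
        corr = tk.dcc(traj)
        assert np.all(corr >= -1.0) and np.all(corr <= 1.0)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)


class TestDensity2D:
    def test_single_point(self):
        grid = tk.density2d(np.array([[1.0, 2.0]]), bins=10)
        assert grid.mass.sum() == pytest.approx(1.0)
        assert np.count_nonzero(grid.mass) == 1

    def test_two_blob_modes(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(500, 2))
        b = rng.normal(size=(500, 2)) + [12, 0]
        grid = tk.density2d(np.concatenate([a, b]), bins=40)
        assert len(grid.modes) == 2

    def test_uniform_grid_near_flat(self):
        xs, ys = np.meshgrid(np.linspace(0, 1, 30), np.linspace(0, 1, 30))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        grid = tk.density2d(pts, bins=6)
        occupied = grid.mass[grid.mass > 0]
        assert occupied.max() / occupied.min() < 1.5

    def test_mass_normalized(self, rng):
        grid = tk.density2d(rng.normal(size=(200, 2)), bins=20)
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-12)
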