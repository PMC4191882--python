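"""Superposition, RMSD/RMSF, PCA, clustering and distance series."""

import numpy as np
import pytest
import scipy.optimize

from kinodyn.enm import build_network, normal_modes, mode_overlap
from kinodyn.synthetic import make_planted_traj, make_two_lobe
from kinodyn.trajectory import (
    Trajectory, superpose, rmsf, pca, project, eigen_spectrum_fractions,
    cluster_leader, distance_series, _pairwise_rmsd,
)

from conftest import bead_structure


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_traj(frames, chain="A") -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    return Trajectory(template=bead_structure(frames[0], chain),
                      coords=frames)


class TestSuperpose:
    def test_rigid_copy_gives_zero_rmsd(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(-10, 10, (20, 3))
        moved = ref @ random_rotation(rng).T + np.array([3.0, -7.0, 1.0])
        fitted, rmsd = superpose(make_traj([moved]), ref)
        assert rmsd[0] < 1e-10
        np.testing.assert_allclose(fitted.coords[0], ref, atol=1e-9)

    def test_single_displaced_atom_closed_form(self):
        """Fit on the undisturbed atoms; total RMSD over all M atoms is
        then d/sqrt(M)."""
        rng = np.random.default_rng(1)
        ref = rng.uniform(-10, 10, (25, 3))
        d = 2.4
        frame = ref.copy()
        frame[0] += np.array([0, 0, d])
        fitted, _ = superpose(make_traj([frame]), ref,
                              selection=np.arange(1, 25))
        total = np.sqrt(((fitted.coords[0] - ref) ** 2).sum() / 25)
        assert total == pytest.approx(d / np.sqrt(25), rel=1e-10)

    def test_matches_brute_force_rotation_search(self):
        """Kabsch RMSD equals an independent numeric minimisation over
        rotation vectors (multi-start refine oracle)."""
        rng = np.random.default_rng(2)
        ref = rng.uniform(-8, 8, (50, 3))
        frame = ref + 0.6 * rng.standard_normal((50, 3))
        frame = frame @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        _, rmsd = superpose(make_traj([frame]), ref)

        refc = ref - ref.mean(0)
        framec = frame - frame.mean(0)

        def objective(rotvec):
            theta = np.linalg.norm(rotvec)
            if theta < 1e-12:
                R = np.eye(3)
            else:
                k = rotvec / theta
                K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]],
                              [-k[1], k[0], 0]])
                R = np.eye(3) + np.sin(theta) * K + \
                    (1 - np.cos(theta)) * K @ K
            return np.sqrt(((framec @ R.T - refc) ** 2).sum() / 50)

        best = min(
            scipy.optimize.minimize(objective, start, method="Nelder-Mead",
                                    options={"xatol": 1e-10,
                                             "fatol": 1e-12}).fun
            for start in [np.zeros(3), [1, 0, 0], [0, 2, 0], [2, 2, 2],
                          [-2, 1, -1], [0, 0, 3]])
        assert rmsd[0] == pytest.approx(best, abs=1e-6)

    def test_too_few_atoms_rejected(self):
        ref = np.eye(3) * 5
        with pytest.raises(ValueError):
            superpose(make_traj([ref]), ref, selection=[0, 1])


class TestRmsf:
    def test_constant_trajectory_zero(self):
        frames = np.repeat(np.random.default_rng(0).uniform(
            0, 10, (1, 12, 3)), 10, axis=0)
        assert rmsf(make_traj(frames), discard_fraction=0.0).max() < 1e-12

    def test_oscillating_atom_closed_form(self):
        base = np.random.default_rng(1).uniform(0, 10, (8, 3))
        a = 1.7
        frames = np.repeat(base[None], 10, axis=0)
        frames[::2, 0, 0] += a
        frames[1::2, 0, 0] -= a
        out = rmsf(make_traj(frames), discard_fraction=0.0)
        assert out[0] == pytest.approx(a, rel=1e-12)
        assert out[1:].max() < 1e-12

    def test_planted_variance_recovered(self):
        toy = make_two_lobe(seed=3)
        n3 = 3 * toy.structure.n_atoms
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.standard_normal((n3, 3)))
        variances = np.array([5.0, 3.0, 1.0])
        traj = make_planted_traj(toy.structure, q, variances, 5000, seed=5)
        out = rmsf(traj, discard_fraction=0.0)
        planted = np.sqrt(
            (q ** 2 * variances).sum(1).reshape(-1, 3).sum(1))
        # beads with meaningful planted motion recovered within 5%
        big = planted > 0.15
        assert np.abs(out[big] / planted[big] - 1).max() < 0.05

    def test_short_window_rejected(self):
        frames = np.zeros((4, 5, 3))
        with pytest.raises(ValueError):
            rmsf(make_traj(frames), discard_fraction=0.8)


class TestPca:
    def test_single_direction_variance(self):
        base = np.random.default_rng(0).uniform(0, 10, (10, 3))
        amplitudes = np.array([-2.0, -1, 0, 1, 2.0])
        frames = np.repeat(base[None], 5, axis=0)
        frames[:, 3, 1] += amplitudes
        model = pca(make_traj(frames), discard_fraction=0.0)
        assert model.eigenvalues[0] == pytest.approx(amplitudes.var(),
                                                     rel=1e-10)
        assert model.eigenvalues[1:].max() < 1e-20

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 10, (40, 15, 3))
        t = make_traj(frames)
        model = pca(t, discard_fraction=0.0)
        flat = frames.reshape(40, -1)
        total = ((flat - flat.mean(0)) ** 2).mean(0).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_planted_modes_recovered(self):
        toy = make_two_lobe(seed=6)
        n3 = 3 * toy.structure.n_atoms
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.standard_normal((n3, 3)))
        variances = np.array([5.0, 3.0, 1.0])
        traj = make_planted_traj(toy.structure, q, variances, 5000, seed=8)
        model = pca(traj, discard_fraction=0.0)
        assert np.abs(model.eigenvalues[:3] / variances - 1).max() < 0.05
        # principal angle between planted and recovered subspaces < 10°
        overlap = q.T @ model.eigenvectors[:, :3]
        sv = np.linalg.svd(overlap, compute_uv=False)
        assert np.degrees(np.arccos(min(sv.min(), 1.0))) < 10.0

    def test_zero_variance_rejected(self):
        frames = np.zeros((5, 4, 3))
        with pytest.raises(ValueError, match="variance"):
            pca(make_traj(frames), discard_fraction=0.0)


class TestProject:
    def test_own_trajectory_reproduces_eigenvalues(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 5, (60, 8, 3))
        t = make_traj(frames)
        model = pca(t, discard_fraction=0.0)
        proj = project(t, model, (0, 1, 2))
        np.testing.assert_allclose(proj.projections.var(axis=0),
                                   model.eigenvalues[:3], rtol=1e-6)

    def test_mean_structure_projects_to_zero(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 5, (30, 8, 3))
        t = make_traj(frames)
        model = pca(t, discard_fraction=0.0)
        mean_traj = make_traj(model.mean[None])
        proj = project(mean_traj, model, (0, 1))
        np.testing.assert_allclose(proj.projections, 0.0, atol=1e-10)

    def test_shifted_trajectories_separate(self):
        """Two trajectories whose means differ along EV1 by a planted
        shift produce projection histograms separated by that shift."""
        toy = make_two_lobe(seed=9)
        n3 = 3 * toy.structure.n_atoms
        rng = np.random.default_rng(10)
        q, _ = np.linalg.qr(rng.standard_normal((n3, 2)))
        t1 = make_planted_traj(toy.structure, q, [4.0, 1.0], 400, seed=11)
        shift = 6.0
        base2 = toy.structure.subset(np.arange(toy.structure.n_atoms))
        base2.coords = base2.coords + shift * q[:, 0].reshape(1, -1, 3)
        t2 = make_planted_traj(base2, q, [4.0, 1.0], 400, seed=12)
        model = pca(t1, discard_fraction=0.0)
        sign = np.sign(q[:, 0] @ model.eigenvectors[:, 0])
        p1 = project(t1, model, (0,)).projections[:, 0]
        p2 = project(t2, model, (0,)).projections[:, 0]
        assert sign * (p2.mean() - p1.mean()) == pytest.approx(shift,
                                                               rel=0.05)

    def test_incomplete_mapping_rejected(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 5, (10, 8, 3))
        t = make_traj(frames)
        model = pca(t, discard_fraction=0.0)
        with pytest.raises(ValueError, match="mapping"):
            project(t, model, (0,), mapping=[(0, 0), (1, 1)])


class TestSpectrum:
    def test_single_mode_fraction_one(self):
        base = np.zeros((6, 3))
        frames = np.repeat(base[None], 8, axis=0)
        frames[:, 0, 0] += np.linspace(-1, 1, 8)
        model = pca(make_traj(frames), discard_fraction=0.0)
        assert eigen_spectrum_fractions(model, 1)[0] == pytest.approx(1.0)

    def test_isotropic_noise_flat_spectrum(self):
        rng = np.random.default_rng(5)
        m = 10
        frames = rng.standard_normal((4000, m, 3))
        model = pca(make_traj(frames), discard_fraction=0.0)
        frac = eigen_spectrum_fractions(model, 3 * m)
        np.testing.assert_allclose(frac, 1.0 / (3 * m), rtol=0.2)

    def test_planted_spectrum_ratios(self):
        toy = make_two_lobe(seed=13)
        n3 = 3 * toy.structure.n_atoms
        rng = np.random.default_rng(14)
        q, _ = np.linalg.qr(rng.standard_normal((n3, 3)))
        traj = make_planted_traj(toy.structure, q, [5.0, 3.0, 1.0], 5000,
                                 seed=15, noise=0.02)
        model = pca(traj, discard_fraction=0.0)
        frac = eigen_spectrum_fractions(model, 3)
        expected = np.array([5, 3, 1]) / 9.0
        assert np.abs(frac / expected - 1).max() < 0.10


class TestClusterLeader:
    def test_everything_one_cluster(self):
        rng = np.random.default_rng(6)
        frames = rng.uniform(0, 1, (12, 6, 3)) * 0.1
        result = cluster_leader(make_traj(frames), cutoff=100.0)
        assert result.sizes == [12]
        assert (result.assignment == 0).all()

    def test_two_planted_bundles(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 10, (6, 3))
        bundle1 = base[None] + 0.05 * rng.standard_normal((7, 6, 3))
        bundle2 = base[None] + 30.0 + 0.05 * rng.standard_normal((5, 6, 3))
        frames = np.concatenate([bundle1, bundle2])
        result = cluster_leader(make_traj(frames), cutoff=2.0)
        assert result.sizes == [7, 5]
        assert len(set(result.assignment[:7])) == 1
        assert len(set(result.assignment[7:])) == 1

    def test_medoids_separated_beyond_cutoff(self):
        rng = np.random.default_rng(8)
        frames = rng.uniform(0, 6, (25, 5, 3))
        cutoff = 3.0
        result = cluster_leader(make_traj(frames), cutoff=cutoff)
        dist = _pairwise_rmsd(frames)
        for a in result.representatives:
            for b in result.representatives:
                if a != b:
                    assert dist[a, b] > cutoff

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        frames = rng.uniform(0, 6, (20, 5, 3))
        r1 = cluster_leader(make_traj(frames), cutoff=3.0)
        r2 = cluster_leader(make_traj(frames), cutoff=3.0)
        assert (r1.assignment == r2.assignment).all()
        assert r1.representatives == r2.representatives


class TestDistanceSeries:
    def test_static_distance(self):
        base = np.zeros((2, 3))
        base[1, 0] = 7.3
        t = make_traj(np.repeat(base[None], 5, axis=0))
        s = distance_series(t, ("A", 1, "CA"), ("A", 2, "CA"))
        assert s.mean == pytest.approx(7.3)
        assert s.sd == 0

    def test_ambiguous_selector_rejected(self):
        struct = bead_structure(np.zeros((2, 3)))
        struct.res_numbers = np.array([1, 1])
        t = Trajectory(template=struct, coords=np.zeros((3, 2, 3)))
        with pytest.raises(ValueError, match="ambiguous"):
            distance_series(t, ("A", 1, "CA"), ("A", 1, "CA"))

    def test_sinusoid_mean(self):
        a, b = 9.0, 2.0
        n = 1000
        base = np.zeros((2, 3))
        frames = np.repeat(base[None], n, axis=0)
        frames[:, 1, 0] = a + b * np.sin(
            np.linspace(0, 20 * np.pi, n, endpoint=False))
        t = make_traj(frames)
        s = distance_series(t, ("A", 1, "CA"), ("A", 2, "CA"),
                            tail_fraction=1.0)
        assert s.mean == pytest.approx(a, rel=0.01)


class TestInvariants:
    def test_pca_matches_enm_modes_for_enm_generated_traj(self):
        """Trajectories generated from elastic-network modes yield PCA
        eigenvectors overlapping those modes (> 0.9 each)."""
        toy = make_two_lobe(seed=16)
        modes = normal_modes(build_network(toy.structure, cutoff=10.0),
                             n_modes=10)
        variances = 1.0 / modes.eigenvalues[:3]
        traj = make_planted_traj(toy.structure,
                                 modes.eigenvectors[:, :3], variances,
                                 4000, seed=17)
        model = pca(traj, discard_fraction=0.0)
        for k in range(3):
            ov = mode_overlap(modes, model.eigenvectors[:, k])
            assert ov[k] > 0.9

    def test_rmsf_invariant_to_rigid_motion(self):
        toy = make_two_lobe(seed=18)
        n3 = 3 * toy.structure.n_atoms
        rng = np.random.default_rng(19)
        q, _ = np.linalg.qr(rng.standard_normal((n3, 2)))
        plain = make_planted_traj(toy.structure, q, [2.0, 1.0], 600,
                                  seed=20)
        wobble = make_planted_traj(toy.structure, q, [2.0, 1.0], 600,
                                   seed=20, rigid_motion=True)
        ref = toy.structure.xyz
        f1, _ = superpose(plain, ref)
        f2, _ = superpose(wobble, ref)
        np.testing.assert_allclose(rmsf(f2, discard_fraction=0.0),
                                   rmsf(f1, discard_fraction=0.0),
                                   rtol=1e-6)
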