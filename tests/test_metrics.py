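"""Superposition, RMSD/RMSF, DCCM, PCA, and free-energy landscapes."""

import math
import subprocess

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from proxiscreen.metrics import (KB_KCAL_PER_MOL_K, convergence_window, dccm,
                                 free_energy_landscape, kabsch_superpose, pca,
                                 rmsd_series, rmsf_per_residue, superpose_to_mean)
from proxiscreen.synthetic import TrajectoryScenario, make_trajectory
from proxiscreen.trajectory import AtomLabel, Trajectory

from conftest import small_trajectory


def svd_kabsch_rmsd(mobile, reference):
    """Independent textbook Kabsch (SVD with reflection fix) in the test."""
    P = mobile - mobile.mean(0)
    Q = reference - reference.mean(0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


class TestKabsch:
    def test_identity(self):
        t = small_trajectory(n_res=5, n_frames=1)
        _, r = kabsch_superpose(t.coords[0], t.coords[0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        t = small_trajectory(n_res=5, n_frames=1)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(t.coords[0]) + np.array([5.0, 5.0, 5.0])
        _, r = kabsch_superpose(moved, t.coords[0])
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_not_superposable(self):
        # a reflection is not a proper rotation, so rmsd stays > 0
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(10, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        _, r = kabsch_superpose(mirrored, ref)
        assert r > 0.1

    def test_matches_rotation_grid_search(self):
        rng = np.random.default_rng(1)
        mobile = rng.normal(size=(10, 3))
        reference = rng.normal(size=(10, 3))
        _, r_kabsch = kabsch_superpose(mobile, reference)
        P = mobile - mobile.mean(0)
        Q = reference - reference.mean(0)
        centered = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
        assert r_kabsch <= centered + 1e-12

        def cost(angles):
            R = Rotation.from_euler("zyx", angles)
            return float(np.sqrt(np.mean(np.sum((R.apply(P) - Q) ** 2, axis=1))))

        grid = np.linspace(-np.pi, np.pi, 13)
        best = min(((cost((a, b, c)), (a, b, c))
                    for a in grid for b in grid for c in grid))[1]
        polished = minimize(cost, best, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12})
        assert r_kabsch == pytest.approx(polished.fun, abs=1e-3)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_atoms_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_constant_trajectory_all_zero(self):
        t = small_trajectory(n_res=5, n_frames=4, sd=0.0)
        np.testing.assert_allclose(rmsd_series(t), 0.0, atol=1e-12)

    def test_rigid_rotations_all_zero(self):
        base = small_trajectory(n_res=6, n_frames=1).coords[0]
        rng = np.random.default_rng(3)
        frames = [base]
        for _ in range(4):
            frames.append(Rotation.random(rng=rng).apply(base) + rng.uniform(-9, 9, 3))
        t = Trajectory([AtomLabel(i + 1, "CA") for i in range(6)], np.array(frames))
        np.testing.assert_allclose(rmsd_series(t), 0.0, atol=1e-9)

    def test_first_frame_zero_and_matches_independent_kabsch(self):
        t = make_trajectory(TrajectoryScenario(n_residues=20, n_frames=30,
                                               sigma=0.5, seed=4, rotation=True))
        series = rmsd_series(t, "ca")
        assert series[0] == 0.0
        for i in range(1, t.n_frames):
            assert series[i] == pytest.approx(
                svd_kabsch_rmsd(t.coords[i], t.coords[0]), abs=1e-9)

    def test_gaussian_fluctuation_magnitude(self):
        # i.i.d. per-atom fluctuations of amplitude sigma: frame-to-frame RMSD
        # concentrates near sigma * sqrt(2) (two independent frames)
        sigma = 0.5
        t = make_trajectory(TrajectoryScenario(n_residues=60, n_frames=400,
                                               sigma=sigma, seed=5))
        series = rmsd_series(t, "ca")
        assert np.mean(series[1:]) == pytest.approx(sigma * math.sqrt(2), rel=0.07)


class TestRmsf:
    def test_constant_trajectory_all_zero(self):
        t = small_trajectory(n_res=5, n_frames=3, sd=0.0)
        np.testing.assert_allclose(rmsf_per_residue(t).to_numpy(), 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        t = small_trajectory(n_res=5, n_frames=1)
        with pytest.raises(ValueError):
            rmsf_per_residue(t)

    def test_two_frame_oscillation_analytic(self):
        # one atom swings +/- a along x around its mean, the rest are fixed;
        # fitting on the fixed atoms, that residue's RMSF equals a exactly
        a = 0.7
        base = small_trajectory(n_res=6, n_frames=1, sd=0.0).coords[0]
        up, down = base.copy(), base.copy()
        up[2, 0] += a
        down[2, 0] -= a
        t = Trajectory([AtomLabel(i + 1, "CA") for i in range(6)],
                       np.array([up, down]))
        fit = np.ones(6, dtype=bool)
        fit[2] = False
        out = rmsf_per_residue(t, None, fit_mask=fit)
        assert out.loc[3] == pytest.approx(a, abs=1e-12)
        assert out.drop(3).max() == pytest.approx(0.0, abs=1e-12)

    def test_planted_sigma_recovered(self):
        sigma = np.linspace(0.3, 0.8, 40)
        t = make_trajectory(TrajectoryScenario(n_residues=40, n_frames=2000,
                                               sigma=sigma, seed=6))
        out = rmsf_per_residue(t, "ca").to_numpy()
        assert np.max(np.abs(out / sigma - 1)) < 0.05


class TestDccm:
    def _paired_motion(self, sign):
        # residues 1 and 2 move together (or oppositely); residues 3..10 fixed
        rng = np.random.default_rng(7)
        base = small_trajectory(n_res=10, n_frames=1, sd=0.0).coords[0]
        frames = []
        for _ in range(50):
            d = rng.normal(size=3)
            f = base.copy()
            f[0] += d
            f[1] += sign * d
            frames.append(f)
        t = Trajectory([AtomLabel(i + 1, "CA") for i in range(10)], np.array(frames))
        fit = np.zeros(10, dtype=bool)
        fit[2:] = True
        C, resids = dccm(t, None, fit_mask=fit)
        return C

    def test_identical_motion_perfectly_correlated(self):
        C = self._paired_motion(+1)
        assert C[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_opposite_motion_anticorrelated(self):
        C = self._paired_motion(-1)
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_rows_zeroed(self):
        C = self._paired_motion(+1)
        assert np.allclose(np.diag(C), 1.0)
        off = C[3:, :][:, :2]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_symmetric_bounded_unit_diagonal(self):
        t = make_trajectory(TrajectoryScenario(n_residues=25, n_frames=200,
                                               sigma=0.5, seed=8,
                                               blocks=[((5, 9), (5, 9), 0.6)]))
        C, resids = dccm(t, "ca")
        assert resids == list(range(1, 26))
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.all(C >= -1) and np.all(C <= 1)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)

    def test_planted_block_recovered(self):
        t = make_trajectory(TrajectoryScenario(n_residues=150, n_frames=2000,
                                               sigma=0.5, seed=9,
                                               blocks=[((20, 25), (20, 25), 0.8)]))
        C, _ = dccm(t, "ca")
        block = C[19:25, 19:25]
        mean_rho = block[~np.eye(6, dtype=bool)].mean()
        assert mean_rho == pytest.approx(0.8, abs=0.05)

    def test_matches_bio3d_reference(self, tmp_path):
        # independent oracle: the residue cross-correlation of the bio3d R
        # package on the same superposed coordinates
        t = make_trajectory(TrajectoryScenario(n_residues=8, n_frames=60,
                                               sigma=0.5, seed=10,
                                               blocks=[((2, 4), (2, 4), 0.7)]))
        ours, _ = dccm(t, "ca")
        aligned = superpose_to_mean(t, "ca")
        xyz = tmp_path / "xyz.tsv"
        np.savetxt(xyz, aligned.reshape(t.n_frames, -1))
        out = tmp_path / "dccm_r.tsv"
        script = tmp_path / "dccm.R"
        script.write_text(
            'suppressMessages(library(bio3d))\n'
            f'm <- as.matrix(read.table("{xyz}"))\n'
            'cc <- dccm(as.xyz(m))\n'
            f'write.table(cc, "{out}", sep="\\t", row.names=FALSE, col.names=FALSE)\n'
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        theirs = np.loadtxt(out)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestPca:
    def test_variance_fractions_normalized_and_sorted(self):
        t = make_trajectory(TrajectoryScenario(n_residues=15, n_frames=100,
                                               sigma=0.4, seed=11))
        proj, frac = pca(t, "ca")
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(frac) <= 1e-12)
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=1e-9)

    def test_planar_fluctuations_have_no_z_variance(self):
        rng = np.random.default_rng(12)
        base = small_trajectory(n_res=8, n_frames=1, sd=0.0).coords[0]
        disp = rng.normal(0, 0.05, (60, 8, 3))
        disp[:, :, 2] = 0.0
        t = Trajectory([AtomLabel(i + 1, "CA") for i in range(8)], base[None] + disp)
        # superposition can leak a little in-plane noise out of plane, so the
        # out-of-plane variance is bounded, not exactly zero
        aligned = superpose_to_mean(t, None)
        var = aligned.var(axis=0).mean(axis=0)
        assert var[2] < 0.05 * (var[0] + var[1])

    def test_planted_mode_ratio_recovered(self):
        t = make_trajectory(TrajectoryScenario(n_residues=50, n_frames=2000,
                                               modes=[9.0, 1.0], seed=13))
        _, frac = pca(t, "ca")
        assert frac[0] == pytest.approx(0.9, abs=0.02)
        assert frac[0] + frac[1] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_covariance_rejected(self):
        t = small_trajectory(n_res=5, n_frames=3, sd=0.0)
        with pytest.raises(ValueError):
            pca(t)


class TestFreeEnergyLandscape:
    def test_single_occupied_bin_is_zero(self):
        fel = free_energy_landscape(np.zeros(10), np.zeros(10), bins=5)
        occ = fel.occupied
        assert occ.sum() == 1
        assert fel.energy[occ][0] == 0.0

    def test_two_bin_analytic_delta(self):
        pc1 = np.array([0.0, 0.0, 0.0, 1.0])
        fel = free_energy_landscape(pc1, np.zeros(4), temperature_K=310.0, bins=2)
        vals = np.sort(fel.energy[fel.occupied])
        want = KB_KCAL_PER_MOL_K * 310.0 * math.log(3)
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(want, abs=1e-6)
        assert want == pytest.approx(0.677, abs=1e-3)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(14)
        fel = free_energy_landscape(rng.normal(size=500), rng.normal(size=500), bins=20)
        assert fel.probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmin(fel.energy) == 0.0

    def test_monotone_in_probability(self):
        rng = np.random.default_rng(15)
        fel = free_energy_landscape(rng.normal(size=2000), rng.normal(size=2000), bins=15)
        occ = fel.occupied
        p = fel.probability[occ]
        f = fel.energy[occ]
        order = np.argsort(p)
        assert np.all(np.diff(f[order]) <= 1e-12)

    def test_bivariate_normal_matches_quadratic_bowl(self):
        rng = np.random.default_rng(16)
        n = 40000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fel = free_energy_landscape(x, y, temperature_K=310.0, bins=25)
        kbt = KB_KCAL_PER_MOL_K * 310.0
        xc = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
        yc = 0.5 * (fel.y_edges[:-1] + fel.y_edges[1:])
        counts = fel.probability * n
        good = counts >= 200
        r2 = xc[:, None] ** 2 + yc[None, :] ** 2
        analytic = 0.5 * kbt * r2
        analytic = analytic - analytic[good & fel.occupied].min()
        diff = np.abs(fel.energy - analytic)[good & fel.occupied]
        assert diff.max() < 0.15

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            free_energy_landscape(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            free_energy_landscape(np.zeros(3), np.zeros(3), bins=1)


class TestConvergenceWindow:
    def test_keeps_last_fifth(self):
        t = small_trajectory(n_res=4, n_frames=100, seed=17)
        tail = convergence_window(t, 0.2)
        assert tail.n_frames == 20
        np.testing.assert_array_equal(tail.coords, t.coords[80:])

    def test_full_fraction_is_identity(self):
        t = small_trajectory(n_res=4, n_frames=7, seed=18)
        np.testing.assert_array_equal(convergence_window(t, 1.0).coords, t.coords)

    def test_ceiling_rule(self):
        t = small_trajectory(n_res=4, n_frames=7, seed=19)
        assert convergence_window(t, 0.2).n_frames == 2

    def test_fraction_bounds(self):
        t = small_trajectory(n_res=4, n_frames=7)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                convergence_window(t, bad)


class TestRigidMotionInvariance:
    def test_metrics_invariant_under_global_rigid_motion(self):
        t = make_trajectory(TrajectoryScenario(n_residues=20, n_frames=120,
                                               sigma=0.5, seed=20,
                                               blocks=[((4, 8), (4, 8), 0.6)]))
        rng = np.random.default_rng(21)
        moved = np.empty_like(t.coords)
        for i in range(t.n_frames):
            moved[i] = Rotation.random(rng=rng).apply(t.coords[i]) + rng.uniform(-15, 15, 3)
        t2 = Trajectory(t.atom_labels, moved, t.dt)

        np.testing.assert_allclose(rmsd_series(t, "ca"), rmsd_series(t2, "ca"), atol=1e-6)
        np.testing.assert_allclose(rmsf_per_residue(t, "ca").to_numpy(),
                                   rmsf_per_residue(t2, "ca").to_numpy(), atol=1e-6)
        np.testing.assert_allclose(dccm(t, "ca")[0], dccm(t2, "ca")[0], atol=1e-6)
        np.testing.assert_allclose(pca(t, "ca")[1], pca(t2, "ca")[1], atol=1e-6)
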