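"""Frames, junction angles, superposition, ensemble statistics, NSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from archkit.core import Atom, Ensemble, ModuleSpan, Structure
from archkit.geometry import (com_separation, ensemble_rmsd, frame_from_matrix,
                              inter_module_angles, junction_rotation, nsd,
                              principal_frame, superpose)
from archkit.synth import build_chain, jitter_ensemble, make_module


def _ca_structure(points, resnames=None):
    atoms = []
    for i, p in enumerate(points):
        rn = resnames[i] if resnames else ("CYS" if i in (0, len(points) - 1) else "ALA")
        atoms.append(Atom(i + 1, "CA", i + 1, rn, "C", p))
    return Structure(atoms)


class TestPrincipalFrame:
    def test_collinear_points_axis_sign_from_nc(self):
        n = 60
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n, dtype=float)  # along +x, N-to-C increasing
        pts[30, 1] = 3.0  # off-axis reference
        st = _ca_structure(pts)
        span = ModuleSpan("M", 1, n, (31, "CA"))
        f = principal_frame(st, span)
        assert f.z_axis @ [1, 0, 0] > 0.99

    def test_prolate_cloud_recovers_generating_axis(self):
        rng = np.random.default_rng(0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.align_vectors([axis], [[0, 0, 1]])[0].as_matrix()
        local = rng.normal(size=(1000, 3)) * [8.0, 8.0, 20.0]
        # orient the cloud N-to-C along +axis
        local = local[np.argsort(local[:, 2])]
        pts = local @ R.T
        perp = np.cross(axis, [1, 0, 0])
        if np.linalg.norm(perp) < 0.1:
            perp = np.cross(axis, [0, 1, 0])
        pts[500] += 15.0 * perp / np.linalg.norm(perp)
        st = _ca_structure(pts)
        f = principal_frame(st, ModuleSpan("M", 1, 1000, (501, "CA")))
        angle = np.rad2deg(np.arccos(np.clip(abs(f.z_axis @ axis), 0, 1)))
        assert angle < 2.0

    def test_spherically_symmetric_cloud_degenerate(self):
        # octahedron vertices: exactly isotropic inertia tensor
        pts = 8.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                              [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        st = _ca_structure(pts)
        with pytest.raises(ValueError, match="ill-defined"):
            principal_frame(st, ModuleSpan("M", 1, 6, (3, "CA")))

    def test_frame_covariant_under_rigid_transform(self, module_pair):
        st, span = module_pair[0]
        f0 = principal_frame(st, span)
        rng = np.random.default_rng(5)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 20
            f1 = principal_frame(st.with_coords(st.coords @ R.T + t), span)
            np.testing.assert_allclose(f1.matrix, R @ f0.matrix, atol=1e-6)


class TestJunctionAngles:
    def test_identical_frames(self):
        f = frame_from_matrix(np.eye(3))
        a = inter_module_angles(f, f)
        assert a.tilt == pytest.approx(0.0, abs=1e-9)
        assert a.twist == pytest.approx(0.0, abs=1e-9)
        assert a.degenerate

    def test_pure_y_rotation_is_tilt(self):
        f1 = frame_from_matrix(np.eye(3))
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        a = inter_module_angles(f1, frame_from_matrix(R))
        assert a.tilt == pytest.approx(90.0, abs=1e-9)

    def test_pure_axial_rotation_is_twist(self):
        f1 = frame_from_matrix(np.eye(3))
        R = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        a = inter_module_angles(f1, frame_from_matrix(R))
        assert a.degenerate
        assert a.twist == pytest.approx(40.0, abs=1e-6)

    def test_round_trip_against_rotation_composition(self):
        rng = np.random.default_rng(3)
        f1 = frame_from_matrix(Rotation.random(random_state=rng).as_matrix())
        for _ in range(50):
            tilt = rng.uniform(1, 179)
            twist = rng.uniform(-179, 179)
            skew = rng.uniform(-179, 179)
            M2 = f1.matrix @ junction_rotation(tilt, twist, skew)
            a = inter_module_angles(f1, frame_from_matrix(M2))
            assert a.tilt == pytest.approx(tilt, abs=1e-9)
            assert np.isclose((a.twist - twist + 180) % 360 - 180, 0, atol=1e-9)
            assert np.isclose((a.skew - skew + 180) % 360 - 180, 0, atol=1e-9)

    def test_tilt_symmetric_under_frame_exchange(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            fa = frame_from_matrix(Rotation.random(random_state=rng).as_matrix())
            fb = frame_from_matrix(Rotation.random(random_state=rng).as_matrix())
            assert (inter_module_angles(fa, fb).tilt
                    == pytest.approx(inter_module_angles(fb, fa).tilt, abs=1e-9))

    def test_chain_construction_recovers_prescribed_angles(self, module_pair):
        m1, m2 = module_pair
        chain, arch = build_chain([m1, m2], [(118.0, 57.0, 89.0, 6)], seed=0)
        fa = principal_frame(chain, arch.modules[0])
        fb = principal_frame(chain, arch.modules[1])
        a = inter_module_angles(fa, fb)
        assert a.tilt == pytest.approx(118.0, abs=1e-6)
        assert a.twist == pytest.approx(57.0, abs=1e-6)
        assert a.skew == pytest.approx(89.0, abs=1e-6)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(50, 3))
        R, t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(80, 3)) * 10
        R0 = Rotation.random(random_state=rng).as_matrix()
        t0 = rng.normal(size=3) * 5
        R, t, rmsd = superpose(pts @ R0.T + t0, pts)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R @ R0, np.eye(3), atol=1e-9)

    def test_noisy_beats_random_rigid_transforms(self):
        rng = np.random.default_rng(2)
        target = rng.normal(size=(200, 3)) * 10
        mobile = target + rng.normal(0, 0.5, size=(200, 3))
        _, _, rmsd = superpose(mobile, target)
        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3)
            trial = np.sqrt(np.mean(np.sum((mobile @ R.T + t - target) ** 2, axis=1)))
            assert rmsd <= trial + 1e-12

    def test_matches_quaternion_eigenvalue_oracle(self):
        # Horn's closed-form: max eigenvalue of the 4x4 profile matrix gives
        # the optimal residual — an independent route to the same optimum
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=(30, 3))
            b = rng.normal(size=(30, 3))
            _, _, rmsd = superpose(a, b)
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            M = ac.T @ bc
            sxx, sxy, sxz = M[0]
            syx, syy, syz = M[1]
            szx, szy, szz = M[2]
            K = np.array([
                [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
                [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
                [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
                [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
            lam = np.linalg.eigvalsh(K)[-1]
            resid2 = np.sum(ac ** 2) + np.sum(bc ** 2) - 2 * lam
            assert rmsd == pytest.approx(np.sqrt(max(resid2, 0) / len(a)), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestEnsembleRmsd:
    def test_duplicates_zero(self, module_pair):
        st, _ = module_pair[0]
        assert ensemble_rmsd(Ensemble([st, st, st])) == pytest.approx(0.0, abs=1e-12)

    def test_jitter_scaling(self, module_pair):
        st, _ = module_pair[0]
        ens = jitter_ensemble(st, 0.5, 10, seed=3)
        pw = ensemble_rmsd(ens, selection="all", mode="pairwise_mean")
        assert pw == pytest.approx(0.5 * np.sqrt(6.0), rel=0.10)

    def test_pairwise_at_least_to_mean(self, module_pair):
        st, _ = module_pair[0]
        for seed in range(3):
            ens = jitter_ensemble(st, 0.8, 8, seed=seed)
            pw = ensemble_rmsd(ens, mode="pairwise_mean")
            tm = ensemble_rmsd(ens, mode="to_mean")
            assert pw >= tm - 1e-9


class TestComSeparation:
    def test_two_single_atom_modules(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0], [11.0, 0, 0]])
        st = _ca_structure(pts, resnames=["CYS", "CYS", "CYS", "CYS"])
        d = com_separation(st, ModuleSpan("A", 1, 2, (1, "CA")),
                           ModuleSpan("B", 3, 4, (3, "CA")))
        assert d == pytest.approx(10.0)

    def test_constructed_dumbbell_gap(self, module_pair):
        m1, m2 = module_pair
        st1, sp1 = m1
        moved = st1.with_coords(st1.coords + np.array([38.0, 0, 0]))
        atoms = list(st1.atoms)
        n = sp1.cys4
        for a in moved.atoms:
            atoms.append(Atom(a.serial + 10000, a.name, a.residue_number + n,
                              a.residue_name, a.element, a.position))
        combined = Structure(atoms)
        spB = ModuleSpan("B", sp1.cys1 + n, sp1.cys4 + n, (sp1.ref_atom[0] + n, "CA"))
        assert com_separation(combined, sp1, spB) == pytest.approx(38.0, abs=1e-6)


class TestNsd:
    def test_identical_zero_and_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100, 3)) * 10
        b = rng.normal(size=(80, 3)) * 10
        assert nsd(a, a) == pytest.approx(0.0, abs=1e-12)
        assert nsd(a, b) == pytest.approx(nsd(b, a), rel=1e-9)

    def test_rotated_copy_aligned(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(60, 3)) * np.array([12, 6, 3])
        R = Rotation.random(random_state=rng).as_matrix()
        b = a @ R.T + rng.normal(size=3) * 5
        assert nsd(a, b, align=True) < 0.05

    def test_half_shifted_lattice_closed_form(self):
        h = 2.0
        g = np.arange(5) * h
        lat = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        shifted = lat + np.array([h / 2, 0, 0])
        # every point's nearest neighbour in the other set is at h/2;
        # within-set spacing is h, so NSD = sqrt((h/2)^2 / h^2) = 0.5
        assert nsd(lat, shifted) == pytest.approx(0.5, abs=1e-12)
        # brute-force O(N^2) nearest-neighbour oracle
        d2 = np.sum((lat[:, None, :] - shifted[None, :, :]) ** 2, axis=2)
        nn_ab = np.sqrt(d2.min(axis=1))
        nn_ba = np.sqrt(d2.min(axis=0))
        dlat = np.sum((lat[:, None, :] - lat[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(dlat, np.inf)
        spacing = np.sqrt(dlat.min(axis=1)).mean()
        expected = np.sqrt(0.5 * (np.mean(nn_ab ** 2) / spacing ** 2
                                  + np.mean(nn_ba ** 2) / spacing ** 2))
        assert nsd(lat, shifted) == pytest.approx(expected, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            nsd(np.zeros((1, 3)), np.zeros((5, 3)))
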