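"""Kabsch superposition, RMSF, B-factor conversion and geometric monitors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from complexdyn.geometry import (
    BFACTOR_PREFACTOR,
    DegenerateFitError,
    apply_transform,
    center_of_mass,
    domain_angle,
    pair_distance,
    rmsf,
    rmsf_to_bfactor,
    superpose_kabsch,
    write_bfactor_pdb,
)
from complexdyn.structure_io import SelectionError, Trajectory, read_pdb
from complexdyn.synthetic import build_toy_complex, preset, simulate_trajectory

from conftest import make_structure


def random_rotation(seed):
    return Rotation.random(random_state=seed).as_matrix()


class TestKabsch:
    def test_identical_sets(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = superpose_kabsch(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_recovers_known_transform(self):
        x = np.random.default_rng(1).normal(size=(10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ Rz.T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = superpose_kabsch(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, Rz, atol=1e-9)
        np.testing.assert_allclose(t, [1, 2, 3], atol=1e-9)

    def test_matches_brute_force_optimizer(self):
        """Noisy cloud: optimal RMSD agrees with a direct rotation search."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 3))
        y = x @ random_rotation(3).T + rng.normal(scale=0.1, size=(10, 3))

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def cost(euler):
            R = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sqrt(((xc @ R.T - yc) ** 2).sum(axis=1).mean())

        best = np.inf
        for a in np.linspace(0, 2 * np.pi, 7, endpoint=False):
            for b in np.linspace(0, np.pi, 4):
                for c in np.linspace(0, 2 * np.pi, 7, endpoint=False):
                    res = minimize(cost, [a, b, c], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                    best = min(best, res.fun)
        _, _, rmsd = superpose_kabsch(x, y)
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 3))
        y = x.copy()
        y[:, 0] *= -1  # mirrored cloud
        R, _, _ = superpose_kabsch(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_too_few_atoms(self):
        with pytest.raises(DegenerateFitError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_atoms(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateFitError):
            superpose_kabsch(line, line)

    @given(st.integers(0, 1000))
    def test_rmsd_invariant_under_shared_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(9, 3))
        y = x + rng.normal(scale=0.3, size=(9, 3))
        _, _, rmsd0 = superpose_kabsch(x, y)
        R = random_rotation(seed)
        t = rng.normal(scale=10, size=3)
        _, _, rmsd1 = superpose_kabsch(apply_transform(x, R, t),
                                       apply_transform(y, R, t))
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)


def _static_trajectory(coords, n_frames=4):
    s = make_structure(coords)
    frames = np.repeat(coords[None, :, :].astype(float), n_frames, axis=0)
    return Trajectory(topology=s, coords=frames,
                      times=np.arange(n_frames, dtype=float))


class TestRMSF:
    def test_static_trajectory_zero(self):
        traj = _static_trajectory(np.random.default_rng(0).normal(size=(6, 3)))
        f = rmsf(traj)
        np.testing.assert_allclose(f.rmsf, 0.0, atol=1e-12)

    def test_alternating_atom_closed_form(self):
        """One residue oscillating +/-1 Å along x -> RMSF exactly 1 Å."""
        base = np.array(
            [[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 1]], dtype=float
        )
        frames = np.repeat(base[None], 4, axis=0)
        frames[0, 0, 0] = +1.0
        frames[1, 0, 0] = -1.0
        frames[2, 0, 0] = +1.0
        frames[3, 0, 0] = -1.0
        s = make_structure(base)
        traj = Trajectory(topology=s, coords=frames, times=np.arange(4.0))
        # fit on the three static residues so no motion is absorbed
        f = rmsf(traj, fit_selection=[1, 2, 3])
        assert f.rmsf[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(f.rmsf[1:], 0.0, atol=1e-12)

    def test_isotropic_noise_matches_closed_form(self):
        """Designed isotropic sd 0.5 Å -> RMSF ~= sqrt(3)*0.5 within 5%."""
        spec = preset("single-state", seed=5, n_frames=2000)
        spec.fluctuation_sd = 0.5
        spec.correlation_blocks = []
        spec.hbond_pairs = []
        toy = build_toy_complex(spec)
        traj, _ = simulate_trajectory(toy)
        f = rmsf(traj)
        assert f.rmsf.mean() == pytest.approx(np.sqrt(3) * 0.5, rel=0.05)

    def test_invariant_under_global_rigid_motion(self):
        spec = preset("single-state", seed=9, n_frames=200)
        spec.hbond_pairs = []
        toy = build_toy_complex(spec)
        traj, _ = simulate_trajectory(toy)
        f0 = rmsf(traj)
        rng = np.random.default_rng(0)
        moved = np.empty_like(traj.coords)
        for k in range(traj.n_frames):
            R = random_rotation(k)
            moved[k] = traj.coords[k] @ R.T + rng.normal(scale=5, size=3)
        traj2 = Trajectory(topology=traj.topology, coords=moved,
                           times=traj.times)
        f1 = rmsf(traj2)
        np.testing.assert_allclose(f1.rmsf, f0.rmsf, rtol=0.01)

    def test_needs_two_frames(self):
        traj = _static_trajectory(np.eye(3) * 3, n_frames=1)
        with pytest.raises(ValueError):
            rmsf(traj)


class TestBFactor:
    @pytest.mark.parametrize(
        "r, expected",
        [(1.0, 8 * np.pi**2 / 3), (0.0, 0.0), (0.5, 8 * np.pi**2 / 3 * 0.25)],
    )
    def test_conversion_closed_form(self, r, expected):
        from complexdyn.geometry import FluctuationSeries

        series = FluctuationSeries(
            chain_ids=np.array(["A"]), res_seqs=np.array([1]),
            rmsf=np.array([r]),
        )
        out = rmsf_to_bfactor(series)
        assert out.b_factor[0] == pytest.approx(expected, abs=1e-10)

    def test_prefactor_value(self):
        assert BFACTOR_PREFACTOR == pytest.approx(26.3189, abs=1e-4)

    def test_bfactor_column_roundtrip(self, tmp_path):
        """Written B column re-parses to the computed values within 0.01."""
        spec = preset("single-state", seed=2, n_frames=50)
        toy = build_toy_complex(spec)
        traj, _ = simulate_trajectory(toy)
        series = rmsf_to_bfactor(rmsf(traj))
        p = tmp_path / "b.pdb"
        write_bfactor_pdb(traj.topology, series, p)
        back = read_pdb(p)
        lookup = {(c, r): b for c, r, b in
                  zip(series.chain_ids, series.res_seqs, series.b_factor)}
        for i in range(back.n_atoms):
            key = (str(back.chain_id[i]), int(back.res_seq[i]))
            assert back.b_factor[i] == pytest.approx(lookup[key], abs=0.01)


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        s = make_structure([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(center_of_mass(s), [1, 0, 0])

    def test_single_atom(self):
        s = make_structure([[3.0, -1.0, 2.0]])
        np.testing.assert_allclose(center_of_mass(s), [3, -1, 2])

    def test_mass_weighting_carbon_oxygen(self):
        s = make_structure([[0, 0, 0], [1, 0, 0]], elements=["C", "O"])
        x = 15.999 / (12.011 + 15.999)
        assert center_of_mass(s)[0] == pytest.approx(x, abs=1e-4)
        assert center_of_mass(s, mass_weighted=False)[0] == pytest.approx(0.5)

    def test_empty_selection_rejected(self):
        s = make_structure([[0, 0, 0]])
        with pytest.raises(SelectionError):
            center_of_mass(s, np.array([], dtype=int))


class TestDomainAngle:
    def _three_group_traj(self, com_a, com_b):
        # ligand: two atoms about the origin; domains: single atoms
        coords = np.array(
            [[0.5, 0, 0], [-0.5, 0, 0], list(com_a), list(com_b)], float
        )
        s = make_structure(coords, chains=["L", "L", "A", "B"],
                           res_seqs=[1, 2, 1, 1])
        return Trajectory(topology=s, coords=coords[None], times=[0.0])

    def test_right_angle(self):
        traj = self._three_group_traj([1, 0, 0], [0, 1, 0])
        a = domain_angle(traj, [0, 1], [2], [3])
        assert a.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_collinear_same_side_zero(self):
        traj = self._three_group_traj([1, 0, 0], [2, 0, 0])
        a = domain_angle(traj, [0, 1], [2], [3])
        assert a.values[0] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_domains(self, single_state_run):
        toy, traj, _ = single_state_run
        ab = domain_angle(traj, toy.domains["L"], toy.domains["G1"],
                          toy.domains["G2"])
        ba = domain_angle(traj, toy.domains["L"], toy.domains["G2"],
                          toy.domains["G1"])
        np.testing.assert_allclose(ab.values, ba.values, atol=1e-10)

    def test_noise_free_design_recovered_exactly(self):
        spec = preset("single-state-noise-free")
        toy = build_toy_complex(spec)
        traj, _ = simulate_trajectory(toy)
        ag = domain_angle(traj, toy.domains["L"], toy.domains["G1"],
                          toy.domains["G2"])
        ar = domain_angle(traj, toy.domains["L"], toy.domains["R1"],
                          toy.domains["R2"])
        np.testing.assert_allclose(ag.values, 60.0, atol=1e-6)
        np.testing.assert_allclose(ar.values, 57.0, atol=1e-6)

    def test_both_definitions_invariant_under_rigid_motion(self, single_state_run):
        toy, traj, _ = single_state_run
        sub = Trajectory(topology=traj.topology, coords=traj.coords[:20],
                         times=traj.times[:20])
        R = random_rotation(4)
        moved = Trajectory(
            topology=traj.topology,
            coords=sub.coords @ R.T + np.array([3.0, -2.0, 8.0]),
            times=sub.times,
        )
        for definition in ("vertex-at-ligand", "axis-to-com"):
            a0 = domain_angle(sub, toy.domains["L"], toy.domains["G1"],
                              toy.domains["G2"], definition=definition)
            a1 = domain_angle(moved, toy.domains["L"], toy.domains["G1"],
                              toy.domains["G2"], definition=definition)
            np.testing.assert_allclose(a1.values, a0.values, atol=1e-8)


class TestPairDistance:
    def test_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        s = make_structure(coords, names=["CZ", "CG1"])
        traj = Trajectory(topology=s, coords=coords[None], times=[0.0])
        d = pair_distance(traj, "name CZ", "name CG1")
        assert d.values[0] == pytest.approx(5.0)

    def test_static_trajectory_constant(self):
        coords = np.array([[0.0, 0, 0], [1.0, 1.0, 1.0]])
        s = make_structure(coords, names=["CZ", "CG1"])
        traj = Trajectory(topology=s, coords=np.repeat(coords[None], 5, 0),
                          times=np.arange(5.0))
        d = pair_distance(traj, "name CZ", "name CG1")
        assert np.ptp(d.values) == 0.0

    def test_ambiguous_spec_rejected(self):
        coords = np.zeros((3, 3))
        s = make_structure(coords)
        traj = Trajectory(topology=s, coords=coords[None], times=[0.0])
        with pytest.raises(SelectionError, match="name CA"):
            pair_distance(traj, "name CA", "name CA")

    def test_designed_contact_frames_match_sidecar(self, occupancy_run):
        toy, traj, sidecar = occupancy_run
        d = pair_distance(traj, "chain L and resid 24 and name NZ",
                          "chain R and resid 120 and name OE1")
        truth = np.array(
            next(iter(sidecar["hbonds"].values()))["contact"], dtype=bool
        )
        np.testing.assert_array_equal(d.values <= 3.0, truth)
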