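"""Superposition, RMSF, ligand RMSD, and the nonbonded energy surrogate."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dyncontact import (
    ContactSchedule,
    SyntheticSpec,
    Trajectory,
    build_synthetic_topology,
    generate_replica,
    interaction_energy_series,
    ligand_rmsd,
    nonbonded_energy,
    percent_energy_difference,
    rmsf,
    superpose,
    truncation_compare,
)
from dyncontact.structmetrics import COULOMB_CONST, _charmm_switch

from conftest import build_topology


def _rmsd(a, b):
    return np.sqrt(((a - b) ** 2).sum(axis=-1).mean())


class TestSuperpose:
    def _cloud(self, rng, n=20):
        return rng.normal(size=(n, 3)) * 4.0

    def test_identity(self, rng):
        x = self._cloud(rng)
        out = superpose(x, x, np.arange(len(x)))
        assert _rmsd(out, x) < 1e-10

    def test_translation_removed(self, rng):
        x = self._cloud(rng)
        out = superpose(x + [5.0, -3.0, 2.0], x, np.arange(len(x)))
        assert _rmsd(out, x) < 1e-10

    def test_rotation_recovered(self, rng):
        x = self._cloud(rng)
        R = Rotation.random(random_state=3).as_matrix()
        out = superpose(x @ R.T + [1.0, 2.0, 3.0], x, np.arange(len(x)))
        assert _rmsd(out, x) < 1e-6

    def test_too_few_atoms(self, rng):
        x = self._cloud(rng)
        with pytest.raises(ValueError):
            superpose(x, x, np.array([0, 1]))


class TestRmsf:
    def _traj(self, sigma, n_frames=600, n_res=30, seed=0):
        spec = SyntheticSpec(n_residues=n_res, n_frames=n_frames,
                             fluct_sigma=sigma, seed=seed, schedules=[])
        top = build_synthetic_topology(spec)
        return generate_replica(top, spec, spec.conditions[0], 0)

    def test_static_trajectory_is_zero(self):
        traj = self._traj(0.0, n_frames=5, n_res=4)
        prof = rmsf(traj)
        assert all(v == 0.0 for v in prof.values.values())

    def test_isotropic_jitter_closed_form(self):
        # sigma per axis -> RMSF = sigma * sqrt(3)
        traj = self._traj(0.5)
        prof = rmsf(traj)
        vals = np.array(list(prof.values.values()))
        assert np.allclose(vals, 0.5 * np.sqrt(3), rtol=0.08)

    def test_doubling_sigma_doubles_rmsf(self):
        v1 = np.mean(list(rmsf(self._traj(0.3, seed=1)).values.values()))
        v2 = np.mean(list(rmsf(self._traj(0.6, seed=1)).values.values()))
        assert v2 / v1 == pytest.approx(2.0, rel=0.05)

    def test_per_residue_sigma_profile(self):
        sig = np.full(30, 0.2)
        sig[10] = 0.8
        traj = self._traj(sig)
        prof = rmsf(traj)
        assert prof.values["A:SYN:11"] > 3 * prof.values["A:SYN:1"]

    def test_needs_two_frames(self):
        traj = self._traj(0.1, n_frames=1, n_res=4)
        with pytest.raises(ValueError):
            rmsf(traj)


class TestLigandRmsd:
    def _traj(self, shift_lig=None, shift_all=None):
        spec = SyntheticSpec(n_residues=6, include_ligand=True, n_frames=3,
                             fluct_sigma=0.0, schedules=[])
        top = build_synthetic_topology(spec)
        traj = generate_replica(top, spec, spec.conditions[0], 0)
        lig = top.atom_role() == "ligand"
        if shift_lig is not None:
            traj.coords[1:, lig, :] += shift_lig
        if shift_all is not None:
            traj.coords[1:] += shift_all
        return traj

    def test_reference_frame_zero(self):
        traj = self._traj()
        series = ligand_rmsd(traj, traj.coords[0])
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_rigid_ligand_shift(self):
        traj = self._traj(shift_lig=np.array([3.0, 0.0, 4.0]))
        series = ligand_rmsd(traj, traj.coords[0])
        assert series.rmsd[0] == pytest.approx(0.0, abs=1e-10)
        assert series.rmsd[1] == pytest.approx(5.0, rel=1e-9)
        assert series.mean == pytest.approx(10.0 / 3, rel=1e-9)

    def test_global_motion_removed(self):
        traj = self._traj(shift_all=np.array([7.0, -2.0, 1.0]))
        series = ligand_rmsd(traj, traj.coords[0])
        assert np.allclose(series.rmsd, 0.0, atol=1e-8)

    def test_requires_ligand(self):
        spec = SyntheticSpec(n_residues=4, n_frames=2, schedules=[])
        top = build_synthetic_topology(spec)
        traj = generate_replica(top, spec, spec.conditions[0], 0)
        with pytest.raises(ValueError, match="ligand"):
            ligand_rmsd(traj, traj.coords[0])


def _two_atom_top(q1, q2, rmin_half=1.0, eps=0.1):
    top = build_topology([[("X1", "C")], [("X2", "C")]],
                         roles=["ligand", "protein"],
                         charges=[q1, q2])
    top.lj_rmin_half = np.array([rmin_half, rmin_half])
    top.lj_eps = np.array([eps, eps])
    return top


class TestNonbondedEnergy:
    def test_beyond_cutoff_zero(self):
        top = _two_atom_top(1.0, -1.0)
        coords = np.array([[0, 0, 0], [15.0, 0, 0]])
        assert nonbonded_energy(top, coords, [0], [1]) == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        top = _two_atom_top(0.0, 0.0, rmin_half=2.0, eps=0.25)
        coords = np.array([[0, 0, 0], [4.0, 0, 0.0]])  # r = r_min,ij
        e = nonbonded_energy(top, coords, [0], [1])
        assert e == pytest.approx(-0.25, rel=1e-12)

    def test_unit_charges_at_3A(self):
        top = _two_atom_top(1.0, -1.0, eps=0.0)
        coords = np.array([[0, 0, 0], [3.0, 0, 0.0]])
        e = nonbonded_energy(top, coords, [0], [1])
        assert e == pytest.approx(-COULOMB_CONST / 3.0, rel=1e-12)
        assert e == pytest.approx(-110.69, abs=0.01)

    def test_pairwise_additivity(self, rng):
        # E(A1 u A2 vs B) = E(A1 vs B) + E(A2 vs B)
        top = build_topology(
            [[("A1", "C")], [("A2", "C")], [("B1", "O"), ("B2", "N")]],
            roles=["ligand", "ligand", "protein"],
            charges=[0.3, -0.2, 0.5, -0.4])
        top.ensure_parameters()
        coords = rng.uniform(0, 6, size=(4, 3))
        e_both = nonbonded_energy(top, coords, [0, 1], [2, 3])
        e_split = (nonbonded_energy(top, coords, [0], [2, 3])
                   + nonbonded_energy(top, coords, [1], [2, 3]))
        assert e_both == pytest.approx(e_split, rel=1e-12)

    def test_switching_continuity(self):
        top = _two_atom_top(0.5, -0.5, rmin_half=1.5, eps=0.1)
        r = np.arange(9.0, 12.5, 0.001)
        e = np.array([
            nonbonded_energy(top, np.array([[0, 0, 0], [x, 0, 0.0]]), [0], [1])
            for x in r
        ])
        # steps stay at the smooth-gradient scale everywhere; a hard
        # truncation at either switching boundary would jump by ~7 kcal/mol
        assert np.abs(np.diff(e)).max() < 0.05
        assert e[-1] == 0.0

    def test_switch_polynomial_endpoints(self):
        assert _charmm_switch(np.array([10.0]), 10, 12)[0] == 1.0
        assert _charmm_switch(np.array([12.0]), 10, 12)[0] == 0.0

    def test_missing_parameters_error(self):
        top = build_topology([[("X1", "C")], [("X2", "C")]],
                             roles=["ligand", "protein"])
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="parameter"):
            nonbonded_energy(top, coords, [0], [1])

    def test_energy_series_on_synthetic_ligand(self):
        spec = SyntheticSpec(n_residues=3, include_ligand=True, n_frames=4,
                             fluct_sigma=0.0, schedules=[
                                 ContactSchedule(("LIG", 1), "vdw", 1.0, 1.0)])
        top = build_synthetic_topology(spec)
        traj = generate_replica(top, spec, spec.conditions[0], 0)
        series = interaction_energy_series(traj)
        assert len(series.energy) == 4
        assert np.all(np.isfinite(series.energy))
        assert np.any(series.energy != 0.0)  # probes are in vdW range


class TestPercentDifference:
    def test_printed_thc_binding_energies(self):
        # -53.9 vs -50.1 kcal/mol: the modulator-free complex is more
        # stable by about 7.5 percent
        assert percent_energy_difference(-53.9, -50.1) == pytest.approx(
            7.58, abs=0.01)

    def test_equal_inputs(self):
        assert percent_energy_difference(-50.0, -50.0) == 0.0

    def test_simple_ratio(self):
        assert percent_energy_difference(-60, -50) == pytest.approx(20.0)

    def test_zero_errors(self):
        with pytest.raises(ValueError):
            percent_energy_difference(0.0, -50.0)


class TestTruncationCompare:
    def test_printed_variant_means(self):
        data = {
            "WT": {"cbd_energy": [-72.7]},
            "d8": {"cbd_energy": [-63.29], "cbd_rmsd": [12.5]},
            "d88": {"cbd_energy": [-58.49], "cbd_rmsd": [5.7]},
            "d98": {"cbd_energy": [-57.83], "cbd_rmsd": [7.7]},
        }
        df = truncation_compare(data).table.set_index("variant")
        assert df.loc["d8", "ddE_vs_wt"] == pytest.approx(9.41, abs=0.01)
        assert df.loc["d88", "ddE_vs_wt"] == pytest.approx(14.21, abs=0.01)
        assert df.loc["d98", "ddE_vs_wt"] == pytest.approx(14.87, abs=0.01)
        assert df.loc["WT", "ddE_vs_wt"] == 0.0

    def test_equal_to_wt_gives_zero(self):
        data = {"WT": {"cbd_energy": [-10.0]}, "v": {"cbd_energy": [-10.0]}}
        df = truncation_compare(data).table.set_index("variant")
        assert df.loc["v", "ddE_vs_wt"] == 0.0

    def test_missing_wt_warns(self):
        with pytest.warns(UserWarning, match="baseline"):
            comp = truncation_compare({"v": {"cbd_energy": [-10.0]}})
        assert "ddE_vs_wt" not in comp.table.columns

    def test_programmed_energy_offset_recovered(self, rng):
        base = rng.normal(-50, 2, size=200)
        data = {"WT": {"cbd_energy": base},
                "v": {"cbd_energy": base + 10.0}}
        df = truncation_compare(data).table.set_index("variant")
        assert df.loc["v", "ddE_vs_wt"] == pytest.approx(10.0, abs=1e-9)
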