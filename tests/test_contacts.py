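"""Geometric contact criteria, detector equivalences, and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dyncontact import ContactCriteria, Trajectory, detect_frame, detect_trajectory
from dyncontact.contacts import INTERACTION_CLASSES

from conftest import build_topology, random_contact_topology, reference_detect


def _classes_of(events):
    return {(e.interaction_class, *e.key) for e in events}


class TestHydrogenBond:
    def _top(self):
        # res1: N-H donor; res2: O acceptor
        return build_topology(
            [[("N", "N"), ("HN", "H")], [("O", "O")]],
            donors=[(0, [1])], acceptors=[2],
        )

    def test_collinear_within_distance(self):
        top = self._top()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0.0]])
        ev = _classes_of(detect_frame(top, coords, classes={"hbond"}))
        assert ("hbond", "A:RES:1", "A:RES:2") in ev

    def test_bent_geometry_rejected(self):
        top = self._top()
        # angle at H is 90 degrees, below the 110 degree minimum
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0.0]])
        assert not detect_frame(top, coords, classes={"hbond"})

    def test_distance_boundary_inclusive(self):
        top = self._top()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [3.5, 0, 0.0]])
        assert detect_frame(top, coords, classes={"hbond"})
        coords[2, 0] = 3.51
        assert not detect_frame(top, coords, classes={"hbond"})

    def test_hydrogen_free_distance_only(self):
        # crystal-structure style input: donor has no hydrogens
        top = build_topology([[("N", "N")], [("O", "O")]],
                             donors=[(0, [])], acceptors=[1])
        coords = np.array([[0, 0, 0], [3.4, 0, 0.0]])
        assert detect_frame(top, coords, classes={"hbond"})


class TestSaltBridge:
    def _top(self):
        return build_topology(
            [[("NZ", "N")], [("OE1", "O")]],
            cationic=[[0]], anionic=[[1]],
        )

    @pytest.mark.parametrize("d,hit", [(5.0, False), (4.0, True), (3.0, True)])
    def test_distance_criterion(self, d, hit):
        coords = np.array([[0, 0, 0], [d, 0, 0.0]])
        ev = detect_frame(self._top(), coords, classes={"salt_bridge"})
        assert bool(ev) is hit


class TestVdw:
    def test_radii_sum_boundary_inclusive(self):
        top = build_topology([[("CB", "C")], [("CB", "C")]])
        coords = np.array([[0, 0, 0], [3.9, 0, 0.0]])  # 1.7 + 1.7 + 0.5
        assert detect_frame(top, coords, classes={"vdw"})
        coords[1, 0] = 3.901
        assert not detect_frame(top, coords, classes={"vdw"})

    def test_suppressed_when_hbonded(self):
        top = build_topology(
            [[("N", "N"), ("HN", "H")], [("O", "O")]],
            donors=[(0, [1])], acceptors=[2],
        )
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0.0]])
        ev = detect_frame(top, coords, classes={"hbond", "vdw"})
        assert {e.interaction_class for e in ev} == {"hbond"}
        # vdw-only request still suppresses the double count
        ev = detect_frame(top, coords, classes={"vdw"})
        assert not ev

    def test_adjacent_backbone_pairs_excluded(self):
        top = build_topology([[("C", "C")], [("N", "N")]])
        coords = np.array([[0, 0, 0], [3.0, 0, 0.0]])
        assert not detect_frame(top, coords, classes={"vdw"})
        # same geometry through side-chain names is a contact
        top2 = build_topology([[("CB", "C")], [("ND1", "N")]])
        assert detect_frame(top2, coords, classes={"vdw"})


class TestPiStack:
    def _top_coords(self, offset, tilt_deg=0.0):
        top = build_topology(
            [[(f"C{i}", "C") for i in range(6)],
             [(f"C{i}", "C") for i in range(6)]],
            rings=[list(range(6)), list(range(6, 12))],
        )
        ang = np.radians(np.arange(6) * 60.0)
        hexagon = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], 1) * 1.4
        ring2 = hexagon @ Rotation.from_euler(
            "x", tilt_deg, degrees=True).as_matrix().T + offset
        return top, np.vstack([hexagon, ring2])

    def test_parallel_stack(self):
        top, coords = self._top_coords(np.array([0, 0, 4.5]))
        assert detect_frame(top, coords, classes={"pi_stack"})

    def test_too_far(self):
        top, coords = self._top_coords(np.array([0, 0, 7.5]))
        assert not detect_frame(top, coords, classes={"pi_stack"})

    def test_perpendicular_rejected_antiparallel_kept(self):
        top, coords = self._top_coords(np.array([0, 0, 5.0]), tilt_deg=90)
        assert not detect_frame(top, coords, classes={"pi_stack"})
        top, coords = self._top_coords(np.array([0, 0, 5.0]), tilt_deg=175)
        assert detect_frame(top, coords, classes={"pi_stack"})

    def test_no_rings_warns_empty(self):
        top = build_topology([[("CB", "C")], [("CB", "C")]])
        coords = np.array([[0, 0, 0], [20.0, 0, 0]])
        with pytest.warns(UserWarning, match="pi_stack"):
            ev = detect_frame(top, coords, classes={"pi_stack"})
        assert ev == set()


class TestWaterBridge:
    def _top(self, middle_role="water"):
        roles = ["protein", "protein", middle_role]
        mid = [("O", "O"), ("H1", "H"), ("H2", "H")] if middle_role == "water" \
            else [("NA", "NA")]
        top = build_topology(
            [[("O", "O")], [("O", "O")], mid],
            acceptors=[0, 1], roles=roles,
        )
        if middle_role == "water":
            from dyncontact.topology import Donor
            top.donors.append(Donor(2, (3, 4)))
            top.acceptors.append(2)
        return top

    def test_single_water_bridge(self):
        top = self._top()
        coords = np.array([
            [-2.8, 0, 0], [2.8, 0, 0],
            [0, 0, 0], [-0.95, 0, 0], [0.95, 0, 0.0],
        ])
        ev = _classes_of(detect_frame(top, coords, classes={"water_bridge"}))
        assert ("water_bridge", "A:RES:1", "A:RES:2") in ev

    def test_ion_is_not_a_bridge(self):
        top = self._top(middle_role="ion")
        coords = np.array([[-2.8, 0, 0], [2.8, 0, 0], [0, 0, 0.0]])
        assert not detect_frame(top, coords, classes={"water_bridge"})

    def test_direct_and_bridged_coexist(self):
        top = build_topology(
            [[("N", "N"), ("HN", "H")], [("O", "O")],
             [("O", "O"), ("H1", "H"), ("H2", "H")]],
            donors=[(0, [1])], acceptors=[2],
            roles=["protein", "protein", "water"],
        )
        from dyncontact.topology import Donor
        top.donors.append(Donor(3, (4, 5)))
        top.acceptors.append(3)
        coords = np.array([
            [0, 0, 0], [1.0, 0, 0], [2.9, 0, 0],  # direct H-bond
            # bridging water: accepts from the N-H, donates H2 to the O
            [2.2, 1.8, 0], [1.465, 1.199, 0], [2.545, 0.914, 0.0],
        ])
        classes = {e.interaction_class
                   for e in detect_frame(top, coords,
                                         classes={"hbond", "water_bridge"})}
        assert classes == {"hbond", "water_bridge"}


class TestDetectorEquivalence:
    def test_grid_equals_bruteforce_oracle(self, rng):
        crit = ContactCriteria()
        for _ in range(100):
            top, coords = random_contact_topology(rng)
            expected = reference_detect(top, coords, crit,
                                        set(INTERACTION_CLASSES))
            for method in ("brute", "grid"):
                got = _classes_of(
                    detect_frame(top, coords, crit, method=method))
                assert got == expected

    def test_rigid_motion_invariance(self, rng):
        top, coords = random_contact_topology(rng)
        ev0 = _classes_of(detect_frame(top, coords))
        R = Rotation.random(random_state=7).as_matrix()
        moved = coords @ R.T + np.array([13.0, -4.0, 8.0])
        assert _classes_of(detect_frame(top, moved)) == ev0

    def test_threshold_monotonicity(self, rng):
        top, coords = random_contact_topology(rng)
        base = ContactCriteria()
        larger = ContactCriteria(
            hbond_da_max=4.5, sb_max=5.0, vdw_pad=1.0,
            pi_centroid_max=8.0, pi_normal_angle_max=45.0,
            hbond_angle_min=90.0,
        )
        for cls in ("hbond", "salt_bridge", "pi_stack"):
            small = _classes_of(detect_frame(top, coords, base, {cls}))
            big = _classes_of(detect_frame(top, coords, larger, {cls}))
            assert small <= big

    def test_keys_canonical(self, rng):
        top, coords = random_contact_topology(rng)
        for e in detect_frame(top, coords):
            assert e.key[0] <= e.key[1]


def test_trajectory_event_counts(rng):
    from dyncontact import ContactSchedule, SyntheticSpec, generate_condition_sets

    spec = SyntheticSpec(n_residues=2, n_frames=50, seed=9, schedules=[
        ContactSchedule((1, 2), "hbond", 1.0, 0.0)])
    _, ta, tb = generate_condition_sets(spec)
    ev = detect_trajectory(ta[0], classes=["hbond"])
    assert len(ev) == 50
    assert detect_trajectory(tb[0], classes=["hbond"]).empty

    empty = detect_trajectory(ta[0], classes=[])
    assert empty.empty


def test_trajectory_brute_equals_grid(rng):
    top, coords = random_contact_topology(rng)
    frames = np.array([coords + rng.normal(0, 0.2, coords.shape)
                       for _ in range(8)])
    traj = Trajectory(top, frames, np.arange(8.0))
    a = detect_trajectory(traj, method="brute")
    b = detect_trajectory(traj, method="grid")
    assert a.equals(b)
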