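"""Shared fixtures: hand-built topologies and an independent, plain-loop
reference contact detector used as the oracle for the optimised paths."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dyncontact.topology import Donor, Topology, annotate_topology


def build_topology(residues, donors=(), acceptors=(), cationic=(), anionic=(),
                   rings=(), charges=None, roles=None):
    """Construct a Topology from a compact residue description.

    ``residues`` is a list of lists of (atom_name, element) per residue;
    annotation arguments use flat atom indices.
    """
    names, elements, res_index = [], [], []
    res_chain, res_number, res_name, res_role = [], [], [], []
    for ri, atoms in enumerate(residues):
        role = roles[ri] if roles else "protein"
        res_chain.append("A" if role != "ligand" else "L")
        res_number.append(ri + 1)
        res_name.append("RES" if role == "protein" else
                        ("LIG" if role == "ligand" else "HOH"))
        res_role.append(role)
        for name, element in atoms:
            names.append(name)
            elements.append(element)
            res_index.append(ri)
    top = Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_index=np.array(res_index, dtype=int),
        res_chain=np.array(res_chain, dtype=object),
        res_number=np.array(res_number, dtype=int),
        res_name=np.array(res_name, dtype=object),
        res_role=np.array(res_role, dtype=object),
        donors=[Donor(a, tuple(h)) for a, h in donors],
        acceptors=list(acceptors),
        cationic_groups=[list(g) for g in cationic],
        anionic_groups=[list(g) for g in anionic],
        rings=[list(r) for r in rings],
        charges=np.array(charges, dtype=float) if charges is not None else None,
    )
    return top


def random_contact_topology(rng, box=14.0):
    """~30 atoms with every annotation type, at random positions in a box
    small enough that all interaction classes actually occur."""
    residues, donors, acceptors, cationic, anionic, rings = [], [], [], [], [], []
    idx = 0
    # two aromatic residues (6-C rings)
    for _ in range(2):
        residues.append([(f"C{j}", "C") for j in range(6)])
        rings.append(list(range(idx, idx + 6)))
        idx += 6
    # one cationic, one anionic residue
    residues.append([("NZ", "N"), ("HZ", "H")])
    cationic.append([idx])
    donors.append((idx, [idx + 1]))
    idx += 2
    residues.append([("OE1", "O"), ("OE2", "O")])
    anionic.append([idx, idx + 1])
    acceptors.extend([idx, idx + 1])
    idx += 2
    # three polar residues: donor N-H plus acceptor O
    for _ in range(3):
        residues.append([("N", "N"), ("HN", "H"), ("O", "O")])
        donors.append((idx, [idx + 1]))
        acceptors.append(idx + 2)
        idx += 3
    # two plain-carbon residues
    for _ in range(2):
        residues.append([("CB", "C"), ("CG", "C")])
        idx += 2
    top = build_topology(residues, donors=donors, acceptors=acceptors,
                         cationic=cationic, anionic=anionic, rings=rings)
    coords = rng.uniform(0, box, size=(top.n_atoms, 3))
    # keep ring atoms planar-ish hexagons so normals are meaningful
    for ring in top.rings:
        center = coords[ring[0]]
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        u = np.cross(axis, [1.0, 0.3, 0.2])
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        for k, a in enumerate(ring):
            ang = math.radians(60 * k)
            coords[a] = center + 1.4 * (math.cos(ang) * u + math.sin(ang) * v)
    return top, coords


# ---------------------------------------------------------------------------
# independent reference detector: plain Python loops, no shared code with
# dyncontact.contacts beyond the Topology annotations
# ---------------------------------------------------------------------------

def _angle(p_apex, p_a, p_b):
    v1, v2 = p_a - p_apex, p_b - p_apex
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _hbond_ok(coords, donor, acc, crit):
    d = np.linalg.norm(coords[donor.atom] - coords[acc])
    if d > crit.hbond_da_max:
        return False
    if not donor.hydrogens:
        return True
    return any(
        _angle(coords[h], coords[donor.atom], coords[acc])
        >= crit.hbond_angle_min
        for h in donor.hydrogens
    )


def reference_detect(top, coords, crit, classes):
    """O(n²) reference: returns set of (class, key1, key2) tuples."""
    res = top.res_index
    role = top.atom_role()
    keys = top.residue_keys()

    def pair(i, j):
        a, b = keys[res[i]], keys[res[j]]
        return (a, b) if a <= b else (b, a)

    out = set()
    hb_pairs, sb_pairs = set(), set()
    for don in top.donors:
        if role[don.atom] not in ("protein", "ligand"):
            continue
        for acc in top.acceptors:
            if role[acc] not in ("protein", "ligand"):
                continue
            if res[don.atom] == res[acc]:
                continue
            if _hbond_ok(coords, don, acc, crit):
                hb_pairs.add(pair(don.atom, acc))
    for grp_c in top.cationic_groups:
        for grp_a in top.anionic_groups:
            for i in grp_c:
                if top.elements[i] != "N":
                    continue
                for j in grp_a:
                    if top.elements[j] != "O" or res[i] == res[j]:
                        continue
                    if np.linalg.norm(coords[i] - coords[j]) <= crit.sb_max:
                        sb_pairs.add(pair(i, j))
    if "hbond" in classes:
        out |= {("hbond",) + p for p in hb_pairs}
    if "salt_bridge" in classes:
        out |= {("salt_bridge",) + p for p in sb_pairs}
    if "pi_stack" in classes:
        for x in range(len(top.rings)):
            for y in range(x + 1, len(top.rings)):
                r1, r2 = top.rings[x], top.rings[y]
                if res[r1[0]] == res[r2[0]]:
                    continue
                c1 = coords[r1].mean(axis=0)
                c2 = coords[r2].mean(axis=0)
                if np.linalg.norm(c1 - c2) > crit.pi_centroid_max:
                    continue

                def normal(ring, c):
                    n = np.zeros(3)
                    pts = [coords[a] - c for a in ring]
                    for k in range(len(pts)):
                        n += np.cross(pts[k], pts[(k + 1) % len(pts)])
                    return n / np.linalg.norm(n)

                cosang = abs(np.dot(normal(r1, c1), normal(r2, c2)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang <= crit.pi_normal_angle_max:
                    out.add(("pi_stack",) + pair(r1[0], r2[0]))
    if "vdw" in classes:
        from dyncontact.topology import BACKBONE_NAMES, ELEMENT_VDW_RADIUS

        heavy = [i for i in range(top.n_atoms)
                 if top.elements[i] != "H" and role[i] in ("protein", "ligand")]
        for a in range(len(heavy)):
            for b in range(a + 1, len(heavy)):
                i, j = heavy[a], heavy[b]
                ri, rj = res[i], res[j]
                if ri == rj:
                    continue
                adjacent = (
                    top.res_chain[ri] == top.res_chain[rj]
                    and abs(int(top.res_number[ri]) - int(top.res_number[rj])) == 1
                )
                if (adjacent and str(top.atom_names[i]) in BACKBONE_NAMES
                        and str(top.atom_names[j]) in BACKBONE_NAMES):
                    continue
                rsum = (ELEMENT_VDW_RADIUS.get(top.elements[i], 1.7)
                        + ELEMENT_VDW_RADIUS.get(top.elements[j], 1.7))
                if np.linalg.norm(coords[i] - coords[j]) <= rsum + crit.vdw_pad:
                    p = pair(i, j)
                    if p not in hb_pairs and p not in sb_pairs:
                        out.add(("vdw",) + p)
    if "water_bridge" in classes:
        for wd in top.donors:
            if role[wd.atom] != "water":
                continue
            touched = set()
            for don in top.donors:
                if role[don.atom] in ("protein", "ligand"):
                    if _hbond_ok(coords, don, wd.atom, crit):
                        touched.add(res[don.atom])
            for acc in top.acceptors:
                if role[acc] in ("protein", "ligand"):
                    if _hbond_ok(coords, wd, acc, crit):
                        touched.add(res[acc])
            mem = sorted(touched)
            for x in range(len(mem)):
                for y in range(x + 1, len(mem)):
                    a, b = keys[mem[x]], keys[mem[y]]
                    out.add(("water_bridge",) + ((a, b) if a <= b else (b, a)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
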