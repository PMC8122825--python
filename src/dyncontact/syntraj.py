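"""Synthetic topologies and trajectory ensembles with programmed contacts.

This module emulates the study design the analysis pipeline targets — two
ligand conditions with five replica trajectories each — as fully synthetic
coordinate sets in which every scheduled contact's per-frame occupancy is an
independent Bernoulli draw with a known, condition-dependent probability.
Downstream detection, fingerprinting and differential statistics can then
be validated against the programmed ground truth.

Geometry model
--------------
Residues are minimal four-atom bodies (CA, N/HN donor, O acceptor) placed on
a wide grid (30 Å spacing) so that no unscheduled inter-residue contact can
occur.  Each scheduled contact owns dedicated *probe atoms* on both partner
residues plus a private rendezvous *site* far from all residue bodies.  In
frames where the contact is "on", the probes sit at the site in an ideal,
mid-threshold geometry (e.g. donor–acceptor 2.9 Å, collinear); in "off"
frames they are parked near their home residue, ≥ 10 Å from any partner.
Every atom additionally jitters with isotropic Gaussian noise of standard
deviation ``fluct_sigma`` per axis — small enough never to flip a contact
state, and exactly what the RMSF calibration (RMSF = σ√3) measures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import Topology, annotate_topology
from .traj_io import Trajectory, write_manifest, write_topology_pdb, write_trajectory

__all__ = [
    "ContactSchedule",
    "SyntheticSpec",
    "build_synthetic_topology",
    "generate_replica",
    "generate_condition_sets",
    "write_fixture_set",
]

LIGAND_ENDPOINT = "LIG"
_GRID = 30.0          # Å between residue homes / contact sites
_SITE_Z = 500.0       # rendezvous plane
_WATER_Z = -500.0     # parking plane for bridge waters in "off" frames
_ROW = 16             # grid columns


@dataclass(frozen=True)
class ContactSchedule:
    """One programmed contact: endpoints, class, per-condition probability.

    Endpoints are 1-based residue indices, or the string ``"LIG"`` for the
    ligand residue.  The key is stored canonically (sorted endpoints).
    """

    contact_key: tuple
    interaction_class: str
    p_condition_A: float
    p_condition_B: float

    def __post_init__(self) -> None:
        if self.interaction_class not in (
            "hbond", "water_bridge", "salt_bridge", "pi_stack", "vdw"
        ):
            raise ValueError(f"unknown interaction class {self.interaction_class}")
        for p in (self.p_condition_A, self.p_condition_B):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        a, b = self.contact_key
        object.__setattr__(self, "contact_key", tuple(sorted((a, b), key=str)))

    def p(self, which: str) -> float:
        return self.p_condition_A if which == "A" else self.p_condition_B


@dataclass
class SyntheticSpec:
    """Design of a synthetic two-condition replica ensemble."""

    n_residues: int = 8
    include_ligand: bool = False
    n_replicas_per_condition: int = 5
    n_frames: int = 1000
    dt: float = 1.0                     # ns per frame
    fluct_sigma: float | np.ndarray = 0.05   # Å per axis, scalar or per-residue
    schedules: list[ContactSchedule] = field(default_factory=list)
    seed: int = 0
    conditions: tuple[str, str] = ("CBD-THC", "THC-only")

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        sig = np.asarray(self.fluct_sigma, dtype=float)
        if np.any(sig < 0):
            raise ValueError("fluct_sigma must be >= 0")
        if sig.ndim == 1 and len(sig) != self.n_residues:
            raise ValueError("per-residue fluct_sigma must have n_residues entries")

    def sigma_for(self, n_total_residues: int) -> np.ndarray:
        sig = np.asarray(self.fluct_sigma, dtype=float)
        if sig.ndim == 0:
            return np.full(n_total_residues, float(sig))
        out = np.full(n_total_residues, float(sig.mean()))
        out[: len(sig)] = sig
        return out


def _resolve_endpoint(ep, spec: SyntheticSpec) -> int:
    """Map a schedule endpoint to a 0-based residue serial."""
    if ep == LIGAND_ENDPOINT:
        if not spec.include_ligand:
            raise ValueError("schedule references the ligand but "
                             "include_ligand is False")
        return spec.n_residues  # ligand sits after protein residues
    idx = int(ep)
    if not 1 <= idx <= spec.n_residues:
        raise ValueError(
            f"schedule endpoint {ep!r} outside [1, {spec.n_residues}]"
        )
    return idx - 1


def _home(i: int) -> np.ndarray:
    return np.array([_GRID * (i % _ROW), _GRID * (i // _ROW), 0.0])


def _site(k: int) -> np.ndarray:
    return np.array([_GRID * (k % _ROW), _GRID * (k // _ROW), _SITE_Z])


def _hexagon(center: np.ndarray, radius: float = 1.4) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1) * radius
    return center + pts


class _SynLayout:
    """Per-schedule probe atom indices and on/off positions."""

    def __init__(self):
        self.probe_atoms: list[np.ndarray] = []   # atom indices per schedule
        self.on_pos: list[np.ndarray] = []        # matching positions, on state
        self.resolved: list[tuple[int, int]] = []  # residue serials per schedule


def build_synthetic_topology(spec: SyntheticSpec) -> Topology:
    """Construct the scaffold topology realizing every scheduled class."""
    names, elements, res_index = [], [], []
    res_chain, res_number, res_name, res_role = [], [], [], []
    coords = []
    charges = []

    def add_residue(chain, number, rname, role):
        res_chain.append(chain)
        res_number.append(number)
        res_name.append(rname)
        res_role.append(role)
        return len(res_name) - 1

    def add_atom(ri, name, element, pos, q=0.0):
        names.append(name)
        elements.append(element)
        res_index.append(ri)
        coords.append(np.asarray(pos, dtype=float))
        charges.append(q)
        return len(names) - 1

    n_total = spec.n_residues + (1 if spec.include_ligand else 0)
    for i in range(spec.n_residues):
        ri = add_residue("A", i + 1, "SYN", "protein")
        h = _home(i)
        add_atom(ri, "CA", "C", h, 0.0)
        add_atom(ri, "N", "N", h + (1.5, 0.0, 0.0), -0.35)
        add_atom(ri, "HN", "H", h + (2.5, 0.0, 0.0), 0.35)
        add_atom(ri, "O", "O", h + (0.0, 1.5, 0.0), 0.0)
    if spec.include_ligand:
        ri = add_residue("L", 1, "LIG", "ligand")
        add_atom(ri, "C1", "C", _home(spec.n_residues), 0.0)

    layout = _SynLayout()
    probe_count = np.zeros(n_total, dtype=int)  # parked-set counter per residue
    ring_count = np.zeros(n_total, dtype=int)   # ring-name counter per residue

    def park(ri: int) -> np.ndarray:
        probe_count[ri] += 1
        return _home(ri) + (0.0, 0.0, 5.0 * probe_count[ri])

    water_serial = 0
    for k, sched in enumerate(spec.schedules):
        a, b = sched.contact_key
        ra, rb = _resolve_endpoint(a, spec), _resolve_endpoint(b, spec)
        if ra == rb:
            raise ValueError(f"schedule {sched.contact_key}: endpoints coincide")
        s = _site(k)
        tag = f"{k:02d}"
        atoms, on = [], []
        cls = sched.interaction_class
        if cls == "hbond":
            pa = park(ra)
            atoms.append(add_atom(ra, "DN" + tag, "N", pa, -0.35))
            on.append(s)
            atoms.append(add_atom(ra, "DH" + tag, "H", pa + (1.0, 0, 0), 0.35))
            on.append(s + (1.0, 0.0, 0.0))
            atoms.append(add_atom(rb, "AO" + tag, "O", park(rb), -0.40))
            on.append(s + (2.9, 0.0, 0.0))
        elif cls == "salt_bridge":
            atoms.append(add_atom(ra, "CN" + tag, "N", park(ra), 1.0))
            on.append(s)
            atoms.append(add_atom(rb, "XO" + tag, "O", park(rb), -1.0))
            on.append(s + (3.5, 0.0, 0.0))
        elif cls == "vdw":
            atoms.append(add_atom(ra, "VC" + tag, "C", park(ra), 0.0))
            on.append(s)
            atoms.append(add_atom(rb, "VC" + tag, "C", park(rb), 0.0))
            on.append(s + (3.5, 0.0, 0.0))
        elif cls == "pi_stack":
            # one ring per endpoint, eclipsed, 4.5 Å apart along the normal
            for ri, zoff in ((ra, 0.0), (rb, 4.5)):
                ring_count[ri] += 1
                rtag = str(ring_count[ri])
                center_off = park(ri)
                hex_on = _hexagon(s + (0.0, 0.0, zoff))
                hex_off = _hexagon(center_off)
                for m, letter in enumerate("ABCDEF"):
                    atoms.append(
                        add_atom(ri, f"R{rtag}{letter}", "C", hex_off[m], 0.0))
                    on.append(hex_on[m])
        elif cls == "water_bridge":
            atoms.append(add_atom(ra, "AO" + tag, "O", park(ra), -0.40))
            on.append(s + (-2.8, 0.0, 0.0))
            atoms.append(add_atom(rb, "AO" + tag, "O", park(rb), -0.40))
            on.append(s + (2.8, 0.0, 0.0))
            water_serial += 1
            wri = add_residue("W", water_serial, "HOH", "water")
            wpark = np.array([_GRID * (k % _ROW), _GRID * (k // _ROW), _WATER_Z])
            atoms.append(add_atom(wri, "O", "O", wpark, -0.834))
            on.append(s)
            atoms.append(add_atom(wri, "H1", "H", wpark + (-0.95, 0, 0), 0.417))
            on.append(s + (-0.95, 0.0, 0.0))
            atoms.append(add_atom(wri, "H2", "H", wpark + (0.95, 0, 0), 0.417))
            on.append(s + (0.95, 0.0, 0.0))
        layout.probe_atoms.append(np.array(atoms, dtype=int))
        layout.on_pos.append(np.array(on, dtype=float))
        layout.resolved.append((ra, rb))

    top = Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_index=np.array(res_index, dtype=int),
        res_chain=np.array(res_chain, dtype=object),
        res_number=np.array(res_number, dtype=int),
        res_name=np.array(res_name, dtype=object),
        res_role=np.array(res_role, dtype=object),
        charges=np.array(charges, dtype=float),
        reference_coords=np.array(coords, dtype=float),
    )
    top.ensure_parameters()
    annotate_topology(top)
    top.syn_layout = layout  # type: ignore[attr-defined]
    return top


def _replica_rng(seed: int, condition: str, replica_index: int) -> np.random.Generator:
    # decoupled, process-stable replica streams (crc32 in place of hash())
    mix = zlib.crc32(f"{condition}|{replica_index}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, mix]))


def generate_replica(topology: Topology, spec: SyntheticSpec, condition: str,
                     replica_index: int) -> Trajectory:
    """One replica trajectory: Bernoulli contact states plus Gaussian jitter.

    Reproducible given (spec.seed, condition, replica_index).
    """
    if condition not in spec.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; spec defines {spec.conditions}"
        )
    layout: _SynLayout = getattr(topology, "syn_layout", None)
    if layout is None:
        raise ValueError("topology was not built by build_synthetic_topology")
    which = "A" if condition == spec.conditions[0] else "B"
    rng = _replica_rng(spec.seed, condition, replica_index)

    F = spec.n_frames
    base = topology.reference_coords
    coords = np.repeat(base[None], F, axis=0)

    if spec.schedules:
        p = np.array([s.p(which) for s in spec.schedules])
        on = rng.random((F, len(spec.schedules))) < p[None, :]
        for k in range(len(spec.schedules)):
            idx = layout.probe_atoms[k]
            frames_on = np.where(on[:, k])[0]
            if len(frames_on):
                coords[np.ix_(frames_on, idx)] = layout.on_pos[k][None]

    sigma_res = spec.sigma_for(topology.n_residues)
    sigma_atom = sigma_res[topology.res_index]
    if np.any(sigma_atom > 0):
        coords += rng.normal(size=coords.shape) * sigma_atom[None, :, None]

    time = spec.dt * np.arange(F)
    return Trajectory(topology, coords, time, condition=condition,
                      replica_id=f"rep{replica_index}")


def generate_condition_sets(spec: SyntheticSpec):
    """All replicas for both conditions, sharing one topology.

    Returns (topology, trajectories_A, trajectories_B).
    """
    top = build_synthetic_topology(spec)
    trajs_a = [
        generate_replica(top, spec, spec.conditions[0], r)
        for r in range(spec.n_replicas_per_condition)
    ]
    trajs_b = [
        generate_replica(top, spec, spec.conditions[1], r)
        for r in range(spec.n_replicas_per_condition)
    ]
    return top, trajs_a, trajs_b


def write_fixture_set(spec: SyntheticSpec, outdir, fmt: str = "dcd") -> Path:
    """Write topology PDB, per-replica trajectories, and a YAML manifest.

    Returns the manifest path; this manifest is the pipeline's standard
    input format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top, trajs_a, trajs_b = generate_condition_sets(spec)
    top_path = outdir / "topology.pdb"
    write_topology_pdb(top, top_path)
    conditions: dict[str, dict[str, list[str]]] = {}
    for traj in trajs_a + trajs_b:
        fname = f"{traj.condition}_{traj.replica_id}.{fmt}".replace("/", "_")
        write_trajectory(traj, outdir / fname, fmt=fmt)
        conditions.setdefault(traj.condition, {})[traj.replica_id] = [fname]
    manifest = outdir / "manifest.yaml"
    write_manifest(manifest, "topology.pdb", conditions, dt=spec.dt)
    return manifest
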