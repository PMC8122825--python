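"""Topology/trajectory reading, writing, slicing, and manifests.

PDB files (topology and multi-model frames) are handled through biotite;
DCD binary trajectories through MDAnalysis.  Coordinates are in Å, times in
ns, frames 0-indexed.  A manifest (YAML or JSON) of the form::

    topology: topology.pdb
    dt: 1.0
    conditions:
      CBD-THC: {rep0: [rep0.dcd], rep1: [rep1.dcd]}
      THC-only: {rep0: [rep0.dcd], ...}

is the pipeline's standard input, grouping replica trajectory files under
condition labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .topology import Topology, annotate_topology, classify_role

__all__ = [
    "Trajectory",
    "TopologyParseError",
    "read_topology",
    "read_trajectory",
    "slice_analysis_range",
    "write_topology_pdb",
    "write_trajectory",
    "read_manifest",
    "write_manifest",
]


class TopologyParseError(ValueError):
    """Raised for malformed PDB records, citing the offending line."""


@dataclass
class Trajectory:
    """Ordered coordinate frames bound to a Topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``time`` is ns per
    frame and strictly increasing.
    """

    topology: Topology
    coords: np.ndarray
    time: np.ndarray
    condition: str = ""
    replica_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.time) != self.coords.shape[0]:
            raise ValueError("time and frame counts differ")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _prescan_pdb(path: Path) -> None:
    """Validate ATOM/HETATM record lengths, raising with the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
                raise TopologyParseError(
                    f"{path}:{lineno}: truncated {rec} record "
                    f"(only {len(line.rstrip())} columns, need coordinates)"
                )


def read_topology(path, ligand_resnames=()) -> Topology:
    """Parse a PDB file into an annotated Topology.

    Residues are classified by role from residue names: waters (HOH/WAT/
    TIP3/...), ions by standard names, names in ``ligand_resnames`` as
    ligand, everything else protein.  Chemical annotations come from the
    built-in amino-acid templates and registered ligand templates.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    _prescan_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # malformed file beyond the pre-scan
        raise TopologyParseError(f"{path}: unparseable PDB: {exc}") from exc

    lig = {r.upper() for r in ligand_resnames}
    n = atoms.array_length()
    elements = np.array([e.upper() if e else "C" for e in atoms.element])

    res_index = np.empty(n, dtype=int)
    res_chain, res_number, res_name = [], [], []
    last = None
    ri = -1
    for i in range(n):
        key = (atoms.chain_id[i], int(atoms.res_id[i]), atoms.res_name[i])
        if key != last:
            ri += 1
            last = key
            res_chain.append(atoms.chain_id[i] or "A")
            res_number.append(int(atoms.res_id[i]))
            res_name.append(atoms.res_name[i])
        res_index[i] = ri

    res_role = np.array([classify_role(rn, lig) for rn in res_name])
    top = Topology(
        atom_names=np.array(atoms.atom_name, dtype=object),
        elements=elements,
        res_index=res_index,
        res_chain=np.array(res_chain, dtype=object),
        res_number=np.array(res_number, dtype=int),
        res_name=np.array(res_name, dtype=object),
        res_role=res_role,
        reference_coords=np.array(atoms.coord, dtype=float),
    )
    return annotate_topology(top)


def _read_frames(path: Path, n_atoms_expected: int) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="DCDReader currently makes independent")
            reader = DCDReader(str(path))
            if reader.n_atoms != n_atoms_expected:
                raise ValueError(
                    f"{path}: atom count mismatch (file has {reader.n_atoms}, "
                    f"topology expects {n_atoms_expected})"
                )
            frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
            reader.close()
        return frames
    if suffix in (".pdb", ".ent"):
        from biotite.structure.io.pdb import PDBFile

        _prescan_pdb(path)
        stack = PDBFile.read(str(path)).get_structure()
        coords = np.atleast_3d(stack.coord)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != n_atoms_expected:
            raise ValueError(
                f"{path}: atom count mismatch (file has {coords.shape[1]}, "
                f"topology expects {n_atoms_expected})"
            )
        return np.array(coords, dtype=float)
    raise ValueError(f"{path}: unsupported trajectory format '{suffix}'")


def read_trajectory(topology: Topology, paths, condition: str = "",
                    replica_id: str = "", dt: float = 1.0) -> Trajectory:
    """Concatenate frame files (multi-model PDB and/or DCD) into a Trajectory.

    Frame timestamps are ``dt * frame_index`` ns starting at 0.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    blocks = [_read_frames(Path(p), topology.n_atoms) for p in paths]
    coords = np.concatenate(blocks, axis=0)
    time = dt * np.arange(coords.shape[0])
    return Trajectory(topology, coords, time, condition, replica_id)


def slice_analysis_range(traj: Trajectory, start: float, end: float) -> Trajectory:
    """Keep frames with start <= time <= end (inclusive endpoints), e.g. the
    100 ns–1 µs production window after discarding initial relaxation."""
    if start >= end:
        raise ValueError("start must be < end")
    mask = (traj.time >= start) & (traj.time <= end)
    if not mask.any():
        raise ValueError(
            f"empty selection: no frames in [{start}, {end}] ns "
            f"(trajectory spans {traj.time[0]}–{traj.time[-1]} ns)"
        )
    return replace(traj, coords=traj.coords[mask], time=traj.time[mask])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _to_atom_array(top: Topology, coords: np.ndarray):
    import biotite.structure as struc

    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(top.atom_names, dtype="U6")
    arr.element = np.asarray(top.elements, dtype="U2")
    arr.res_id = top.res_number[top.res_index]
    arr.res_name = np.asarray(top.res_name[top.res_index], dtype="U5")
    arr.chain_id = np.asarray(top.res_chain[top.res_index], dtype="U4")
    arr.hetero = np.isin(top.atom_role(), ("ligand", "water", "ion"))
    return arr


def write_topology_pdb(top: Topology, path, coords=None) -> None:
    from biotite.structure.io.pdb import PDBFile

    if coords is None:
        coords = top.reference_coords
    if coords is None:
        raise ValueError("no coordinates available for topology")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(top, coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write frames as a multi-model PDB or a CHARMM/NAMD-style DCD."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arrays = [_to_atom_array(traj.topology, f) for f in traj.coords]
        stack = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif fmt == "dcd":
        import warnings as _warnings

        import MDAnalysis as mda

        u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
        with _warnings.catch_warnings():
            _warnings.filterwarnings(
                "ignore", message="No dimensions set for current frame")
            with mda.coordinates.DCD.DCDWriter(str(path),
                                               traj.topology.n_atoms) as w:
                for frame in traj.coords:
                    u.atoms.positions = frame
                    w.write(u.atoms)
    else:
        raise ValueError(f"unsupported trajectory format '{fmt}'")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(path, topology_path, conditions: dict, dt: float = 1.0) -> None:
    """``conditions`` maps condition -> {replica_id: [file, ...]}."""
    doc = {
        "topology": str(topology_path),
        "dt": float(dt),
        "conditions": {
            c: {r: [str(p) for p in paths] for r, paths in reps.items()}
            for c, reps in conditions.items()
        },
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    for key in ("topology", "conditions"):
        if key not in doc:
            raise ValueError(f"manifest {path} missing '{key}'")
    doc.setdefault("dt", 1.0)
    # resolve paths relative to the manifest location
    base = path.parent
    doc["topology"] = str((base / doc["topology"]))
    doc["conditions"] = {
        c: {r: [str(base / p) for p in paths] for r, paths in reps.items()}
        for c, reps in doc["conditions"].items()
    }
    return doc
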