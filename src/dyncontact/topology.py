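"""Molecular topology container and residue chemistry annotation.

A :class:`Topology` holds the per-atom identity of a system (names, elements,
residue membership, role) together with the chemical annotations that contact
detection needs: hydrogen-bond donors and acceptors, charged groups, and
aromatic rings.  Annotations are derived from per-residue templates keyed by
residue and atom names — the usual convention for the 20 standard amino
acids — plus dynamic rules for synthetic residues and registered ligands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Donor",
    "residue_key_str",
    "annotate_topology",
    "register_ligand_template",
    "ELEMENT_VDW_RADIUS",
    "ELEMENT_LJ",
]

# van der Waals radii (Å), Bondi-style values used for radii-sum contact cutoffs
ELEMENT_VDW_RADIUS = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_VDW = 1.70

# element-level Lennard-Jones defaults (r_min/2 in Å, epsilon in kcal/mol),
# CHARMM-like magnitudes; used when no atom parameter table is supplied
ELEMENT_LJ = {
    "H": (0.2245, 0.046), "C": (2.000, 0.070), "N": (1.850, 0.200),
    "O": (1.700, 0.120), "S": (2.000, 0.450), "P": (2.150, 0.585),
}
_DEFAULT_LJ = (2.000, 0.100)

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP3P", "SPC", "SOL"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "BR", "IOD",
                "SOD", "CLA", "POT", "CAL", "CS", "LI"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HA2", "HA3"}


@dataclass(frozen=True)
class Donor:
    """A hydrogen-bond donor heavy atom with its attached hydrogens.

    ``hydrogens`` may be empty for hydrogen-free (e.g. crystal-structure)
    topologies; detectors then fall back to distance-only criteria.
    """

    atom: int
    hydrogens: tuple[int, ...] = ()


@dataclass
class Topology:
    """Per-atom identity plus the chemical annotations used for contacts.

    Atom order is the frame coordinate order.  ``res_index`` maps each atom
    to a 0-based residue serial; residue identity lives in the parallel
    per-residue arrays ``res_chain``/``res_number``/``res_name``/``res_role``.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray            # (n_atoms,) str, upper-case symbols
    res_index: np.ndarray           # (n_atoms,) int
    res_chain: np.ndarray           # (n_res,) str
    res_number: np.ndarray          # (n_res,) int
    res_name: np.ndarray            # (n_res,) str
    res_role: np.ndarray            # (n_res,) str in {protein, ligand, water, ion}

    donors: list[Donor] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    cationic_groups: list[list[int]] = field(default_factory=list)
    anionic_groups: list[list[int]] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)

    charges: np.ndarray | None = None        # (n_atoms,) e
    lj_rmin_half: np.ndarray | None = None   # (n_atoms,) Å
    lj_eps: np.ndarray | None = None         # (n_atoms,) kcal/mol

    reference_coords: np.ndarray | None = None  # (n_atoms, 3) Å, scaffold/first model

    def __post_init__(self) -> None:
        if len(self.atom_names) != len(self.res_index):
            raise ValueError("atom_names and res_index length mismatch")
        for ring in self.rings:
            if len(ring) < 5:
                raise ValueError("aromatic ring must contain >= 5 atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_name)

    def atom_role(self) -> np.ndarray:
        """Per-atom role, broadcast from residues."""
        return self.res_role[self.res_index]

    def vdw_radii(self) -> np.ndarray:
        return np.array(
            [ELEMENT_VDW_RADIUS.get(e, _DEFAULT_VDW) for e in self.elements]
        )

    def residue_key(self, ri: int) -> str:
        return residue_key_str(
            self.res_chain[ri], int(self.res_number[ri]),
            self.res_name[ri], self.res_role[ri],
        )

    def residue_keys(self) -> list[str]:
        return [self.residue_key(i) for i in range(self.n_residues)]

    def atoms_of_residue(self, ri: int) -> np.ndarray:
        return np.where(self.res_index == ri)[0]

    def heavy_atoms(self) -> np.ndarray:
        return np.where(self.elements != "H")[0]

    def ensure_parameters(self) -> None:
        """Fill missing charges / LJ parameters with element-level defaults."""
        if self.charges is None:
            self.charges = np.zeros(self.n_atoms)
        if self.lj_rmin_half is None or self.lj_eps is None:
            rmin = np.empty(self.n_atoms)
            eps = np.empty(self.n_atoms)
            for i, e in enumerate(self.elements):
                rmin[i], eps[i] = ELEMENT_LJ.get(e, _DEFAULT_LJ)
            self.lj_rmin_half, self.lj_eps = rmin, eps


def residue_key_str(chain: str, number: int, name: str, role: str) -> str:
    """Human-readable residue key; ligands keyed ``LIG:<resname>``."""
    if role == "ligand":
        return f"LIG:{name}"
    return f"{chain}:{name}:{number}"


# ---------------------------------------------------------------------------
# residue templates
# ---------------------------------------------------------------------------
# Side-chain chemistry of the standard amino acids by atom name.  Backbone
# N (donor, H named H/HN) and O (acceptor) are added for every amino acid.
# Format: donors {heavy: [H names]}, acceptors [names], cationic [[group]],
# anionic [[group]], rings [[ordered names]].

_SIDECHAIN = {
    "ARG": dict(
        donors={"NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
        acceptors=[], cationic=[["NE", "NH1", "NH2", "CZ"]], anionic=[], rings=[],
    ),
    "ASN": dict(donors={"ND2": ["HD21", "HD22"]}, acceptors=["OD1"],
                cationic=[], anionic=[], rings=[]),
    "ASP": dict(donors={}, acceptors=["OD1", "OD2"], cationic=[],
                anionic=[["OD1", "OD2", "CG"]], rings=[]),
    "CYS": dict(donors={"SG": ["HG", "HG1"]}, acceptors=[], cationic=[],
                anionic=[], rings=[]),
    "GLN": dict(donors={"NE2": ["HE21", "HE22"]}, acceptors=["OE1"],
                cationic=[], anionic=[], rings=[]),
    "GLU": dict(donors={}, acceptors=["OE1", "OE2"], cationic=[],
                anionic=[["OE1", "OE2", "CD"]], rings=[]),
    "HIS": dict(donors={"ND1": ["HD1"], "NE2": ["HE2"]}, acceptors=["ND1", "NE2"],
                cationic=[], anionic=[],
                rings=[["CG", "ND1", "CE1", "NE2", "CD2"]]),
    "LYS": dict(donors={"NZ": ["HZ1", "HZ2", "HZ3"]}, acceptors=[],
                cationic=[["NZ"]], anionic=[], rings=[]),
    "MET": dict(donors={}, acceptors=["SD"], cationic=[], anionic=[], rings=[]),
    "PHE": dict(donors={}, acceptors=[], cationic=[], anionic=[],
                rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]),
    "SER": dict(donors={"OG": ["HG", "HG1"]}, acceptors=["OG"], cationic=[],
                anionic=[], rings=[]),
    "THR": dict(donors={"OG1": ["HG1"]}, acceptors=["OG1"], cationic=[],
                anionic=[], rings=[]),
    "TRP": dict(donors={"NE1": ["HE1"]}, acceptors=[], cationic=[], anionic=[],
                rings=[["CG", "CD1", "NE1", "CE2", "CD2"],
                       ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"]]),
    "TYR": dict(donors={"OH": ["HH"]}, acceptors=["OH"], cationic=[], anionic=[],
                rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]]),
}

# user-registered ligand templates: resname -> dict like _SIDECHAIN entries
_LIGAND_TEMPLATES: dict[str, dict] = {}


def register_ligand_template(resname: str, *, donors=None, acceptors=None,
                             cationic=None, anionic=None, rings=None) -> None:
    """Declare the contact chemistry of a ligand residue by atom names."""
    _LIGAND_TEMPLATES[resname.upper()] = dict(
        donors=donors or {}, acceptors=acceptors or [],
        cationic=cationic or [], anionic=anionic or [], rings=rings or [],
    )


def _name_index(names: np.ndarray, atom_idx: np.ndarray) -> dict[str, int]:
    return {names[i]: int(i) for i in atom_idx}


def _synthetic_annotations(top: Topology, ri: int, by_name: dict[str, int]):
    """Dynamic template for synthetic residues: probe chemistry is encoded
    in atom names (DNxx donor N with DHxx hydrogen, AOxx acceptor, CNxx
    cationic, XOxx anionic, R<k><A-F> ring carbons)."""
    donors, acceptors, cationic, anionic = [], [], [], []
    rings: dict[str, list[tuple[str, int]]] = {}
    for name, idx in by_name.items():
        if name.startswith("DN"):
            h = by_name.get("DH" + name[2:])
            donors.append(Donor(idx, (h,) if h is not None else ()))
        elif name.startswith("AO") or name.startswith("WO"):
            acceptors.append(idx)
        elif name.startswith("CN"):
            cationic.append([idx])
        elif name.startswith("XO"):
            anionic.append([idx])
        elif name.startswith("R") and len(name) >= 3 and name[-1] in "ABCDEF":
            rings.setdefault(name[:-1], []).append((name, idx))
    ring_lists = [
        [i for _, i in sorted(members)] for _, members in sorted(rings.items())
    ]
    return donors, acceptors, cationic, anionic, ring_lists


def annotate_topology(top: Topology) -> Topology:
    """Derive donor/acceptor/charged/ring annotations from residue templates.

    Standard amino acids use the built-in templates; waters become both
    donors and acceptors (for bridge detection); ligand residues use
    registered templates, falling back to vdW-only annotation with a warning.
    Synthetic residues (resname ``SYN``/``LIG`` probe naming) are decoded
    from their atom-name convention.
    """
    top.donors, top.acceptors = [], []
    top.cationic_groups, top.anionic_groups, top.rings = [], [], []

    for ri in range(top.n_residues):
        idx = top.atoms_of_residue(ri)
        by_name = _name_index(top.atom_names, idx)
        resname = top.res_name[ri].upper()
        role = top.res_role[ri]

        if role == "water":
            ow = next((by_name[n] for n in ("O", "OW", "OH2") if n in by_name), None)
            if ow is not None:
                hyd = tuple(by_name[n] for n in ("H1", "H2", "HW1", "HW2") if n in by_name)
                top.donors.append(Donor(ow, hyd))
                top.acceptors.append(ow)
            continue
        if role == "ion":
            continue

        if resname in STANDARD_AA:
            tmpl = _SIDECHAIN.get(resname, dict(donors={}, acceptors=[],
                                                cationic=[], anionic=[], rings=[]))
            # backbone
            if "N" in by_name and resname != "PRO":
                hyd = tuple(by_name[n] for n in ("H", "HN", "H1", "H2", "H3")
                            if n in by_name)
                top.donors.append(Donor(by_name["N"], hyd))
            if "O" in by_name:
                top.acceptors.append(by_name["O"])
            if "OXT" in by_name:
                top.acceptors.append(by_name["OXT"])
                if "O" in by_name:
                    top.anionic_groups.append([by_name["O"], by_name["OXT"]])
            for heavy, hnames in tmpl["donors"].items():
                if heavy in by_name:
                    hyd = tuple(by_name[h] for h in hnames if h in by_name)
                    top.donors.append(Donor(by_name[heavy], hyd))
            top.acceptors.extend(by_name[a] for a in tmpl["acceptors"] if a in by_name)
            for grp in tmpl["cationic"]:
                members = [by_name[a] for a in grp if a in by_name]
                if members:
                    top.cationic_groups.append(members)
            for grp in tmpl["anionic"]:
                members = [by_name[a] for a in grp if a in by_name]
                if members:
                    top.anionic_groups.append(members)
            for ring in tmpl["rings"]:
                members = [by_name[a] for a in ring if a in by_name]
                if len(members) == len(ring):
                    top.rings.append(members)
            continue

        if resname in _LIGAND_TEMPLATES or role in ("protein", "ligand"):
            tmpl = _LIGAND_TEMPLATES.get(resname)
            if tmpl is not None:
                for heavy, hnames in tmpl["donors"].items():
                    if heavy in by_name:
                        hyd = tuple(by_name[h] for h in hnames if h in by_name)
                        top.donors.append(Donor(by_name[heavy], hyd))
                top.acceptors.extend(by_name[a] for a in tmpl["acceptors"]
                                     if a in by_name)
                for grp in tmpl["cationic"]:
                    members = [by_name[a] for a in grp if a in by_name]
                    if members:
                        top.cationic_groups.append(members)
                for grp in tmpl["anionic"]:
                    members = [by_name[a] for a in grp if a in by_name]
                    if members:
                        top.anionic_groups.append(members)
                for ring in tmpl["rings"]:
                    members = [by_name[a] for a in ring if a in by_name]
                    if len(members) == len(ring):
                        top.rings.append(members)
                continue
            # synthetic probe naming or unknown residue
            d, a, c, an, r = _synthetic_annotations(top, ri, by_name)
            if d or a or c or an or r:
                top.donors.extend(d)
                top.acceptors.extend(a)
                top.cationic_groups.extend(c)
                top.anionic_groups.extend(an)
                top.rings.extend(r)
            else:
                # body atoms N/HN/O of synthetic residues, or template-less input
                if "N" in by_name:
                    hyd = tuple(by_name[n] for n in ("HN", "H") if n in by_name)
                    top.donors.append(Donor(by_name["N"], hyd))
                    if "O" in by_name:
                        top.acceptors.append(by_name["O"])
                elif role == "ligand" and resname not in ("LIG", "SYN"):
                    warnings.warn(
                        f"no template for ligand residue {resname}; "
                        "using vdW-only annotation", stacklevel=2,
                    )
        # synthetic body donors/acceptors even when probes exist
        if resname in ("SYN", "LIG") and "N" in by_name:
            if not any(d.atom == by_name["N"] for d in top.donors):
                hyd = tuple(by_name[n] for n in ("HN", "H") if n in by_name)
                top.donors.append(Donor(by_name["N"], hyd))
            if "O" in by_name and by_name["O"] not in top.acceptors:
                top.acceptors.append(by_name["O"])
    return top


def classify_role(resname: str, ligand_resnames: set[str]) -> str:
    rn = resname.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in ligand_resnames:
        return "ligand"
    return "protein"
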