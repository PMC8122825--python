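"""Structural and energetic trajectory metrics: superposition, RMSF, ligand
RMSD, a nonbonded ligand–receptor interaction-energy surrogate, and
truncation-variant comparison.

The energy model is a plain pairwise nonbonded interaction energy —
Coulomb (332.0636·q_i·q_j/r kcal·Å/mol/e²) plus Lennard-Jones in the
r_min/ε form — under a CHARMM-style switching function on 10–12 Å.  It is a
deliberately simple surrogate for relative, within-pipeline comparisons
(means, percent differences, ΔΔE); its absolute kcal/mol values are not
comparable to published binding free energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .topology import Topology
from .traj_io import Trajectory

__all__ = [
    "RMSFProfile",
    "LigandRMSDSeries",
    "InteractionEnergySeries",
    "TruncationComparison",
    "superpose",
    "rmsf",
    "ligand_rmsd",
    "nonbonded_energy",
    "interaction_energy_series",
    "percent_energy_difference",
    "truncation_compare",
    "COULOMB_CONST",
]

COULOMB_CONST = 332.0636  # kcal·Å/(mol·e²)


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation in Å."""

    values: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["residue", "rmsf"]
        )


@dataclass
class LigandRMSDSeries:
    rmsd: np.ndarray  # per frame, Å
    time: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.rmsd.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time, "rmsd": self.rmsd})


@dataclass
class InteractionEnergySeries:
    energy: np.ndarray  # per frame, kcal/mol
    time: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.energy.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time, "energy": self.energy})


@dataclass
class TruncationComparison:
    """Per-variant mean ligand energies and RMSD, with ΔΔE vs wild type."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _fit_transform(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid-body fit (orthogonal Procrustes / Kabsch) of mobile
    onto reference; returns (rotation matrix, mobile centroid, ref centroid)."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.as_matrix(), cm, cr


def superpose(mobile_frames: np.ndarray, reference: np.ndarray,
              selection: np.ndarray) -> np.ndarray:
    """Least-squares superpose each frame onto the reference using the
    selection atoms; the transform is applied to all atoms."""
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ValueError("need >= 3 selection atoms for superposition")
    mobile_frames = np.asarray(mobile_frames, dtype=float)
    single = mobile_frames.ndim == 2
    frames = mobile_frames[None] if single else mobile_frames
    out = np.empty_like(frames)
    ref_sel = reference[selection]
    for f in range(frames.shape[0]):
        R, cm, cr = _fit_transform(frames[f][selection], ref_sel)
        out[f] = (frames[f] - cm) @ R.T + cr
    return out[0] if single else out


def _selection_indices(top: Topology, selection) -> np.ndarray:
    """Resolve a selection: atom-index array, 'protein'/'ligand' role name,
    or None (all heavy atoms)."""
    if selection is None:
        return top.heavy_atoms()
    if isinstance(selection, str):
        idx = np.where((top.atom_role() == selection)
                       & (top.elements != "H"))[0]
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def rmsf(traj: Trajectory, selection=None, reference: str = "mean",
         superpose_selection=None) -> RMSFProfile:
    """Per-residue RMSF about the time-mean position, after optional
    superposition on a stable selection.

    The per-residue value is the average over the residue's selected
    (heavy) atoms of each atom's RMSF sqrt(⟨|x − ⟨x⟩|²⟩); for isotropic
    Gaussian jitter of per-axis σ this equals σ√3.
    """
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames for RMSF")
    sel = _selection_indices(traj.topology, selection)
    coords = traj.coords
    if superpose_selection is not None:
        sup = _selection_indices(traj.topology, superpose_selection)
        coords = superpose(coords, coords[0], sup)
    if reference == "mean":
        ref = coords.mean(axis=0)
    elif reference == "frame":
        ref = coords[0]
    else:
        raise ValueError("reference must be 'mean' or 'frame'")
    disp2 = ((coords[:, sel, :] - ref[sel]) ** 2).sum(axis=2).mean(axis=0)
    atom_rmsf = np.sqrt(disp2)
    prof: dict[str, list[float]] = {}
    res_of = traj.topology.res_index[sel]
    for a, ri in enumerate(res_of):
        prof.setdefault(traj.topology.residue_key(int(ri)), []).append(
            float(atom_rmsf[a])
        )
    return RMSFProfile({k: float(np.mean(v)) for k, v in prof.items()})


def ligand_rmsd(traj: Trajectory, reference: np.ndarray,
                receptor_selection="protein") -> LigandRMSDSeries:
    """Heavy-atom RMSD of the ligand versus its reference pose, after
    superposing each frame on the receptor selection only (the ligand is
    not re-fit, so drift or site exit shows as large RMSD)."""
    top = traj.topology
    lig = np.where((top.atom_role() == "ligand") & (top.elements != "H"))[0]
    if lig.size == 0:
        raise ValueError("topology contains no ligand residue")
    rec = _selection_indices(top, receptor_selection)
    fitted = superpose(traj.coords, np.asarray(reference, float), rec)
    d = fitted[:, lig, :] - np.asarray(reference, float)[lig]
    rmsd = np.sqrt((d ** 2).sum(axis=2).mean(axis=1))
    return LigandRMSDSeries(rmsd, traj.time.copy())


# ---------------------------------------------------------------------------
# nonbonded energy surrogate
# ---------------------------------------------------------------------------

def _charmm_switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM switching polynomial: 1 below r_on, 0 above r_off, C1-smooth."""
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    sw = ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3
    return np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, sw))


def nonbonded_energy(topology: Topology, frame: np.ndarray,
                     group_a, group_b, cutoff: float = 12.0,
                     switch_on: float = 10.0) -> float:
    """Inter-group Coulomb + Lennard-Jones energy (kcal/mol) for one frame.

    E = Σ_pairs sw(r)·[332.0636 q_i q_j / r + ε_ij((r_min,ij/r)¹² −
    2(r_min,ij/r)⁶)] with r_min,ij = r_min,i/2 + r_min,j/2 and
    ε_ij = √(ε_i ε_j); pairs beyond the cutoff contribute zero.
    """
    ia = _selection_indices(topology, group_a)
    ib = _selection_indices(topology, group_b)
    if topology.charges is None or topology.lj_rmin_half is None:
        missing = [int(i) for i in np.concatenate([ia, ib])][:10]
        raise ValueError(
            f"missing charge/LJ parameters for atoms (first few: {missing}); "
            "call topology.ensure_parameters() or supply a parameter table"
        )
    frame = np.asarray(frame, dtype=float)
    d = frame[ia][:, None, :] - frame[ib][None, :, :]
    r = np.sqrt((d ** 2).sum(axis=2))
    mask = r <= cutoff
    if not mask.any():
        return 0.0
    r = np.where(mask, r, np.inf)
    q = topology.charges
    elec = COULOMB_CONST * q[ia][:, None] * q[ib][None, :] / r
    rmin = topology.lj_rmin_half[ia][:, None] + topology.lj_rmin_half[ib][None, :]
    eps = np.sqrt(topology.lj_eps[ia][:, None] * topology.lj_eps[ib][None, :])
    sr6 = (rmin / r) ** 6
    lj = eps * (sr6 * sr6 - 2.0 * sr6)
    sw = _charmm_switch(np.where(mask, r, cutoff), switch_on, cutoff)
    return float(((elec + lj) * sw * mask).sum())


def interaction_energy_series(traj: Trajectory, group_a="ligand",
                              group_b="protein", cutoff: float = 12.0,
                              switch_on: float = 10.0
                              ) -> InteractionEnergySeries:
    e = np.array([
        nonbonded_energy(traj.topology, traj.coords[f], group_a, group_b,
                         cutoff, switch_on)
        for f in range(traj.n_frames)
    ])
    return InteractionEnergySeries(e, traj.time.copy())


def percent_energy_difference(mean_E_ref: float, mean_E_alt: float) -> float:
    """100·(|E_ref| − |E_alt|)/|E_alt|: how much more stabilising (more
    negative) the reference mean interaction energy is than the alternative."""
    if mean_E_ref == 0 or mean_E_alt == 0:
        raise ValueError("mean energies must be nonzero")
    return 100.0 * (abs(mean_E_ref) - abs(mean_E_alt)) / abs(mean_E_alt)


def truncation_compare(variant_data: dict[str, dict], wt_label: str = "WT"
                       ) -> TruncationComparison:
    """Summarise N-terminal truncation variants.

    ``variant_data`` maps variant label -> dict with any of the keys
    ``cbd_energy``, ``thc_energy``, ``cbd_rmsd``; each value is a flat
    sequence pooling frames/replicas.  Adds a ΔΔE column (variant mean CBD
    energy minus wild type) when the wild-type baseline is present.
    """
    rows = []
    for label, data in variant_data.items():
        rows.append({
            "variant": label,
            "mean_cbd_energy": float(np.mean(data["cbd_energy"]))
            if "cbd_energy" in data else np.nan,
            "mean_thc_energy": float(np.mean(data["thc_energy"]))
            if "thc_energy" in data else np.nan,
            "mean_cbd_rmsd": float(np.mean(data["cbd_rmsd"]))
            if "cbd_rmsd" in data else np.nan,
        })
    df = pd.DataFrame(rows)
    if df["variant"].duplicated().any():
        raise ValueError("variant labels must be unique")
    if wt_label in set(df["variant"]):
        wt_e = float(df.loc[df["variant"] == wt_label, "mean_cbd_energy"].iloc[0])
        df["ddE_vs_wt"] = df["mean_cbd_energy"] - wt_e
    else:
        warnings.warn(f"no {wt_label!r} baseline; ΔΔE column omitted",
                      stacklevel=2)
    return TruncationComparison(df)
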