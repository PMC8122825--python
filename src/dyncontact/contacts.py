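"""Per-frame detection of the interaction classes used in dynamic contact
networks: hydrogen bonds, single-water-mediated hydrogen bonds, salt bridges,
π-stacking, and van der Waals contacts.

Geometric criteria follow the conventions of the GetContacts family of
tools and are fully config-exposed through :class:`ContactCriteria`:

* hydrogen bond — donor–acceptor heavy-atom distance ≤ 3.5 Å and, when the
  donor carries hydrogens, a donor–H–acceptor angle ≥ 110°; hydrogen-free
  topologies degrade to the distance-only criterion,
* salt bridge — any cationic-group nitrogen to anionic-group oxygen ≤ 4.0 Å,
* π-stack — ring-centroid distance ≤ 7.0 Å and inter-normal angle ≤ 30°
  (or ≥ 150°, i.e. anti-parallel),
* van der Waals — heavy-atom distance ≤ r_i + r_j + 0.5 Å, suppressed for
  residue pairs already hydrogen-bonded or salt-bridged in the same frame,
  and excluding intra-residue and sequence-adjacent backbone-only pairs,
* water bridge — one water hydrogen-bonded to polar atoms of two different
  protein/ligand residues in the same frame.

All boundary comparisons are inclusive (≤ / ≥), so ties are deterministic.
Two detection paths exist: a vectorised all-candidate-pairs path and a
grid-accelerated path (k-d tree pruning); both apply identical criteria and
return identical event sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import BACKBONE_NAMES, Topology
from .traj_io import Trajectory

__all__ = [
    "ContactCriteria",
    "ContactEvent",
    "INTERACTION_CLASSES",
    "detect_frame",
    "detect_water_bridges",
    "detect_trajectory",
    "write_events_tsv",
    "read_events_tsv",
]

INTERACTION_CLASSES = ("hbond", "water_bridge", "salt_bridge", "pi_stack", "vdw")


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds; all distances in Å, angles in degrees."""

    hbond_da_max: float = 3.5
    hbond_angle_min: float = 110.0
    sb_max: float = 4.0
    vdw_pad: float = 0.5
    pi_centroid_max: float = 7.0
    pi_normal_angle_max: float = 30.0

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "hbond_angle_min", "sb_max", "vdw_pad",
                     "pi_centroid_max", "pi_normal_angle_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True, order=True)
class ContactEvent:
    frame_index: int
    interaction_class: str
    key: tuple[str, str]  # canonical: key[0] <= key[1]


def _canonical(k1: str, k2: str) -> tuple[str, str]:
    return (k1, k2) if k1 <= k2 else (k2, k1)


# ---------------------------------------------------------------------------
# candidate pair tables (topology-dependent, frame-independent)
# ---------------------------------------------------------------------------

class _PairTables:
    """Candidate atom-pair tables per interaction class for one topology."""

    def __init__(self, top: Topology):
        self.top = top
        role = top.atom_role()
        self.pl_atom = np.isin(role, ("protein", "ligand"))
        res = top.res_index
        keys = top.residue_keys()
        self.res_keys = keys

        # hbond rows: donor heavy, hydrogen (-1 if none), acceptor
        hd, hh, ha = [], [], []
        for don in top.donors:
            if not self.pl_atom[don.atom]:
                continue
            hs = don.hydrogens if don.hydrogens else (-1,)
            for acc in top.acceptors:
                if not self.pl_atom[acc] or res[acc] == res[don.atom]:
                    continue
                for h in hs:
                    hd.append(don.atom)
                    hh.append(h)
                    ha.append(acc)
        self.hb_d = np.array(hd, dtype=int)
        self.hb_h = np.array(hh, dtype=int)
        self.hb_a = np.array(ha, dtype=int)

        # salt bridge rows: cationic N vs anionic O
        si, sj = [], []
        cat_n = [a for grp in top.cationic_groups for a in grp
                 if top.elements[a] == "N"]
        ani_o = [a for grp in top.anionic_groups for a in grp
                 if top.elements[a] == "O"]
        for i in cat_n:
            for j in ani_o:
                if res[i] != res[j]:
                    si.append(i)
                    sj.append(j)
        self.sb_i = np.array(si, dtype=int)
        self.sb_j = np.array(sj, dtype=int)

        # pi rings
        self.rings = [np.asarray(r, dtype=int) for r in top.rings]
        self.ring_res = np.array(
            [res[r[0]] for r in self.rings] or [], dtype=int)
        pi_pairs = [
            (a, b)
            for a in range(len(self.rings))
            for b in range(a + 1, len(self.rings))
            if self.ring_res[a] != self.ring_res[b]
        ]
        self.pi_a = np.array([p[0] for p in pi_pairs], dtype=int)
        self.pi_b = np.array([p[1] for p in pi_pairs], dtype=int)

        # vdw: heavy protein/ligand atoms, inter-residue, minus
        # sequence-adjacent backbone-only pairs
        heavy = np.where((top.elements != "H") & self.pl_atom)[0]
        radii = top.vdw_radii()
        vi, vj = [], []
        backbone = np.isin(top.atom_names.astype(str), list(BACKBONE_NAMES))
        for n, i in enumerate(heavy):
            for j in heavy[n + 1:]:
                ri, rj = res[i], res[j]
                if ri == rj:
                    continue
                if (
                    backbone[i] and backbone[j]
                    and top.res_chain[ri] == top.res_chain[rj]
                    and abs(int(top.res_number[ri]) - int(top.res_number[rj])) == 1
                ):
                    continue
                vi.append(i)
                vj.append(j)
        self.vdw_i = np.array(vi, dtype=int)
        self.vdw_j = np.array(vj, dtype=int)
        self.vdw_cut = (
            radii[self.vdw_i] + radii[self.vdw_j] if len(vi) else np.empty(0)
        )

        # water-bridge rows: water oxygen (its donor entry) vs polar
        # protein/ligand atoms (donors' heavy atoms and acceptors)
        water_donors = [d for d in top.donors
                        if role[d.atom] == "water"]
        polar = sorted(
            {d.atom for d in top.donors if self.pl_atom[d.atom]}
            | {a for a in top.acceptors if self.pl_atom[a]}
        )
        # polar-atom donor hydrogens (for the protein-donates-to-water case)
        don_h = {d.atom: d.hydrogens for d in top.donors}
        # one row per (water, polar atom, polar hydrogen); polar atoms
        # without donor hydrogens get a single row with ph = -1
        acc_set = {a for a in top.acceptors if self.pl_atom[a]}
        wb_w, wb_wh1, wb_wh2, wb_p, wb_ph, wb_acc = [], [], [], [], [], []
        for wd in water_donors:
            h1 = wd.hydrogens[0] if len(wd.hydrogens) > 0 else -1
            h2 = wd.hydrogens[1] if len(wd.hydrogens) > 1 else -1
            for p in polar:
                for ph in don_h.get(p, ()) or (-1,):
                    wb_w.append(wd.atom)
                    wb_wh1.append(h1)
                    wb_wh2.append(h2)
                    wb_p.append(p)
                    wb_ph.append(ph)
                    wb_acc.append(p in acc_set)
        self.wb_w = np.array(wb_w, dtype=int)
        self.wb_wh1 = np.array(wb_wh1, dtype=int)
        self.wb_wh2 = np.array(wb_wh2, dtype=int)
        self.wb_p = np.array(wb_p, dtype=int)
        self.wb_ph = np.array(wb_ph, dtype=int)
        self.wb_acc = np.array(wb_acc, dtype=bool)


_PAIR_CACHE: dict[int, _PairTables] = {}


def _tables(top: Topology) -> _PairTables:
    key = id(top)
    tab = _PAIR_CACHE.get(key)
    if tab is None or tab.top is not top:
        tab = _PairTables(top)
        _PAIR_CACHE.clear()
        _PAIR_CACHE[key] = tab
    return tab


# ---------------------------------------------------------------------------
# vectorised geometry
# ---------------------------------------------------------------------------

def _dist(coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Pairwise distances; coords (F, A, 3) -> (F, n)."""
    d = coords[:, i, :] - coords[:, j, :]
    return np.sqrt(np.einsum("fij,fij->fi", d, d))


def _angle_deg(coords, apex, a, b, mask=None) -> np.ndarray:
    """Angle at `apex` between directions to a and b, degrees; (F, n)."""
    v1 = coords[:, a, :] - coords[:, apex, :]
    v2 = coords[:, b, :] - coords[:, apex, :]
    num = np.einsum("fij,fij->fi", v1, v2)
    den = np.sqrt(
        np.einsum("fij,fij->fi", v1, v1) * np.einsum("fij,fij->fi", v2, v2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.clip(num / np.maximum(den, 1e-300), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def _hbond_row_mask(coords, d_idx, h_idx, a_idx, crit) -> np.ndarray:
    """Boolean (F, n_rows): row satisfies the hydrogen-bond criterion."""
    if len(d_idx) == 0:
        return np.zeros((coords.shape[0], 0), dtype=bool)
    ok = _dist(coords, d_idx, a_idx) <= crit.hbond_da_max
    has_h = h_idx >= 0
    if has_h.any():
        h_safe = np.where(has_h, h_idx, 0)
        ang = _angle_deg(coords, h_safe, d_idx, a_idx)
        ok &= ~has_h[None, :] | (ang >= crit.hbond_angle_min)
    return ok


def _ring_centroids_normals(coords, rings):
    """Centroids and unit normals (Newell's method) for each ring; coords
    (F, A, 3) -> (F, R, 3), (F, R, 3)."""
    F = coords.shape[0]
    R = len(rings)
    cents = np.empty((F, R, 3))
    norms = np.empty((F, R, 3))
    for r, ring in enumerate(rings):
        pts = coords[:, ring, :]  # (F, k, 3)
        c = pts.mean(axis=1)
        cents[:, r] = c
        v = pts - c[:, None, :]
        nrm = np.cross(v, np.roll(v, -1, axis=1)).sum(axis=1)
        nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-300)
        norms[:, r] = nrm
    return cents, norms


# ---------------------------------------------------------------------------
# per-class detection over a frame block
# ---------------------------------------------------------------------------

def _collect(frame_ids, cls, rp1, rp2, rows):
    """Append deduplicated (frame, class, key1, key2) rows."""
    if len(frame_ids) == 0:
        return
    df = pd.DataFrame({"frame": frame_ids, "key1": rp1, "key2": rp2})
    df = df.drop_duplicates()
    df.insert(1, "class", cls)
    rows.append(df)


def _respair_arrays(tab, i_idx, j_idx):
    res = tab.top.res_index
    k = np.array(tab.res_keys, dtype=object)
    a, b = k[res[i_idx]], k[res[j_idx]]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return a2, b2


def _detect_block(top, coords, crit, classes, frame_offset=0, subset=None):
    """Detect events on a coordinate block (F, A, 3).

    ``subset`` optionally restricts candidate rows per class (grid pruning);
    it maps class name -> boolean row mask.
    """
    tab = _tables(top)
    rows: list[pd.DataFrame] = []
    F = coords.shape[0]
    frames = np.arange(F) + frame_offset
    need_vdw_suppress = "vdw" in classes
    hb_sb_pairs = None  # (frame, key1, key2) DataFrame for suppression

    def sel(arr, cls):
        if subset and cls in subset:
            return arr[subset[cls]]
        return arr

    # --- hydrogen bonds (also needed for vdw suppression) ---
    hb_df = None
    if "hbond" in classes or need_vdw_suppress:
        d_i = sel(tab.hb_d, "hbond")
        h_i = sel(tab.hb_h, "hbond")
        a_i = sel(tab.hb_a, "hbond")
        if len(tab.hb_d) == 0 and "hbond" in classes:
            warnings.warn("hbond requested but topology has no donor/acceptor "
                          "annotations", stacklevel=2)
        ok = _hbond_row_mask(coords, d_i, h_i, a_i, crit)
        f, r = np.where(ok)
        k1, k2 = _respair_arrays(tab, d_i[r], a_i[r])
        hb_df = pd.DataFrame(
            {"frame": frames[f], "key1": k1, "key2": k2}).drop_duplicates()
        if "hbond" in classes:
            out = hb_df.copy()
            out.insert(1, "class", "hbond")
            rows.append(out)

    # --- salt bridges ---
    sb_df = None
    if "salt_bridge" in classes or need_vdw_suppress:
        i_i = sel(tab.sb_i, "salt_bridge")
        j_i = sel(tab.sb_j, "salt_bridge")
        if len(tab.sb_i) == 0 and "salt_bridge" in classes:
            if not top.cationic_groups or not top.anionic_groups:
                warnings.warn("salt_bridge requested but charged-group "
                              "annotations are absent", stacklevel=2)
        ok = _dist(coords, i_i, j_i) <= crit.sb_max if len(i_i) else \
            np.zeros((F, 0), dtype=bool)
        f, r = np.where(ok)
        k1, k2 = _respair_arrays(tab, i_i[r], j_i[r])
        sb_df = pd.DataFrame(
            {"frame": frames[f], "key1": k1, "key2": k2}).drop_duplicates()
        if "salt_bridge" in classes:
            out = sb_df.copy()
            out.insert(1, "class", "salt_bridge")
            rows.append(out)

    # --- pi stacking ---
    if "pi_stack" in classes:
        if len(tab.pi_a) == 0:
            if len(tab.rings) < 2:
                warnings.warn("pi_stack requested but topology has fewer than "
                              "two aromatic rings", stacklevel=2)
        else:
            a_i = sel(tab.pi_a, "pi_stack")
            b_i = sel(tab.pi_b, "pi_stack")
            cents, norms = _ring_centroids_normals(coords, tab.rings)
            dvec = cents[:, a_i, :] - cents[:, b_i, :]
            dist = np.sqrt(np.einsum("fij,fij->fi", dvec, dvec))
            cosang = np.abs(
                np.einsum("fij,fij->fi", norms[:, a_i, :], norms[:, b_i, :])
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = (dist <= crit.pi_centroid_max) & (ang <= crit.pi_normal_angle_max)
            f, r = np.where(ok)
            ring_atom_a = np.array([tab.rings[x][0] for x in a_i], dtype=int)
            ring_atom_b = np.array([tab.rings[x][0] for x in b_i], dtype=int)
            k1, k2 = _respair_arrays(tab, ring_atom_a[r], ring_atom_b[r])
            _collect(frames[f], "pi_stack", k1, k2, rows)

    # --- van der Waals ---
    if "vdw" in classes:
        i_i = sel(tab.vdw_i, "vdw")
        j_i = sel(tab.vdw_j, "vdw")
        cut = sel(tab.vdw_cut, "vdw")
        if len(i_i):
            ok = _dist(coords, i_i, j_i) <= cut[None, :] + crit.vdw_pad
            f, r = np.where(ok)
            k1, k2 = _respair_arrays(tab, i_i[r], j_i[r])
            vdw_df = pd.DataFrame(
                {"frame": frames[f], "key1": k1, "key2": k2}).drop_duplicates()
            suppress = pd.concat(
                [d for d in (hb_df, sb_df) if d is not None],
                ignore_index=True) if (hb_df is not None or sb_df is not None) \
                else None
            if suppress is not None and len(suppress):
                merged = vdw_df.merge(
                    suppress.drop_duplicates(), how="left", indicator=True,
                    on=["frame", "key1", "key2"])
                vdw_df = merged[merged["_merge"] == "left_only"].drop(
                    columns="_merge")
            vdw_df.insert(1, "class", "vdw")
            rows.append(vdw_df)

    # --- water bridges ---
    if "water_bridge" in classes:
        wb = _water_bridge_block(top, coords, crit, frames, tab)
        if wb is not None:
            rows.append(wb)

    if not rows:
        return pd.DataFrame(columns=["frame", "class", "key1", "key2"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["frame", "class", "key1", "key2"],
                           ignore_index=True)


def _water_bridge_block(top, coords, crit, frames, tab):
    """Single-water bridges: water W hydrogen-bonded to polar atoms of two
    different protein/ligand residues in the same frame."""
    if len(tab.wb_w) == 0:
        return None
    F = coords.shape[0]
    d_ok = _dist(coords, tab.wb_w, tab.wb_p) <= crit.hbond_da_max
    # water donates: angle at either water hydrogen, polar atom must accept
    ang_ok = np.zeros_like(d_ok)
    for h in (tab.wb_wh1, tab.wb_wh2):
        has = (h >= 0) & tab.wb_acc
        if has.any():
            hs = np.where(has, h, 0)
            ang = _angle_deg(coords, hs, tab.wb_w, tab.wb_p)
            ang_ok |= has[None, :] & (ang >= crit.hbond_angle_min)
    # polar atom donates to water oxygen
    hasp = tab.wb_ph >= 0
    if hasp.any():
        hp = np.where(hasp, tab.wb_ph, 0)
        ang = _angle_deg(coords, hp, tab.wb_p, tab.wb_w)
        ang_ok |= hasp[None, :] & (ang >= crit.hbond_angle_min)
    # hydrogen-free fallback: no hydrogens on either side -> distance only
    no_h = (tab.wb_wh1 < 0) & (~hasp)
    ang_ok |= no_h[None, :]
    hb = d_ok & ang_ok
    if not hb.any():
        return None
    res = top.res_index
    keys = np.array(tab.res_keys, dtype=object)
    recs = []
    for fi in range(F):
        rrows = np.where(hb[fi])[0]
        if len(rrows) == 0:
            continue
        by_water: dict[int, set[int]] = {}
        for r in rrows:
            by_water.setdefault(tab.wb_w[r], set()).add(res[tab.wb_p[r]])
        seen = set()
        for members in by_water.values():
            mem = sorted(members)
            for x in range(len(mem)):
                for y in range(x + 1, len(mem)):
                    k1, k2 = keys[mem[x]], keys[mem[y]]
                    if k1 > k2:
                        k1, k2 = k2, k1
                    seen.add((k1, k2))
        for k1, k2 in sorted(seen):
            recs.append((frames[fi], "water_bridge", k1, k2))
    if not recs:
        return None
    return pd.DataFrame(recs, columns=["frame", "class", "key1", "key2"])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _grid_subsets(top, coords_1frame, crit, classes):
    """Prune candidate rows with a k-d tree; criteria applied afterwards are
    identical to the brute-force path, so results match exactly."""
    tab = _tables(top)
    tree = cKDTree(coords_1frame)
    subsets = {}

    def prune(i_idx, j_idx, radius):
        if len(i_idx) == 0:
            return np.zeros(0, dtype=bool)
        pairs = tree.query_pairs(radius * 1.0000001, output_type="set")
        mask = np.fromiter(
            ((int(a), int(b)) in pairs or (int(b), int(a)) in pairs
             or a == b for a, b in zip(i_idx, j_idx)),
            dtype=bool, count=len(i_idx),
        )
        return mask

    if "hbond" in classes:
        subsets["hbond"] = prune(tab.hb_d, tab.hb_a, crit.hbond_da_max)
    if "salt_bridge" in classes:
        subsets["salt_bridge"] = prune(tab.sb_i, tab.sb_j, crit.sb_max)
    if "vdw" in classes and len(tab.vdw_i):
        rmax = 2 * top.vdw_radii().max() + crit.vdw_pad
        subsets["vdw"] = prune(tab.vdw_i, tab.vdw_j, rmax)
        # suppression needs full hbond/salt-bridge sets
        subsets.setdefault("hbond", prune(tab.hb_d, tab.hb_a, crit.hbond_da_max))
        subsets.setdefault(
            "salt_bridge", prune(tab.sb_i, tab.sb_j, crit.sb_max))
    return subsets


def detect_frame(topology: Topology, coords: np.ndarray,
                 criteria: ContactCriteria | None = None,
                 classes=None, frame_index: int = 0,
                 method: str = "brute") -> set[ContactEvent]:
    """Detect contacts in a single frame; returns a set of ContactEvents.

    ``method`` selects the candidate-generation path: ``"brute"`` evaluates
    every candidate pair; ``"grid"`` prunes with a k-d tree first.  Both
    apply identical criteria.
    """
    criteria = criteria or ContactCriteria()
    classes = set(classes) if classes is not None else set(INTERACTION_CLASSES)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinates do not match topology atom count")
    subset = None
    if method == "grid":
        subset = _grid_subsets(topology, coords, criteria, classes)
    elif method != "brute":
        raise ValueError(f"unknown method '{method}'")
    df = _detect_block(topology, coords[None], criteria, classes,
                       frame_offset=frame_index, subset=subset)
    return {
        ContactEvent(int(f), c, (k1, k2))
        for f, c, k1, k2 in zip(df["frame"], df["class"],
                                df["key1"], df["key2"])
    }


def detect_water_bridges(topology: Topology, coords: np.ndarray,
                         criteria: ContactCriteria | None = None,
                         frame_index: int = 0) -> set[ContactEvent]:
    """Water-mediated hydrogen bonds in one frame (empty if no waters)."""
    return detect_frame(topology, coords, criteria, {"water_bridge"},
                        frame_index=frame_index)


def detect_trajectory(traj: Trajectory,
                      criteria: ContactCriteria | None = None,
                      classes=None, method: str = "auto",
                      chunk: int = 200) -> pd.DataFrame:
    """Detect contacts on every frame; returns a table (frame, class,
    key1, key2) — one row per (class, residue pair) per frame at most."""
    criteria = criteria or ContactCriteria()
    classes = set(classes) if classes is not None else set(INTERACTION_CLASSES)
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if not classes:
        return pd.DataFrame(columns=["frame", "class", "key1", "key2"])
    if method == "auto":
        method = "brute" if traj.topology.n_atoms <= 600 else "grid"
    if method == "brute":
        blocks = []
        for start in range(0, traj.n_frames, chunk):
            co = traj.coords[start:start + chunk]
            blocks.append(
                _detect_block(traj.topology, co, criteria, classes,
                              frame_offset=start)
            )
        return pd.concat(blocks, ignore_index=True)
    if method == "grid":
        blocks = []
        for fi in range(traj.n_frames):
            subset = _grid_subsets(traj.topology, traj.coords[fi],
                                   criteria, classes)
            blocks.append(
                _detect_block(traj.topology, traj.coords[fi][None], criteria,
                              classes, frame_offset=fi, subset=subset)
            )
        return pd.concat(blocks, ignore_index=True)
    raise ValueError(f"unknown method '{method}'")


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """GetContacts-style per-frame table: frame, class, key1, key2."""
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
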