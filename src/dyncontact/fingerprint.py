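"""Interaction-frequency fingerprints from per-frame contact event tables.

The interaction frequency of a contact is the fraction of analysed frames
in which it is present: 1.0 means present in every frame, 0.5 in half of
them, 0 means it never occurs.  Multiple events of one key within a frame
count once — frequency is a per-frame indicator average.  A contact enters
downstream analysis only if its frequency reaches the fingerprint cutoff
(0.5 for residue–residue, 0.3 for ligand–protein) in at least one replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "RESIDUE_CUTOFF",
    "LIGAND_CUTOFF",
    "compute_frequencies",
    "apply_fingerprint_cutoff",
    "ligand_fingerprint_table",
    "fingerprints_to_frame",
    "write_fingerprints_tsv",
    "fingerprint_matrix",
]

RESIDUE_CUTOFF = 0.5
LIGAND_CUTOFF = 0.3


@dataclass
class Fingerprint:
    """Per-replica mapping (class, key1, key2) -> frequency in [0, 1]."""

    condition: str
    replica_id: str
    n_frames_analysed: int
    freq: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def get(self, cls: str, key1: str, key2: str) -> float:
        k1, k2 = (key1, key2) if key1 <= key2 else (key2, key1)
        return self.freq.get((cls, k1, k2), 0.0)


def compute_frequencies(events: pd.DataFrame, n_frames_analysed: int,
                        condition: str = "", replica_id: str = "") -> Fingerprint:
    """Frequency = distinct frames containing the (class, key) event divided
    by the number of analysed frames."""
    if n_frames_analysed < 1:
        raise ValueError("n_frames_analysed must be >= 1")
    fp = Fingerprint(condition, replica_id, n_frames_analysed)
    if len(events) == 0:
        return fp
    if events["frame"].min() < 0 or events["frame"].max() >= n_frames_analysed:
        raise ValueError(
            "event table references frames outside the analysed range "
            f"[0, {n_frames_analysed - 1}]"
        )
    counts = (
        events.drop_duplicates(["frame", "class", "key1", "key2"])
        .groupby(["class", "key1", "key2"], sort=True)
        .size()
    )
    for (cls, k1, k2), n in counts.items():
        fp.freq[(cls, k1, k2)] = n / n_frames_analysed
    return fp


def _is_ligand_key(key: tuple[str, str, str]) -> bool:
    return key[1].startswith("LIG:") or key[2].startswith("LIG:")


def apply_fingerprint_cutoff(fps: list[Fingerprint],
                             mode: str = "residue_residue",
                             cutoff: float | None = None) -> set:
    """Keys retained iff their max frequency over replicas reaches the
    cutoff (a contact counts if frequent enough in at least one trajectory).

    ``mode`` selects which keys are screened and the default cutoff:
    residue–residue pairs at 0.5, ligand–protein contacts at 0.3.
    """
    if not fps:
        raise ValueError("no fingerprints given")
    if mode not in ("residue_residue", "ligand_protein"):
        raise ValueError(f"unknown mode {mode!r}")
    if cutoff is None:
        cutoff = RESIDUE_CUTOFF if mode == "residue_residue" else LIGAND_CUTOFF
    want_ligand = mode == "ligand_protein"
    best: dict[tuple, float] = {}
    for fp in fps:
        for key, f in fp.freq.items():
            if _is_ligand_key(key) != want_ligand:
                continue
            if f > best.get(key, 0.0):
                best[key] = f
    return {key for key, f in best.items() if f >= cutoff}


def pooled_ligand_frequencies(events: pd.DataFrame, n_frames_analysed: int,
                              condition: str = "",
                              replica_id: str = "") -> Fingerprint:
    """Ligand–residue frequencies pooled over interaction classes: the
    fraction of frames in which the ligand touches the residue through any
    class.  Pooling is done at the event level (union of frames), so values
    stay in [0, 1]."""
    fp = Fingerprint(condition, replica_id, n_frames_analysed)
    if len(events) == 0:
        return fp
    lig = events[
        events["key1"].str.startswith("LIG:")
        | events["key2"].str.startswith("LIG:")
    ]
    if len(lig) == 0:
        return fp
    counts = (
        lig.drop_duplicates(["frame", "key1", "key2"])
        .groupby(["key1", "key2"], sort=True)
        .size()
    )
    for (k1, k2), n in counts.items():
        fp.freq[("any", k1, k2)] = n / n_frames_analysed
    return fp


def ligand_fingerprint_table(fps_by_condition: dict[str, list[Fingerprint]]
                             ) -> pd.DataFrame:
    """Mean ligand-contact frequency per residue and condition (the
    residue-level averages shown in ligand fingerprint plots).

    Input fingerprints should be class-pooled (see
    :func:`pooled_ligand_frequencies`); class-resolved fingerprints are
    pooled by their per-class maximum.
    """
    rows = []
    for cond, fps in fps_by_condition.items():
        if not fps:
            raise ValueError(f"condition {cond!r} has no replicas")
        per_rep = []
        for fp in fps:
            pooled: dict[str, float] = {}
            for (cls, k1, k2), f in fp.freq.items():
                resid = k2 if k1.startswith("LIG:") else k1
                if not (k1.startswith("LIG:") or k2.startswith("LIG:")):
                    continue
                pooled[resid] = max(pooled.get(resid, 0.0), f)
            per_rep.append(pooled)
        residues = sorted({r for p in per_rep for r in p})
        for resid in residues:
            rows.append({
                "condition": cond,
                "residue": resid,
                "mean_freq": float(np.mean([p.get(resid, 0.0) for p in per_rep])),
            })
    df = pd.DataFrame(rows, columns=["condition", "residue", "mean_freq"])

    def resnum(key: str) -> int:
        try:
            return int(key.rsplit(":", 1)[1])
        except (ValueError, IndexError):
            return -1

    df["_n"] = df["residue"].map(resnum)
    df = df.sort_values(["condition", "_n", "residue"]).drop(columns="_n")
    return df.reset_index(drop=True)


def fingerprints_to_frame(fps: list[Fingerprint]) -> pd.DataFrame:
    """Long-format table: condition, replica, class, key1, key2, freq."""
    rows = [
        (fp.condition, fp.replica_id, cls, k1, k2, f)
        for fp in fps
        for (cls, k1, k2), f in sorted(fp.freq.items())
    ]
    return pd.DataFrame(
        rows, columns=["condition", "replica", "class", "key1", "key2", "freq"]
    )


def write_fingerprints_tsv(fps: list[Fingerprint], path) -> None:
    fingerprints_to_frame(fps).to_csv(path, sep="\t", index=False,
                                      float_format="%.6f")


def fingerprint_matrix(fps: list[Fingerprint]) -> pd.DataFrame:
    """Wide-format keys × replicas matrix for heatmap-style plots."""
    df = fingerprints_to_frame(fps)
    if len(df) == 0:
        return df
    df["key"] = df["class"] + "|" + df["key1"] + "|" + df["key2"]
    df["rep"] = df["condition"] + "/" + df["replica"]
    return df.pivot_table(index="key", columns="rep", values="freq",
                          fill_value=0.0)
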