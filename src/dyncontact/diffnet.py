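"""Differential contact network between two trajectory ensembles.

For every contact key the per-replica frequencies of condition A and B are
compared by

    Δ_freq = mean(Freq_A) − mean(Freq_B)

with a two-sample Student's t-test (pooled variance by default, Welch by
flag) on the per-replica frequencies.  A contact enters the differential
("allosteric") network when p < 0.05 and |Δ_freq| > 0.4 — the effect-size
gate stands in for multiple-testing correction, which is deliberately not
applied.  Contacts with positive Δ are condition-A-enriched (drawn red in
flare plots), negative Δ condition-B-enriched (blue).

A *molecular switch* is a residue shared by two hydrogen bonds whose
frequencies shift in opposite directions between conditions — e.g. one
partner bond formed in the modulator-bound ensemble, the alternative bond
formed without it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprint import Fingerprint

__all__ = [
    "DifferentialRecord",
    "AllostericNetwork",
    "delta_freq",
    "differential_test",
    "differential_records",
    "filter_network",
    "detect_switches",
    "export_flare",
    "export_table",
    "read_table",
]

P_MAX_DEFAULT = 0.05
DELTA_MIN_DEFAULT = 0.4


@dataclass(frozen=True)
class DifferentialRecord:
    interaction_class: str
    key: tuple[str, str]
    mean_freq_A: float
    mean_freq_B: float
    delta_freq: float
    t_stat: float
    p_value: float
    passes: bool = False


@dataclass
class AllostericNetwork:
    """Only records passing the significance/effect-size filter."""

    records: list[DifferentialRecord] = field(default_factory=list)
    condition_A: str = "A"
    condition_B: str = "B"

    def __post_init__(self) -> None:
        if any(not r.passes for r in self.records):
            raise ValueError("AllostericNetwork must contain passing records only")

    def signs(self) -> dict[tuple, str]:
        return {
            (r.interaction_class, r.key):
                "A_enriched" if r.delta_freq > 0 else "B_enriched"
            for r in self.records
        }


def delta_freq(freqs_A, freqs_B) -> tuple[float, float, float]:
    """(mean_A, mean_B, Δ) with Δ = mean_A − mean_B; argument order is
    condition A (e.g. modulator-bound) minus condition B."""
    freqs_A, freqs_B = np.asarray(freqs_A, float), np.asarray(freqs_B, float)
    if freqs_A.size == 0 or freqs_B.size == 0:
        raise ValueError("frequency lists must be non-empty")
    ma, mb = float(freqs_A.mean()), float(freqs_B.mean())
    return ma, mb, ma - mb


def differential_test(freqs_A, freqs_B, welch: bool = False
                      ) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-replica frequencies.

    Degenerate conventions: both samples constant and equal → (0, 1);
    constant but different → (±inf, 0) with a warning, since the difference
    is then deterministic at the resolution of the data.
    """
    a, b = np.asarray(freqs_A, float), np.asarray(freqs_B, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicas per condition for the t-test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "both samples constant but different; p set to 0 by convention",
            stacklevel=2,
        )
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def differential_records(fps_A: list[Fingerprint], fps_B: list[Fingerprint],
                         keys=None, p_max: float = P_MAX_DEFAULT,
                         delta_min: float = DELTA_MIN_DEFAULT,
                         welch: bool = False) -> list[DifferentialRecord]:
    """Per-contact Δ_freq, t statistic and p-value over two replica sets.

    ``keys`` restricts analysis to fingerprint-retained (class, key1, key2)
    tuples; by default every key observed in either condition is tested.
    A key absent from a replica has frequency 0 there.
    """
    if keys is None:
        keys = {k for fp in fps_A + fps_B for k in fp.freq}
    records = []
    for cls, k1, k2 in sorted(keys):
        fa = [fp.get(cls, k1, k2) for fp in fps_A]
        fb = [fp.get(cls, k1, k2) for fp in fps_B]
        ma, mb, d = delta_freq(fa, fb)
        t, p = differential_test(fa, fb, welch=welch)
        records.append(DifferentialRecord(
            cls, (k1, k2), ma, mb, d, t, p,
            passes=(p < p_max and abs(d) > delta_min),
        ))
    return records


def filter_network(records: list[DifferentialRecord],
                   p_max: float = P_MAX_DEFAULT,
                   delta_min: float = DELTA_MIN_DEFAULT,
                   fingerprint_keys=None,
                   condition_A: str = "A",
                   condition_B: str = "B") -> AllostericNetwork:
    """Keep records with p < p_max and |Δ_freq| > delta_min (strict
    inequalities), optionally restricted to fingerprint-retained keys."""
    kept = []
    for r in records:
        if fingerprint_keys is not None and \
                (r.interaction_class, *r.key) not in fingerprint_keys:
            continue
        if r.p_value < p_max and abs(r.delta_freq) > delta_min:
            kept.append(DifferentialRecord(
                r.interaction_class, r.key, r.mean_freq_A, r.mean_freq_B,
                r.delta_freq, r.t_stat, r.p_value, passes=True,
            ))
    return AllostericNetwork(kept, condition_A, condition_B)


def detect_switches(network: AllostericNetwork) -> list[tuple[str, str, str]]:
    """Residue triples (X, Z, Y): two passing hydrogen bonds X–Z and Y–Z
    share endpoint Z with opposite-signed Δ_freq — the signature of a
    contact switch rewired by the allosteric ligand.  Ranked by the smaller
    |Δ| of the pair, largest first."""
    hb = [r for r in network.records if r.interaction_class == "hbond"]
    triples = []
    for i in range(len(hb)):
        for j in range(i + 1, len(hb)):
            ri, rj = hb[i], hb[j]
            if ri.delta_freq * rj.delta_freq >= 0:
                continue
            shared = set(ri.key) & set(rj.key)
            if len(shared) != 1:
                continue
            z = shared.pop()
            x = next(k for k in ri.key if k != z)
            y = next(k for k in rj.key if k != z)
            if ri.delta_freq < 0:  # list the A-enriched partner first
                x, y = y, x
            triples.append(
                ((x, z, y), min(abs(ri.delta_freq), abs(rj.delta_freq)))
            )
    triples.sort(key=lambda t: -t[1])
    return [t[0] for t in triples]


def export_flare(network: AllostericNetwork, path=None) -> dict:
    """Flare-plot JSON: edges weighted by |Δ_freq|, colored red for
    condition-A-enriched contacts and blue for condition-B-enriched."""
    edges = []
    for r in sorted(network.records,
                    key=lambda r: (r.interaction_class, r.key)):
        a_enriched = r.delta_freq > 0
        edges.append({
            "name1": r.key[0],
            "name2": r.key[1],
            "frames": [0],
            "weight": abs(r.delta_freq),
            "class": r.interaction_class,
            "category": "A_enriched" if a_enriched else "B_enriched",
            "color": "red" if a_enriched else "blue",
        })
    doc = {
        "edges": edges,
        "conditions": {"A": network.condition_A, "B": network.condition_B},
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return doc


_TABLE_COLS = ["class", "key1", "key2", "mean_A", "mean_B", "delta", "t", "p"]


def export_table(records, path=None) -> pd.DataFrame:
    """TSV of differential records (passing or all, as given)."""
    if isinstance(records, AllostericNetwork):
        records = records.records
    df = pd.DataFrame(
        [
            (r.interaction_class, r.key[0], r.key[1], r.mean_freq_A,
             r.mean_freq_B, r.delta_freq, r.t_stat, r.p_value)
            for r in records
        ],
        columns=_TABLE_COLS,
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def read_table(path, p_max: float = P_MAX_DEFAULT,
               delta_min: float = DELTA_MIN_DEFAULT) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialRecord(
            row["class"], (row["key1"], row["key2"]), row["mean_A"],
            row["mean_B"], row["delta"], row["t"], row["p"],
            passes=(row["p"] < p_max and abs(row["delta"]) > delta_min),
        )
        for _, row in df.iterrows()
    ]
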