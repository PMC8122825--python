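"""Ballesteros–Weinstein (BW) numbering for GPCR transmembrane helices.

The BW scheme labels residue *r* of helix *h* as ``h.pos`` where the most
conserved residue of the helix is assigned position 50, so
``pos = 50 + r - anchor_h``.  Anchors (and the helix spans they label) are
receptor-specific and supplied by the user as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .topology import Topology

__all__ = ["BWMap", "annotate_bw", "read_bw_config"]


@dataclass
class BWMap:
    """Per-helix x.50 anchors plus the residue spans each helix covers.

    ``anchors`` maps helix index (1–7, plus 8 for helix 8 if desired) to the
    residue number assigned position 50.  ``spans`` maps helix index to an
    inclusive (first, last) residue-number range; residues outside all spans
    stay unlabeled.  A missing span defaults to anchor ± 25 residues.
    """

    anchors: dict[int, int]
    spans: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.anchors:
            if not 1 <= h <= 8:
                raise ValueError(f"helix index {h} outside 1..8")

    def span(self, helix: int) -> tuple[int, int]:
        if helix in self.spans:
            return self.spans[helix]
        a = self.anchors[helix]
        return (a - 25, a + 25)

    def label(self, resnum: int) -> str | None:
        for h, anchor in self.anchors.items():
            lo, hi = self.span(h)
            if lo <= resnum <= hi:
                return f"{h}.{50 + resnum - anchor}"
        return None


def annotate_bw(topology: Topology, bwmap: BWMap) -> dict[str, str]:
    """Map residue key -> BW label for protein residues inside helix spans."""
    out: dict[str, str] = {}
    for ri in range(topology.n_residues):
        if topology.res_role[ri] != "protein":
            continue
        label = bwmap.label(int(topology.res_number[ri]))
        if label is not None:
            out[topology.residue_key(ri)] = label
    return out


def read_bw_config(path) -> BWMap:
    """Read a whitespace-delimited config: ``helix anchor [start end]``."""
    anchors: dict[int, int] = {}
    spans: dict[int, tuple[int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 4):
            raise ValueError(f"{path}:{lineno}: expected 'helix anchor [start end]'")
        h = int(parts[0])
        anchors[h] = int(parts[1])
        if len(parts) == 4:
            spans[h] = (int(parts[2]), int(parts[3]))
    return BWMap(anchors, spans)
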