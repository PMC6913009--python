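"""Tiling sgRNA enumeration over a CDS.

Every 23-nt window on either strand whose final three bases match an allowed
PAM (NGG or NAG by default) yields one 20-nt spacer.  The Cas9 blunt cut falls
between spacer positions 17 and 18 (3 bp 5' of the PAM); ``cut_site`` records
the 0-based CDS coordinate of the first base 3' of the cut on the plus strand,
so that a minus-strand guide's cut site mirrors cleanly (cut' = L - cut).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .reference import CdsReference, reverse_complement

__all__ = ["SgrnaRecord", "design_tiling_sgrnas", "write_library", "read_library"]

logger = logging.getLogger(__name__)

SPACER_LEN = 20
_WINDOW = 23  # spacer + PAM


@dataclass(frozen=True)
class SgrnaRecord:
    """One tiling-library guide: spacer + PAM at a specific CDS position."""

    spacer: str
    pam: str
    strand: str  # "+" or "-" relative to the CDS
    cut_site: int  # 0-based CDS coordinate, first base 3' of the blunt cut
    duplicate: bool = False  # spacer occurs at more than one position

    def residue(self, ref: CdsReference) -> int:
        """1-based residue containing the cut site (clamped at the CDS end)."""
        pos = min(self.cut_site, len(ref.sequence) - 1)
        return pos // 3 + 1


def _pam_tails(pams: tuple[str, ...]) -> set[str]:
    tails = set()
    for pam in pams:
        pam = pam.upper()
        if len(pam) != 3 or pam[0] != "N" or pam[1:] not in {"GG", "AG"}:
            raise ValueError(f"unsupported PAM pattern {pam!r} (expected NGG/NAG)")
        tails.add(pam[1:])
    return tails


def design_tiling_sgrnas(
    ref: CdsReference, pams: tuple[str, ...] = ("NGG", "NAG")
) -> list[SgrnaRecord]:
    """Enumerate all spacers with an allowed PAM on either strand of the CDS.

    Guides are restricted to windows fully inside the CDS; duplicated spacers
    are retained at every position but flagged.
    """
    tails = _pam_tails(pams)
    seq = ref.sequence
    L = len(seq)
    if L < _WINDOW:
        logger.warning("%s: CDS shorter than %d nt, no sgRNAs designed", ref.gene_id, _WINDOW)
        return []

    records: list[SgrnaRecord] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for pos in range(L - _WINDOW + 1):
            pam = s[pos + SPACER_LEN : pos + _WINDOW]
            if pam[1:] in tails:
                cut = pos + 17 if strand == "+" else L - (pos + 17)
                records.append(
                    SgrnaRecord(spacer=s[pos : pos + SPACER_LEN], pam=pam, strand=strand, cut_site=cut)
                )

    counts = Counter(r.spacer for r in records)
    records = [
        replace(r, duplicate=True) if counts[r.spacer] > 1 else r for r in records
    ]
    records.sort(key=lambda r: (r.cut_site, r.strand, r.spacer))
    return records


def write_library(records: list[SgrnaRecord], ref: CdsReference, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": ref.gene_id,
            "spacer": [r.spacer for r in records],
            "pam": [r.pam for r in records],
            "strand": [r.strand for r in records],
            "cut_site_0based": [r.cut_site for r in records],
            "residue_1based": [r.residue(ref) for r in records],
            "duplicate": [int(r.duplicate) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> list[SgrnaRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"spacer": str, "pam": str, "strand": str})
    return [
        SgrnaRecord(
            spacer=row.spacer,
            pam=row.pam,
            strand=row.strand,
            cut_site=int(row.cut_site_0based),
            duplicate=bool(getattr(row, "duplicate", 0)),
        )
        for row in df.itertuples()
    ]
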