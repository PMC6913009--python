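"""sgRNA barcode counting and per-guide enrichment.

Spacers are matched exactly (20-mer) at a located position in each barcode
read — either a fixed offset or relative to a flanking anchor sequence (the
anchor mode absorbs staggered-primer designs that shift the spacer by a
variable number of bases).  Fold changes use a +1 pseudocount on normalized
counts:  log2fc = log2((c_after+1)/N_after) - log2((c_before+1)/N_before).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import SPACER_LEN, SgrnaRecord
from .reference import CdsReference

__all__ = [
    "count_spacers",
    "count_table",
    "sgrna_profile",
    "replicate_correlation",
]

logger = logging.getLogger(__name__)


def _unique_spacers(library: Sequence[SgrnaRecord]) -> list[str]:
    seen: dict[str, None] = {}
    dup = 0
    for rec in library:
        if rec.spacer in seen:
            dup += 1
        seen[rec.spacer] = None
    if dup:
        logger.warning("%d duplicate spacers collapsed for counting", dup)
    return list(seen)


def count_spacers(
    fastq: str | Path | Iterable[str],
    library: Sequence[SgrnaRecord],
    locate: str = "fixed_offset",
    offset: int = 0,
    anchor: str | None = None,
) -> tuple[pd.Series, int]:
    """Exact spacer counts from barcode reads.

    ``fastq`` may be a FASTQ path or an iterable of read sequences.  Returns
    (counts indexed by spacer, number of unassigned reads).  In
    ``flank_anchor`` mode the spacer is taken immediately after the single
    occurrence of ``anchor``; reads where the anchor is absent or ambiguous
    are unassigned.
    """
    spacers = _unique_spacers(library)
    lookup = {s: i for i, s in enumerate(spacers)}
    counts = np.zeros(len(spacers), dtype=np.int64)
    unassigned = 0
    if isinstance(fastq, (str, Path)):
        seqs: Iterable[str] = (str(r.seq) for r in SeqIO.parse(str(fastq), "fastq"))
    else:
        seqs = fastq
    if locate == "flank_anchor" and not anchor:
        raise ValueError("flank_anchor mode requires an anchor sequence")
    for seq in seqs:
        if locate == "fixed_offset":
            candidate = seq[offset : offset + SPACER_LEN]
        elif locate == "flank_anchor":
            first = seq.find(anchor)
            if first < 0 or seq.find(anchor, first + 1) >= 0:
                unassigned += 1
                continue
            start = first + len(anchor)
            candidate = seq[start : start + SPACER_LEN]
        else:
            raise ValueError(f"unknown locate mode {locate!r}")
        idx = lookup.get(candidate)
        if idx is None:
            unassigned += 1
        else:
            counts[idx] += 1
    return pd.Series(counts, index=pd.Index(spacers, name="spacer"), name="count"), unassigned


def count_table(count_before: pd.Series, count_after: pd.Series) -> pd.DataFrame:
    """Before/after count table with pseudocount-normalized log2 fold changes."""
    df = pd.DataFrame({"count_before": count_before, "count_after": count_after}).fillna(0)
    n_before = max(int(df["count_before"].sum()), 1)
    n_after = max(int(df["count_after"].sum()), 1)
    df["log2fc"] = np.log2((df["count_after"] + 1) / n_after) - np.log2(
        (df["count_before"] + 1) / n_before
    )
    return df


def sgrna_profile(
    table: pd.DataFrame, sgrnas: Sequence[SgrnaRecord], ref: CdsReference
) -> pd.Series:
    """Per-residue mean log2fc of guides cutting within each codon.

    Residues with no guide are missing (NaN).
    """
    n = ref.protein_length
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    lfc = table["log2fc"]
    for rec in sgrnas:
        if rec.spacer not in lfc.index:
            continue
        residue = rec.residue(ref)
        if 1 <= residue <= n:
            sums[residue - 1] += lfc[rec.spacer]
            counts[residue - 1] += 1
    with np.errstate(invalid="ignore"):
        track = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(track, index=pd.RangeIndex(1, n + 1, name="residue"), name="log2fc")


def replicate_correlation(table_rep1: pd.DataFrame, table_rep2: pd.DataFrame) -> float:
    """Pearson correlation of log2 fold changes over guides shared by replicates."""
    shared = table_rep1.index.intersection(table_rep2.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sgRNAs; need at least 3")
    x = table_rep1.loc[shared, "log2fc"].to_numpy(dtype=float)
    y = table_rep2.loc[shared, "log2fc"].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    if math.isnan(r):
        raise ValueError("degenerate fold-change vectors (zero variance)")
    return r
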