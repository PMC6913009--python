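"""Per-effect-type frequencies, coverage denominators and summary tables.

The frequency of an effect type is its read count divided by the number of
retained reads whose alignment fully contains the effect's codon-extended
nucleotide footprint ("covered region").  Reads only partially overlapping a
footprint cannot establish presence or absence of the event and are excluded
from that denominator.  Residues with zero coverage are reported as missing
(NaN), never as frequency 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extraction import AaEffect, AlignedFragment
from .reference import CdsReference

__all__ = [
    "FragmentPool",
    "covering_reads",
    "effect_frequencies",
    "substitution_frequency",
    "aa_coverage",
    "substitution_pattern",
    "depth_saturation",
    "AMINO_ACIDS",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class FragmentPool:
    """Aligned reference spans of the retained read pool, as numpy arrays."""

    starts: np.ndarray
    ends: np.ndarray

    @classmethod
    def from_fragments(cls, fragments: Iterable[AlignedFragment]) -> "FragmentPool":
        spans = [(f.cds_start, f.ref_end) for f in fragments]
        if spans:
            starts, ends = (np.asarray(a, dtype=np.int64) for a in zip(*spans))
        else:
            starts = ends = np.empty(0, dtype=np.int64)
        return cls(starts=starts, ends=ends)

    @classmethod
    def from_spans(cls, spans: Sequence[tuple[int, int]]) -> "FragmentPool":
        if spans:
            starts, ends = (np.asarray(a, dtype=np.int64) for a in zip(*spans))
        else:
            starts = ends = np.empty(0, dtype=np.int64)
        return cls(starts=starts, ends=ends)

    def __len__(self) -> int:
        return len(self.starts)

    def covering(self, start: int, end: int) -> int:
        """Number of reads whose span fully contains [start, end)."""
        if end <= start:
            raise ValueError(f"empty region [{start}, {end})")
        return int(np.count_nonzero((self.starts <= start) & (self.ends >= end)))

    def codon_coverage(self, n_codons: int) -> np.ndarray:
        """Per-residue count of reads fully covering each codon (index 0 = residue 1)."""
        out = np.zeros(n_codons, dtype=np.int64)
        for i in range(n_codons):
            a, b = 3 * i, 3 * i + 3
            out[i] = np.count_nonzero((self.starts <= a) & (self.ends >= b))
        return out


def _as_pool(fragments) -> FragmentPool:
    if isinstance(fragments, FragmentPool):
        return fragments
    return FragmentPool.from_fragments(fragments)


def covering_reads(region: tuple[int, int], fragments) -> int:
    """Count fragments whose aligned span fully contains ``region``."""
    return _as_pool(fragments).covering(*region)


EFFECT_COLUMNS = [
    "category",
    "residue_start",
    "affected_length",
    "alt_residues",
    "read_count",
    "covering_reads",
    "frequency",
]


def effect_frequencies(
    effects: Iterable[AaEffect],
    fragments,
    categories: tuple[str, ...] = ("aa_deletion", "combo"),
    min_count: int = 9,
) -> pd.DataFrame:
    """Per-effect-key frequency table for one condition.

    Keys are (category, residue_start, affected_length, alt_residues); keys
    supported by fewer than ``min_count`` reads are dropped, and each retained
    key's frequency uses its own footprint-containment denominator.
    """
    pool = _as_pool(fragments)
    counts: dict[tuple, int] = {}
    footprints: dict[tuple, tuple[int, int]] = {}
    for eff in effects:
        if eff.category not in categories:
            continue
        key = eff.key
        counts[key] = counts.get(key, 0) + 1
        footprints.setdefault(key, eff.footprint)
    rows = []
    for key, n in counts.items():
        if n < min_count:
            continue
        cov = pool.covering(*footprints[key])
        if cov <= 0:
            continue
        category, rs, al, alt = key
        rows.append((category, rs, al, alt, n, cov, n / cov))
    df = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    return df.sort_values(["residue_start", "category", "affected_length", "alt_residues"]).reset_index(
        drop=True
    )


def _substitution_residues(eff: AaEffect, ref: CdsReference) -> list[int]:
    """Residues of a substitution effect whose amino acid actually changed."""
    protein = ref.protein + "*"
    out = []
    for offset in range(eff.affected_length):
        residue = eff.residue_start + offset
        if residue - 1 < len(protein) and eff.alt_residues[offset] != protein[residue - 1]:
            out.append(residue)
    return out


def substitution_frequency(
    effects: Iterable[AaEffect],
    fragments,
    ref: CdsReference,
    min_count: int = 9,
    include_nonsense: bool = False,
) -> pd.Series:
    """Per-residue substitution frequency (missense reads / codon coverage).

    A multi-residue substitution contributes its read once to every residue it
    changes.  Substitutions introducing a stop codon are excluded by default
    (they behave as null alleles, not missense changes).  Residues with zero
    coverage are NaN.
    """
    pool = _as_pool(fragments)
    n = ref.protein_length
    counts: dict[tuple, int] = {}
    keyed: dict[tuple, AaEffect] = {}
    for eff in effects:
        if eff.category != "substitution":
            continue
        if not include_nonsense and "*" in eff.alt_residues:
            continue
        counts[eff.key] = counts.get(eff.key, 0) + 1
        keyed.setdefault(eff.key, eff)
    numerator = np.zeros(n, dtype=np.int64)
    for key, c in counts.items():
        if c < min_count:
            continue
        for residue in _substitution_residues(keyed[key], ref):
            if 1 <= residue <= n:
                numerator[residue - 1] += c
    denominator = pool.codon_coverage(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(denominator > 0, numerator / np.maximum(denominator, 1), np.nan)
    return pd.Series(freq, index=pd.RangeIndex(1, n + 1, name="residue"), name="freq_sub")


def aa_coverage(
    effect_table: pd.DataFrame, protein_length: int, max_affected: int = 3
) -> tuple[float, np.ndarray]:
    """Fraction of residues touched by >=1 retained deletion/combo key.

    Only keys affecting at most ``max_affected`` residues count, mirroring the
    false-positive guard applied in scoring.
    """
    touched = np.zeros(protein_length, dtype=bool)
    for row in effect_table.itertuples():
        if row.category not in ("aa_deletion", "combo"):
            continue
        length = max(int(row.affected_length), 1)
        if int(row.affected_length) > max_affected:
            continue
        a = int(row.residue_start) - 1
        touched[max(a, 0) : min(a + length, protein_length)] = True
    return float(touched.mean()) if protein_length else 0.0, touched


def substitution_pattern(
    effects: Iterable[AaEffect], residues: Sequence[int], ref: CdsReference, min_count: int = 0
) -> pd.DataFrame:
    """Read counts per (residue, alternative amino acid) for listed residues.

    Alternatives equal to the reference residue (protein-level silent) and
    stop gains are excluded.
    """
    protein = ref.protein
    counts: dict[tuple, int] = {}
    for eff in effects:
        if eff.category != "substitution":
            continue
        counts[eff.key] = counts.get(eff.key, 0) + 1
    mat = pd.DataFrame(0, index=pd.Index(residues, name="residue"), columns=list(AMINO_ACIDS))
    for (category, rs, al, alt), c in counts.items():
        if c < min_count:
            continue
        for offset in range(al):
            residue = rs + offset
            if residue not in mat.index:
                continue
            aa = alt[offset]
            if aa == "*" or residue - 1 >= len(protein) or aa == protein[residue - 1]:
                continue
            mat.loc[residue, aa] += c
    return mat


def depth_saturation(
    calls: Sequence[tuple[tuple[int, int], AaEffect | None]],
    depths: Sequence[int],
    seed: int = 0,
    min_count: int = 9,
    categories: tuple[str, ...] = ("aa_deletion", "combo"),
) -> pd.DataFrame:
    """Retained effect-key counts at seeded subsampled depths.

    ``calls`` pairs each retained read's reference span with its effect (or
    None).  Key retention is purely count-based, so denominators are not
    needed here.
    """
    rng = np.random.default_rng(seed)
    n = len(calls)
    rows = []
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds pool size {n}")
        idx = rng.choice(n, size=depth, replace=False) if depth < n else np.arange(n)
        counts: dict[tuple, int] = {}
        for i in idx:
            eff = calls[i][1]
            if eff is not None and eff.category in categories:
                counts[eff.key] = counts.get(eff.key, 0) + 1
        row = {"depth": depth}
        for cat in categories:
            row[cat] = sum(
                1 for key, c in counts.items() if key[0] == cat and c >= min_count
            )
        rows.append(row)
    return pd.DataFrame(rows)
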