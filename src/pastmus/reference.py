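"""Coding-sequence reference handling and nucleotide/codon/residue coordinate maps.

A tiling mutagenesis screen reads out mutations in coordinates of the target
gene's CDS.  Everything downstream (sgRNA design, variant calling, per-residue
scoring) is expressed against a single validated :class:`CdsReference`.

Internal coordinates are 0-based, half-open on the nucleotide sequence;
residues are numbered 1-based in all user-facing outputs (the convention used
when naming sites such as F115 or M104).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CdsReference",
    "CdsValidationError",
    "load_cds",
    "translate",
    "reverse_complement",
    "CODON_TO_AA",
    "STOP_CODONS",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; stop codons appear as '*'."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3))


class CdsValidationError(ValueError):
    """Raised when a putative CDS violates the reference invariants."""


@dataclass(frozen=True)
class CdsReference:
    """A validated coding sequence with codon/residue coordinate helpers.

    Invariants enforced at construction: the sequence is uppercase ACGT, its
    length is a positive multiple of 3, and its translation contains no
    internal stop codon.  ``protein_length`` excludes the terminal stop codon
    when one is present.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise CdsValidationError(f"{self.gene_id}: empty sequence")
        for pos, base in enumerate(seq):
            if base not in "ACGT":
                raise CdsValidationError(
                    f"{self.gene_id}: non-ACGT character {base!r} at position {pos + 1}"
                )
        if len(seq) % 3:
            raise CdsValidationError(
                f"{self.gene_id}: length {len(seq)} is not a multiple of 3"
            )
        protein = translate(seq)
        internal = protein[:-1]
        if "*" in internal:
            codon = internal.index("*") + 1
            raise CdsValidationError(
                f"{self.gene_id}: internal stop at codon {codon}"
            )

    # -- derived views ----------------------------------------------------

    @property
    def protein_length(self) -> int:
        """Number of residues excluding the terminal stop codon (if present)."""
        n = len(self.sequence) // 3
        return n - 1 if self.sequence[-3:] in STOP_CODONS else n

    @property
    def protein(self) -> str:
        """Translation without the terminal stop."""
        return translate(self.sequence)[: self.protein_length]

    # -- coordinate maps --------------------------------------------------

    def residue_to_nt_range(self, residue: int) -> tuple[int, int]:
        """Half-open nt interval of a 1-based residue's codon."""
        if not 1 <= residue <= len(self.sequence) // 3:
            raise ValueError(f"residue {residue} outside 1..{len(self.sequence) // 3}")
        return 3 * (residue - 1), 3 * residue

    def nt_to_residue(self, pos: int) -> int:
        """1-based residue whose codon contains 0-based nt position ``pos``."""
        if not 0 <= pos < len(self.sequence):
            raise ValueError(f"nt position {pos} outside [0, {len(self.sequence)})")
        return pos // 3 + 1

    def codon(self, residue: int) -> str:
        a, b = self.residue_to_nt_range(residue)
        return self.sequence[a:b]


def load_cds(fasta_path: str | Path, gene_id: str | None = None) -> CdsReference:
    """Load and validate a CDS from FASTA.

    The first record is used unless ``gene_id`` selects a specific one.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise CdsValidationError(f"{fasta_path}: no FASTA records")
    if gene_id is None:
        record = records[0]
    else:
        by_id = {r.id: r for r in records}
        if gene_id not in by_id:
            raise CdsValidationError(
                f"{fasta_path}: no record {gene_id!r}; available: {sorted(by_id)}"
            )
        record = by_id[gene_id]
    return CdsReference(gene_id=record.id, sequence=str(record.seq).upper())
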