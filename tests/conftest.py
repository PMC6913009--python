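"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from hypothesis import settings

from pastmus.extraction import AlignedFragment, NtVariant
from pastmus.reference import CdsReference, translate

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def toy_ref() -> CdsReference:
    """ATG GCT GGT TAA -> protein MAG."""
    return CdsReference(gene_id="toy", sequence="ATGGCTGGTTAA")


@pytest.fixture
def mkp_ref() -> CdsReference:
    """ATG AAA CCC TAA -> protein MKP."""
    return CdsReference(gene_id="mkp", sequence="ATGAAACCCTAA")


def random_cds_protein(n_codons: int, seed: int) -> CdsReference:
    """Random CDS with ``n_codons`` codons including the terminal stop."""
    rng = np.random.default_rng(seed)
    nonstop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    body = "".join(nonstop[i] for i in rng.integers(len(nonstop), size=n_codons - 2))
    return CdsReference(gene_id="rand", sequence="ATG" + body + "TAA")


# ---------------------------------------------------------------------------
# independent oracles


def apply_variants_full(seq: str, variants: list[NtVariant]) -> str:
    """Apply sorted variants to the whole CDS."""
    parts = []
    pos = 0
    for v in sorted(variants, key=lambda v: v.ref_start):
        parts.append(seq[pos : v.ref_start])
        parts.append(v.alt)
        pos = v.ref_start + v.ref_length
    parts.append(seq[pos:])
    return "".join(parts)


def oracle_protein_diff(ref: CdsReference, variants: list[NtVariant]) -> tuple:
    """Brute-force mutant translation + residue-level prefix/suffix trim.

    Translates the *entire* mutant CDS (no windowing) and trims the longest
    common prefix, then suffix, of the two proteins — an independent route to
    the canonical (category, residue_start, affected_length, alt_residues).
    """
    mutant = apply_variants_full(ref.sequence, variants)
    assert len(mutant) % 3 == 0
    ref_prot = translate(ref.sequence)
    mut_prot = translate(mutant)
    limit = min(len(ref_prot), len(mut_prot))
    p = 0
    while p < limit and ref_prot[p] == mut_prot[p]:
        p += 1
    s = 0
    while s < limit - p and ref_prot[-1 - s] == mut_prot[-1 - s]:
        s += 1
    ref_rem = ref_prot[p : len(ref_prot) - s]
    alt = mut_prot[p : len(mut_prot) - s]
    net = len(mutant) - len(ref.sequence)
    if not ref_rem and not alt:
        return ("silent", None, 0, "")
    if not alt:
        cat = "aa_deletion"
    elif net != 0:
        cat = "combo"
    elif len(ref_rem) == len(alt):
        cat = "substitution"
    else:
        cat = "combo"
    return (cat, p + 1, len(ref_rem), alt)


def make_affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


def realign_fragment(
    ref: CdsReference, read: str, aligner: Align.PairwiseAligner, read_id: str = "r"
) -> AlignedFragment:
    """Realign a read to the CDS with an affine-gap aligner -> AlignedFragment."""
    aln = aligner.align(ref.sequence, read)[0]
    ref_blocks, query_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    if query_blocks[0][0] > 0:
        ops.append(("S", int(query_blocks[0][0])))
    for i, (rb, qb) in enumerate(zip(ref_blocks, query_blocks)):
        if i:
            dref = int(rb[0] - ref_blocks[i - 1][1])
            dq = int(qb[0] - query_blocks[i - 1][1])
            if dref:
                ops.append(("D", dref))
            if dq:
                ops.append(("I", dq))
        ops.append(("M", int(rb[1] - rb[0])))
    if query_blocks[-1][1] < len(read):
        ops.append(("S", len(read) - int(query_blocks[-1][1])))
    return AlignedFragment(
        read_id=read_id,
        cds_start=int(ref_blocks[0][0]),
        cigar=tuple(ops),
        query_seq=read,
        base_qualities=bytes([40]) * len(read),
    )


def plant_random_variants(
    ref: CdsReference, rng: np.random.Generator, margin: int = 18
) -> tuple[list[NtVariant], str, tuple[int, int]]:
    """One random in-frame variant set + the mutant read carrying it.

    Returns (variants, mutant read string, reference span of the read).  The
    variants sit at least ``margin`` nt inside the read so that realignment
    and codon extension never clip them.
    """
    L = len(ref.sequence)
    flen = int(rng.integers(120, 240))
    start = int(rng.integers(0, L - flen + 1))
    end = start + flen
    kind = rng.choice(["del", "ins", "sub", "del+sub"])
    lo, hi = start + margin, end - margin
    variants: list[NtVariant] = []
    if kind == "del":
        d = int(rng.choice([3, 6, 9, 12]))
        pos = int(rng.integers(lo, hi - d))
        variants.append(NtVariant("deletion", pos, d, ""))
    elif kind == "ins":
        n = 3
        pos = int(rng.integers(lo, hi))
        ins = "".join("ACGT"[i] for i in rng.integers(4, size=n))
        variants.append(NtVariant("insertion", pos, 0, ins))
    elif kind == "sub":
        n = int(rng.integers(1, 4))
        pos = int(rng.integers(lo, hi - n))
        alt = ""
        for i in range(n):
            old = ref.sequence[pos + i]
            new = "ACGT"[int(rng.integers(4))]
            while new == old:
                new = "ACGT"[int(rng.integers(4))]
            alt += new
        variants.append(NtVariant("substitution", pos, n, alt))
    else:  # deletion plus a nearby point change, still in frame
        d = int(rng.choice([3, 6]))
        pos = int(rng.integers(lo, hi - d - 30))
        variants.append(NtVariant("deletion", pos, d, ""))
        spos = pos + d + int(rng.integers(5, 20))
        old = ref.sequence[spos]
        new = "ACGT"[int(rng.integers(4))]
        while new == old:
            new = "ACGT"[int(rng.integers(4))]
        variants.append(NtVariant("substitution", spos, 1, new))
    read = (
        ref.sequence[start : variants[0].ref_start]
        + "".join(
            v.alt + ref.sequence[v.ref_start + v.ref_length : w.ref_start]
            for v, w in zip(variants, variants[1:])
        )
        + variants[-1].alt
        + ref.sequence[variants[-1].ref_start + variants[-1].ref_length : end]
    )
    return variants, read, (start, end)
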