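"""Per-read mutation extraction and amino-acid effect calling.

Aligned ~250 bp cDNA fragments (SAM) are compared against the CDS to emit
nucleotide-level variants, classify the net reading frame, and translate
in-frame changes into amino-acid effects:

* ``aa_deletion`` — in-frame deletion removing residues, no new residue;
* ``combo``       — in-frame indel combining residue loss (or gain) with a
                    changed residue;
* ``substitution``— missense change with no length change;
* ``silent``      — nucleotide change with identical protein;
* ``frameshift``  — net indel length not a multiple of 3 (filtered out of
                    all downstream quantification).

The canonical residue interval of an effect is obtained by translating the
codon-extended window around all variants of a read and trimming the longest
common prefix, then the longest common suffix, at the residue level.  This
yields a single deterministic call for repeat-region-ambiguous indels.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
import pysam

from .reference import CdsReference, translate

__all__ = [
    "AlignedFragment",
    "NtVariant",
    "AaEffect",
    "ReadCall",
    "SamStats",
    "read_sam",
    "mean_quality",
    "quality_filter",
    "extract_nt_variants",
    "classify_frame",
    "translate_effect",
    "call_fragment",
    "mutagenesis_window_profile",
    "UncoveredVariantError",
]

logger = logging.getLogger(__name__)

_QUERY_OPS = frozenset("M=XIS")
_REF_OPS = frozenset("M=XD")


@dataclass(slots=True)
class AlignedFragment:
    """One aligned cDNA fragment in CDS coordinates.

    ``cigar`` is a tuple of (op, length) with op in {M,=,X,I,D,S}.
    ``base_qualities`` holds Phred scores as bytes, or None when absent.
    """

    read_id: str
    cds_start: int
    cigar: tuple[tuple[str, int], ...]
    query_seq: str
    base_qualities: bytes | None = None

    @property
    def ref_end(self) -> int:
        return self.cds_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.cds_start, self.ref_end


@dataclass(frozen=True, slots=True)
class NtVariant:
    """A nucleotide-level difference between a read and the reference."""

    kind: str  # deletion | insertion | substitution
    ref_start: int  # 0-based CDS coordinate
    ref_length: int  # 0 for insertion
    alt: str  # empty for deletion

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_length

    @property
    def net(self) -> int:
        return len(self.alt) - self.ref_length


@dataclass(frozen=True, slots=True)
class AaEffect:
    """Protein-level consequence of one read's in-frame variants."""

    category: str
    residue_start: int  # 1-based; 0 for wildtype
    affected_length: int  # residues on the reference protein
    alt_residues: str
    source_variants: tuple[NtVariant, ...] = ()
    has_insertion: bool = False

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.category, self.residue_start, self.affected_length, self.alt_residues)

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference nt interval used for coverage denominators.

        At least one codon wide so that insertion-only effects (affected
        length 0) still have a well-defined covered region.
        """
        a = 3 * (self.residue_start - 1)
        b = a + 3 * max(self.affected_length, 1)
        return a, b


class ReadCall(NamedTuple):
    frame: str  # wildtype | sub_only | in_frame_indel | frameshift
    effect: AaEffect | None
    status: str  # called | wildtype | frameshift | uncallable


@dataclass
class SamStats:
    total: int = 0
    used: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0


_CIGAR_CODE = {0: "M", 1: "I", 2: "D", 4: "S", 7: "=", 8: "X"}


def read_sam(
    sam_path: str | Path,
    ref: CdsReference,
    offset: int = 0,
    stats: SamStats | None = None,
) -> Iterator[AlignedFragment]:
    """Stream mapped primary alignments from a SAM/BAM file.

    ``offset`` shifts alignment coordinates when reads were aligned to an
    amplicon sub-reference rather than the full CDS.  Unmapped, secondary and
    supplementary records are skipped and counted in ``stats``.
    """
    if stats is None:
        stats = SamStats()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        names = list(fh.references or ())
        if names and ref.gene_id not in names:
            raise ValueError(
                f"{sam_path}: reference {ref.gene_id!r} not in SAM header; "
                f"available: {names}"
            )
        for rec in fh:
            stats.total += 1
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary:
                stats.skipped_secondary += 1
                continue
            if rec.is_supplementary:
                stats.skipped_supplementary += 1
                continue
            cigar = tuple(
                (_CIGAR_CODE.get(code, chr(code)), ln) for code, ln in (rec.cigartuples or ())
            )
            quals = rec.query_qualities
            stats.used += 1
            yield AlignedFragment(
                read_id=rec.query_name,
                cds_start=rec.reference_start + offset,
                cigar=cigar,
                query_seq=rec.query_sequence or "",
                base_qualities=bytes(quals) if quals is not None else None,
            )


def mean_quality(frag: AlignedFragment) -> float | None:
    if not frag.base_qualities:
        return None
    return sum(frag.base_qualities) / len(frag.base_qualities)


_warned_missing_quals = False


def quality_filter(frag: AlignedFragment, min_q: float = 30, mode: str = "mean") -> bool:
    """Keep a fragment iff its base quality passes the threshold.

    ``mode='mean'`` (default) drops reads whose mean Phred quality is below
    ``min_q``; ``mode='min'`` requires every base to pass.  Missing qualities
    ('*' in SAM) pass with a one-time warning.
    """
    global _warned_missing_quals
    if not frag.base_qualities:
        if not _warned_missing_quals:
            logger.warning("reads without base qualities treated as passing the quality filter")
            _warned_missing_quals = True
        return True
    if mode == "mean":
        return mean_quality(frag) >= min_q
    if mode == "min":
        return min(frag.base_qualities) >= min_q
    raise ValueError(f"unknown quality filter mode {mode!r}")


def extract_nt_variants(frag: AlignedFragment, ref: CdsReference) -> list[NtVariant]:
    """Diff an aligned fragment against the reference.

    Maximal runs of consecutive mismatching bases merge into one substitution
    variant; I/D ops emit insertion/deletion variants.  Soft-clipped bases are
    ignored.  CIGAR ops outside {M,=,X,I,D,S} reject the read.
    """
    seq = ref.sequence
    query = frag.query_seq
    rpos = frag.cds_start
    qpos = 0
    out: list[NtVariant] = []
    for op, ln in frag.cigar:
        if op in "M=X":
            refblock = seq[rpos : rpos + ln]
            qblock = query[qpos : qpos + ln]
            if refblock != qblock:
                i = 0
                while i < ln:
                    if qblock[i] != refblock[i]:
                        j = i + 1
                        while j < ln and qblock[j] != refblock[j]:
                            j += 1
                        out.append(NtVariant("substitution", rpos + i, j - i, qblock[i:j]))
                        i = j
                    else:
                        i += 1
            rpos += ln
            qpos += ln
        elif op == "I":
            out.append(NtVariant("insertion", rpos, 0, query[qpos : qpos + ln]))
            qpos += ln
        elif op == "D":
            out.append(NtVariant("deletion", rpos, ln, ""))
            rpos += ln
        elif op == "S":
            qpos += ln
        else:
            raise ValueError(f"read {frag.read_id}: unsupported CIGAR op {op!r}")
    # merge substitution runs split across an op boundary
    merged: list[NtVariant] = []
    for v in out:
        if (
            merged
            and v.kind == "substitution"
            and merged[-1].kind == "substitution"
            and merged[-1].ref_end == v.ref_start
        ):
            prev = merged.pop()
            v = NtVariant("substitution", prev.ref_start, prev.ref_length + v.ref_length, prev.alt + v.alt)
        merged.append(v)
    merged.sort(key=lambda v: v.ref_start)
    return merged


def classify_frame(variants: list[NtVariant]) -> str:
    """Net-frame class of one read's variants."""
    if not variants:
        return "wildtype"
    net = 0
    has_indel = False
    for v in variants:
        if v.kind != "substitution":
            has_indel = True
            net += v.net
    if not has_indel:
        return "sub_only"
    return "in_frame_indel" if net % 3 == 0 else "frameshift"


class UncoveredVariantError(ValueError):
    """The fragment does not cover the codon-extended window of its variants."""


def _apply_variants(seq: str, variants: Iterable[NtVariant], ws: int, we: int) -> str:
    parts: list[str] = []
    pos = ws
    for v in variants:
        parts.append(seq[pos : v.ref_start])
        parts.append(v.alt)
        pos = v.ref_end
    parts.append(seq[pos:we])
    return "".join(parts)


def translate_effect(
    variants: list[NtVariant],
    ref: CdsReference,
    frag_span: tuple[int, int] | None = None,
) -> AaEffect:
    """Translate a frame-preserving variant set into its amino-acid effect.

    The reference window is extended to codon boundaries around all variants,
    both windows are translated, and the longest common prefix then suffix are
    trimmed at the residue level; what remains defines the canonical residue
    interval and replacement residues.

    Raises :class:`UncoveredVariantError` when ``frag_span`` does not fully
    contain the codon-extended window (such reads cannot be unambiguously
    translated and are excluded from effect calling).
    """
    if not variants:
        return AaEffect("wildtype", 0, 0, "")
    net = sum(v.net for v in variants)
    if net % 3:
        raise ValueError("variants shift the reading frame; no amino-acid effect")
    vmin = min(v.ref_start for v in variants)
    vmax = max(v.ref_end for v in variants)
    L = len(ref.sequence)
    ws = (vmin // 3) * 3
    we = -(-vmax // 3) * 3
    if we <= ws:  # pure insertion exactly at a codon boundary
        we = min(ws + 3, L)
        if we <= ws:
            ws = we - 3
    while True:
        if frag_span is not None and not (frag_span[0] <= ws and we <= frag_span[1]):
            raise UncoveredVariantError(
                f"fragment span {frag_span} does not cover variant window [{ws}, {we})"
            )
        mutant = _apply_variants(ref.sequence, variants, ws, we)
        ref_prot = translate(ref.sequence[ws:we])
        mut_prot = translate(mutant)

        limit = min(len(ref_prot), len(mut_prot))
        p = 0
        while p < limit and ref_prot[p] == mut_prot[p]:
            p += 1
        s = 0
        while s < limit - p and ref_prot[-1 - s] == mut_prot[-1 - s]:
            s += 1
        # An indel diff flush with the right window edge (prefix trim consumed
        # the whole shorter protein, so no mismatch or suffix residue anchors
        # it) is not yet canonical: inside a repeat run the prefix-first trim
        # could shift it further right.  Extend the window until anchored.
        if net != 0 and p == limit and s == 0 and we < L:
            we += 3
            continue
        break
    ref_rem = ref_prot[p : len(ref_prot) - s]
    alt = mut_prot[p : len(mut_prot) - s]
    has_ins = any(v.kind == "insertion" for v in variants)

    if not ref_rem and not alt:
        return AaEffect("silent", ws // 3 + 1, 0, "", tuple(variants), has_ins)
    residue_start = ws // 3 + p + 1
    if not alt:
        category = "aa_deletion"
    elif net != 0:
        category = "combo"
    elif len(ref_rem) == len(alt):
        category = "substitution"
    else:  # net == 0 with unequal trims (compensating indels)
        category = "combo"
    return AaEffect(category, residue_start, len(ref_rem), alt, tuple(variants), has_ins)


def call_fragment(frag: AlignedFragment, ref: CdsReference) -> ReadCall:
    """Full per-read call: variants, frame class, amino-acid effect.

    Reads whose in-frame change introduces a premature stop codon are
    truncating alleles, not residue-level information; they are filtered out
    alongside frameshifts (status ``stop_gain``).
    """
    # fast path: a single full-match M block
    if len(frag.cigar) == 1 and frag.cigar[0][0] in "M=":
        n = frag.cigar[0][1]
        if frag.query_seq == ref.sequence[frag.cds_start : frag.cds_start + n]:
            return ReadCall("wildtype", None, "wildtype")
    variants = extract_nt_variants(frag, ref)
    frame = classify_frame(variants)
    if frame == "wildtype":
        return ReadCall(frame, None, "wildtype")
    if frame == "frameshift":
        return ReadCall(frame, None, "frameshift")
    try:
        effect = translate_effect(variants, ref, frag.ref_span)
    except UncoveredVariantError:
        return ReadCall(frame, None, "uncallable")
    if "*" in effect.alt_residues:
        return ReadCall(frame, effect, "stop_gain")
    return ReadCall(frame, effect, "called")


def _variant_signature(variants: Iterable[NtVariant]) -> tuple:
    return tuple((v.kind, v.ref_start, v.ref_length, v.alt) for v in variants)


def mutagenesis_window_profile(
    fragments: Iterable[AlignedFragment],
    ref: CdsReference,
    cut_site: int,
    window_nt: int = 20,
    downsample_to: int = 100_000,
    min_count: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mutation-variety profile around one Cas9 cut site.

    Reads are downsampled (without replacement, seeded) to ``downsample_to``,
    variants are restricted to +/- ``window_nt`` of the cut site, and variant
    signatures seen fewer than ``min_count`` times are dropped.  Returns one
    row per retained signature with its count and in-frame status.
    """
    frags = list(fragments)
    if len(frags) > downsample_to:
        frags = random.Random(seed).sample(frags, downsample_to)
    lo, hi = cut_site - window_nt, cut_site + window_nt
    counts: dict[tuple, int] = {}
    for frag in frags:
        variants = [
            v
            for v in extract_nt_variants(frag, ref)
            if v.ref_start <= hi and max(v.ref_end, v.ref_start + 1) >= lo
        ]
        if not variants:
            continue
        sig = _variant_signature(variants)
        counts[sig] = counts.get(sig, 0) + 1
    rows = []
    for sig, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if n < min_count:
            continue
        net = sum(len(alt) - ln for kind, start, ln, alt in sig)
        has_indel = any(kind != "substitution" for kind, *_ in sig)
        rows.append(
            {
                "signature": ";".join(f"{k}@{s}:{l}:{a}" for k, s, l, a in sig),
                "count": n,
                "in_frame": bool(not has_indel or net % 3 == 0),
                "has_indel": has_indel,
            }
        )
    return pd.DataFrame(rows, columns=["signature", "count", "in_frame", "has_indel"])
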