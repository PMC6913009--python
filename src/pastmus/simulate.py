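"""Synthetic tiling-mutagenesis screen generator.

Emulates the full data-generating process of a positive-selection tiling
screen so the analysis pipeline can be exercised end to end without external
data:

1. a random CDS and its tiling sgRNA library;
2. a cell population in which each cell carries one integrated guide and each
   allele is independently edited at that guide's cut site (deletion-skewed
   indel spectrum plus rare missense outcomes);
3. allele-level function calls and a genotype->phenotype rule — recessive
   loss of function requires that no functional allele remains, a dominant
   gain-of-function allele acts alone, and for essential genes the all-null
   genotype is removed from the population (cell death);
4. selection as multinomial read sampling with resistant cells weighted by
   an enrichment factor, random ~250 bp fragmentation and per-base
   sequencing errors, written as truth alignments (correct POS/CIGAR).

Identical configuration + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
import yaml

from .design import SgrnaRecord, design_tiling_sgrnas, write_library
from .extraction import AlignedFragment, NtVariant, classify_frame, translate_effect
from .quantify import _substitution_residues
from .reference import CdsReference, translate

__all__ = [
    "SimulationConfig",
    "Allele",
    "Cell",
    "TruthTable",
    "SimulatedScreen",
    "random_cds",
    "reachable_residues",
    "choose_critical_residues",
    "allele_class",
    "classify_resistance",
    "simulate_population",
    "simulate_fragments",
    "simulate_barcode_reads",
    "simulate_screen",
    "simulate_replicate_screens",
    "write_outputs",
]

CONDITIONS = ("before", "after", "mock")

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults model a desk-scale diploid positive-selection screen: high
    per-allele editing, a deletion-skewed repair spectrum (deletion length
    1-12 nt with probability ~ 0.7**len, 10% 1-2 nt insertions), rare
    missense outcomes, ~250 bp fragments and Illumina-like 1e-3 per-base
    error.
    """

    protein_length: int = 200
    ploidy: int = 2
    gene_essential: bool = False
    inheritance: str = "recessive"  # or "dominant"
    critical_residues: tuple[int, ...] | None = None  # None: auto-place n_critical
    n_critical: int = 5
    n_cells: int = 20_000  # keeps ~5 reads per allele at the default depth,
    # matching the read support per variant of the full-scale protocol at its
    # recommended before-library sequencing depth
    edit_rate: float = 0.8
    # per-guide editing efficiency ~ Beta with mean edit_rate and this
    # concentration (guide-intrinsic, so replicate screens share it);
    # 0 disables the heterogeneity
    guide_efficiency_concentration: float = 5.0
    missense_rate: float = 0.05
    insertion_rate: float = 0.1
    deletion_decay: float = 0.7
    max_deletion: int = 12
    max_insertion: int = 2
    enrichment: float = 50.0
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 25.0
    seq_error_rate: float = 1e-3
    depth: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edit_rate", "missense_rate", "insertion_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.inheritance not in ("recessive", "dominant"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.critical_residues is not None:
            bad = [r for r in self.critical_residues if not 1 <= r <= self.protein_length]
            if bad:
                raise ValueError(f"critical residues outside protein: {bad}")


@dataclass(frozen=True)
class Allele:
    variant: NtVariant | None
    cls: str  # functional | function_altering | null


@dataclass(frozen=True)
class Cell:
    sgrna_index: int
    alleles: tuple[Allele, ...]
    resistant: bool


@dataclass
class TruthTable:
    ref: CdsReference
    sgrnas: list[SgrnaRecord]
    cells: list[Cell]
    critical_residues: frozenset[int]
    n_dead: int = 0


@dataclass
class SimulatedScreen:
    config: SimulationConfig
    ref: CdsReference
    sgrnas: list[SgrnaRecord]
    truth: TruthTable
    fragments: dict[str, list[AlignedFragment]] = field(default_factory=dict)


def random_cds(
    protein_length: int, rng: np.random.Generator, gene_id: str = "synth"
) -> CdsReference:
    """Random CDS: ATG start, ``protein_length``-1 random non-stop codons, stop."""
    codons = rng.choice(len(_NONSTOP_CODONS), size=protein_length - 1)
    body = "".join(_NONSTOP_CODONS[i] for i in codons)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return CdsReference(gene_id=gene_id, sequence="ATG" + body + stop)


def guide_efficiencies(config: SimulationConfig, n_guides: int) -> np.ndarray:
    """Per-guide editing efficiencies (guide-intrinsic, so derived from the
    configuration seed: replicate screens of one library share them)."""
    kappa = config.guide_efficiency_concentration
    if kappa > 0 and 0 < config.edit_rate < 1:
        eff_rng = np.random.default_rng([config.seed, 104729])
        return eff_rng.beta(
            config.edit_rate * kappa, (1 - config.edit_rate) * kappa, size=n_guides
        )
    return np.full(n_guides, config.edit_rate)


def reachable_residues(
    ref: CdsReference,
    sgrnas: Sequence[SgrnaRecord],
    config: SimulationConfig,
    max_affected: int = 3,
) -> dict[int, float]:
    """Interrogation richness: efficiency-weighted in-frame deletion outcomes
    per residue.

    For every guide and in-frame deletion length, the canonical (trimmed)
    effect is computed exactly as the analysis pipeline computes it; an
    outcome counts toward a residue when it touches it, spans at most
    ``max_affected`` residues and introduces no stop codon, weighted by the
    guide's editing efficiency relative to the library mean.  Residues with
    richness 0 carry no deletion-level information in this screen.
    """
    L = len(ref.sequence)
    n = ref.protein_length
    richness: dict[int, float] = {}
    lengths = range(3, config.max_deletion + 1, 3)
    if config.edit_rate > 0:
        efficiencies = guide_efficiencies(config, len(sgrnas))
        mean_eff = config.edit_rate
    else:  # no editing: richness reduces to structural reach
        efficiencies = np.ones(len(sgrnas))
        mean_eff = 1.0
    span_cache: dict[tuple[int, int], range | None] = {}
    for gi, rec in enumerate(sgrnas):
        weight = efficiencies[gi] / mean_eff
        for d in lengths:
            start = min(rec.cut_site, L - d)
            span = span_cache.get((start, d))
            if span is None and (start, d) not in span_cache:
                eff = translate_effect([NtVariant("deletion", start, d, "")], ref)
                ok = (
                    eff.category in ("aa_deletion", "combo")
                    and "*" not in eff.alt_residues
                    and eff.affected_length <= max_affected
                )
                span = (
                    range(eff.residue_start, eff.residue_start + max(eff.affected_length, 1))
                    if ok
                    else None
                )
                span_cache[(start, d)] = span
            if span is None:
                continue
            for r in span:
                if 1 <= r <= n:
                    richness[r] = richness.get(r, 0.0) + weight
    return richness


def choose_critical_residues(
    ref: CdsReference,
    sgrnas: Sequence[SgrnaRecord],
    config: SimulationConfig,
    max_affected: int = 3,
    min_outcomes: int = 4,
) -> tuple[int, ...]:
    """Deterministically place ``n_critical`` critical residues, evenly spread
    across the well-interrogated part of the protein.

    Eligible residues are touched by at least ``min_outcomes`` distinct
    in-frame deletion outcomes of the library (so the planted truth is
    recoverable in principle); the planted sites sit at the centers of
    ``n_critical`` equal strata of the eligible set, representative of the
    protein body rather than the terminal fringe where guide density and
    deletion directionality leave a tiling screen least powered.
    """
    richness = reachable_residues(ref, sgrnas, config, max_affected)
    eligible = sorted(r for r, c in richness.items() if c >= min_outcomes)
    k = config.n_critical
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} well-interrogated residues; cannot plant {k} critical sites"
        )
    idx = [int((i + 0.5) * len(eligible) / k) for i in range(k)]
    return tuple(eligible[i] for i in idx)


def allele_class(
    variant: NtVariant | None, ref: CdsReference, critical: frozenset[int]
) -> str:
    """Functional call for one allele.

    Frameshifts and stop-gains are null; frame-preserving changes touching a
    critical residue are function-altering; everything else (wild type,
    silent, neutral in-frame changes) is functional.
    """
    if variant is None:
        return "functional"
    frame = classify_frame([variant])
    if frame == "frameshift":
        return "null"
    effect = translate_effect([variant], ref)
    if effect.category in ("wildtype", "silent"):
        return "functional"
    if "*" in effect.alt_residues:
        return "null"
    if effect.category == "substitution":
        affected = _substitution_residues(effect, ref)
    else:
        affected = range(effect.residue_start, effect.residue_start + max(effect.affected_length, 1))
    return "function_altering" if any(r in critical for r in affected) else "functional"


def classify_resistance(classes: Sequence[str], config: SimulationConfig) -> bool | None:
    """Genotype -> phenotype; ``None`` marks cell death (essential gene, all null).

    Recessive: resistant iff no functional allele remains (all alleles null,
    or function-altering in one or more and null in all the rest).  Dominant:
    one function-altering allele suffices.
    """
    if config.inheritance == "dominant":
        return "function_altering" in classes
    if all(c == "null" for c in classes):
        return None if config.gene_essential else True
    return "functional" not in classes


def _deletion_lengths(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(1, config.max_deletion + 1)
    probs = config.deletion_decay ** lengths
    return lengths, probs / probs.sum()


def _draw_edit(
    rng: np.random.Generator, cut_site: int, ref: CdsReference, config: SimulationConfig
) -> NtVariant:
    L = len(ref.sequence)
    if rng.random() < config.missense_rate:
        pos = min(cut_site, L - 1)
        old = ref.sequence[pos]
        alt = _BASES[rng.integers(4)]
        while alt == old:
            alt = _BASES[rng.integers(4)]
        return NtVariant("substitution", pos, 1, alt)
    if rng.random() < config.insertion_rate:
        n = int(rng.integers(1, config.max_insertion + 1))
        ins = "".join(_BASES[i] for i in rng.integers(4, size=n))
        return NtVariant("insertion", min(cut_site, L), 0, ins)
    lengths, probs = _deletion_lengths(config)
    n = int(rng.choice(lengths, p=probs))
    start = min(cut_site, L - n)
    return NtVariant("deletion", start, n, "")


def simulate_population(
    config: SimulationConfig,
    ref: CdsReference | None = None,
    sgrnas: list[SgrnaRecord] | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Build the edited cell population with allele-level ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ref is None:
        ref = random_cds(config.protein_length, rng)
    if sgrnas is None:
        sgrnas = design_tiling_sgrnas(ref)
    if not sgrnas:
        raise ValueError("no sgRNAs could be designed on the simulated CDS")
    if config.critical_residues is None:
        critical = frozenset(choose_critical_residues(ref, sgrnas, config))
    else:
        critical = frozenset(config.critical_residues)

    class_cache: dict[NtVariant | None, str] = {None: "functional"}

    def cached_class(v: NtVariant | None) -> str:
        if v not in class_cache:
            class_cache[v] = allele_class(v, ref, critical)
        return class_cache[v]

    guide_eff = guide_efficiencies(config, len(sgrnas))
    guide_idx = rng.integers(len(sgrnas), size=config.n_cells)
    edited = rng.random((config.n_cells, config.ploidy)) < guide_eff[guide_idx][:, None]
    cells: list[Cell] = []
    n_dead = 0
    for i in range(config.n_cells):
        cut = sgrnas[guide_idx[i]].cut_site
        alleles = []
        for a in range(config.ploidy):
            variant = _draw_edit(rng, cut, ref, config) if edited[i, a] else None
            alleles.append(Allele(variant=variant, cls=cached_class(variant)))
        resistant = classify_resistance([al.cls for al in alleles], config)
        if resistant is None:
            n_dead += 1
            continue
        cells.append(Cell(sgrna_index=int(guide_idx[i]), alleles=tuple(alleles), resistant=resistant))
    return TruthTable(
        ref=ref, sgrnas=sgrnas, cells=cells, critical_residues=critical, n_dead=n_dead
    )


# ---------------------------------------------------------------------------
# read sampling


def _cell_weights(truth: TruthTable, config: SimulationConfig, condition: str) -> np.ndarray:
    n = len(truth.cells)
    if condition == "before":
        return np.full(n, 1.0 / n)
    if condition == "after":
        w = np.array(
            [config.enrichment if c.resistant else 1.0 for c in truth.cells], dtype=float
        )
        return w / w.sum()
    raise ValueError(f"unknown condition {condition!r}")


def _allowed_alleles(cell: Cell, config: SimulationConfig, condition: str) -> tuple[int, ...]:
    if condition == "after" and config.gene_essential:
        allowed = tuple(i for i, al in enumerate(cell.alleles) if al.cls != "null")
        if allowed:
            return allowed
    return tuple(range(len(cell.alleles)))


def _mutant_sequence(ref_seq: str, v: NtVariant | None) -> str:
    if v is None:
        return ref_seq
    return ref_seq[: v.ref_start] + v.alt + ref_seq[v.ref_end :]


def _fragment_alignment(
    v: NtVariant | None, a: int, b: int
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Truth alignment (cds_start, cigar) for mutant-coordinate slice [a, b)."""
    flen = b - a
    if v is None or v.kind == "substitution":
        return a, (("M", flen),)
    if v.kind == "deletion":
        vs = v.ref_start  # junction position, same in mutant coords
        if b <= vs:
            return a, (("M", flen),)
        if a >= vs:
            return a + v.ref_length, (("M", flen),)
        return a, (("M", vs - a), ("D", v.ref_length), ("M", b - vs))
    # insertion
    vs, ve = v.ref_start, v.ref_start + len(v.alt)
    if b <= vs:
        return a, (("M", flen),)
    if a >= ve:
        return a - len(v.alt), (("M", flen),)
    left = max(vs - a, 0)
    inside = min(b, ve) - max(a, vs)
    right = max(b - ve, 0)
    ops: list[tuple[str, int]] = []
    if left:
        ops.append(("M", left))
    if inside:
        # an insertion flush with an alignment end is a soft clip, not I
        ops.append(("I" if left and right else "S", inside))
    if right:
        ops.append(("M", right))
    start = a if left else v.ref_start
    if not left and not right:  # fragment entirely inside the insertion
        return v.ref_start, (("S", flen),)
    return start, tuple(ops)


_QUAL_CACHE: dict[int, bytes] = {}


def _quals(n: int) -> bytes:
    q = _QUAL_CACHE.get(n)
    if q is None:
        q = _QUAL_CACHE[n] = bytes([37]) * n
    return q


def simulate_fragments(
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    depth: int | None = None,
) -> list[AlignedFragment]:
    """Sample ``depth`` aligned cDNA fragments for one condition.

    ``mock`` draws pure wild-type transcripts (sequencing error only); the
    other conditions draw a cell (selection-weighted for ``after``), then an
    allele, then a uniformly placed fragment of Normal(mean, sd) length.

    The sequenced amplicon extends past the CDS (primers sit in UTR
    sequence), so fragments may overhang either CDS end; the overhanging
    bases carry no CDS information and are trimmed from the emitted
    alignment.  This keeps full-codon coverage uniform across the protein,
    including the terminal residues.
    """
    if depth is None:
        depth = config.depth
    ref_seq = truth.ref.sequence
    L = len(ref_seq)

    if condition == "mock":
        cell_idx = np.full(depth, -1)
    else:
        weights = _cell_weights(truth, config, condition)
        cell_idx = rng.choice(len(truth.cells), size=depth, p=weights)

    flens = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=depth)
    ).astype(np.int64)
    np.clip(flens, 30, None, out=flens)
    start_u = rng.random(depth)
    allele_u = rng.integers(0, 1 << 30, size=depth)
    err_counts = rng.binomial(flens, config.seq_error_rate)
    n_err = int(err_counts.sum())
    err_pos_u = rng.random(n_err)
    err_base = rng.integers(0, 3, size=n_err)

    # per-allele caches
    mut_cache: dict[NtVariant | None, str] = {}

    cells = truth.cells
    out: list[AlignedFragment] = []
    e = 0  # error pool cursor
    cell_idx_l = cell_idx.tolist()
    flens_l = flens.tolist()
    start_u_l = start_u.tolist()
    allele_u_l = allele_u.tolist()
    err_counts_l = err_counts.tolist()
    err_pos_l = err_pos_u.tolist()
    err_base_l = err_base.tolist()

    for i in range(depth):
        ci = cell_idx_l[i]
        if ci < 0:
            variant = None
        else:
            cell = cells[ci]
            allowed = _allowed_alleles(cell, config, condition)
            variant = cell.alleles[allowed[allele_u_l[i] % len(allowed)]].variant
        mut = mut_cache.get(variant)
        if mut is None:
            mut = mut_cache[variant] = _mutant_sequence(ref_seq, variant)
        tlen = len(mut)
        nominal = flens_l[i]
        # fragment start over the UTR-extended amplicon, then trimmed to the
        # CDS; a minimum 30 nt overlap keeps every read informative
        a = int(start_u_l[i] * (tlen + nominal - 60 + 1)) - (nominal - 30)
        b = min(a + nominal, tlen)
        a = max(a, 0)
        flen = b - a
        qseq = mut[a:b]
        k = err_counts_l[i]
        if k:
            # error counts were drawn at the nominal length; thinning the
            # uniform positions to the trimmed length keeps the per-base rate
            chars = list(qseq)
            changed = False
            for _ in range(k):
                pos = int(err_pos_l[e] * nominal)
                if pos < flen:
                    base = chars[pos]
                    repl = _BASES[err_base_l[e]]
                    if repl == base:  # pick the next base to guarantee a change
                        repl = _BASES[(err_base_l[e] + 1) % 4]
                    chars[pos] = repl
                    changed = True
                e += 1
            if changed:
                qseq = "".join(chars)
        cds_start, cigar = _fragment_alignment(variant, a, b)
        out.append(
            AlignedFragment(
                read_id=f"{condition}.{i}",
                cds_start=cds_start,
                cigar=cigar,
                query_seq=qseq,
                base_qualities=_quals(flen),
            )
        )
    return out


def simulate_barcode_reads(
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    n_reads: int,
    rng: np.random.Generator,
    flank5: str = "TTGTGGAAAGGACGAAACACCG",
    flank3: str = "GTTTTAGAGCTAGAAATAGCAAG",
) -> list[str]:
    """sgRNA barcode reads: vector flank + integrated spacer + scaffold flank."""
    weights = _cell_weights(truth, config, condition)
    cell_idx = rng.choice(len(truth.cells), size=n_reads, p=weights)
    return [
        flank5 + truth.sgrnas[truth.cells[ci].sgrna_index].spacer + flank3
        for ci in cell_idx.tolist()
    ]


def simulate_screen(
    config: SimulationConfig,
    conditions: Iterable[str] = ("before", "after"),
) -> SimulatedScreen:
    """Population plus fragment sets for the requested conditions."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_population(config, rng=rng)
    screen = SimulatedScreen(config=config, ref=truth.ref, sgrnas=truth.sgrnas, truth=truth)
    for condition in conditions:
        screen.fragments[condition] = simulate_fragments(truth, config, condition, rng)
    return screen


def simulate_replicate_screens(
    config: SimulationConfig,
    n_replicates: int = 2,
    conditions: Iterable[str] = ("before", "after"),
) -> list[SimulatedScreen]:
    """Independent replicate screens of the same gene and sgRNA library.

    The CDS, library and planted critical residues are fixed by
    ``config.seed``; each replicate then grows and sequences its own cell
    population (the screening protocol this models runs two replicate
    selections per treatment).
    """
    setup_rng = np.random.default_rng(config.seed)
    ref = random_cds(config.protein_length, setup_rng)
    sgrnas = design_tiling_sgrnas(ref)
    screens = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, rep + 1])
        truth = simulate_population(config, ref=ref, sgrnas=sgrnas, rng=rng)
        screen = SimulatedScreen(config=config, ref=ref, sgrnas=sgrnas, truth=truth)
        for condition in conditions:
            screen.fragments[condition] = simulate_fragments(truth, config, condition, rng)
        screens.append(screen)
    return screens


# ---------------------------------------------------------------------------
# file output


def _write_sam(path: Path, ref: CdsReference, fragments: Iterable[AlignedFragment]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.gene_id, "LN": len(ref.sequence)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in fragments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = frag.read_id
            rec.query_sequence = frag.query_seq
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = frag.cds_start
            rec.mapping_quality = 60
            rec.cigarstring = "".join(f"{n}{op}" for op, n in frag.cigar)
            if frag.base_qualities is not None:
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in frag.base_qualities)
                )
            out.write(rec)


def _write_fastq(path: Path, reads: Iterable[tuple[str, str, bytes | None]]) -> None:
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            qual = "".join(chr(q + 33) for q in quals) if quals else "I" * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def _write_truth(path: Path, truth: TruthTable) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tsgrna_index\tallele\tvariant\tclass\tresistant\n")
        for i, cell in enumerate(truth.cells):
            for a, allele in enumerate(cell.alleles):
                v = allele.variant
                vs = f"{v.kind}@{v.ref_start}:{v.ref_length}:{v.alt}" if v else "."
                fh.write(f"{i}\t{cell.sgrna_index}\t{a}\t{vs}\t{allele.cls}\t{int(cell.resistant)}\n")


def write_outputs(
    screen: SimulatedScreen,
    outdir: str | Path,
    barcode_reads: int = 0,
) -> dict[str, Path]:
    """Write FASTA, library TSV, SAM+FASTQ per condition and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, truth, config = screen.ref, screen.truth, screen.config
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / f"{ref.gene_id}.fasta"
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{ref.gene_id}\n{ref.sequence}\n")

    paths["library"] = outdir / "sgrna_library.tsv"
    write_library(screen.sgrnas, ref, paths["library"])

    for condition, frags in screen.fragments.items():
        sam = outdir / f"{condition}.sam"
        fastq = outdir / f"{condition}.fastq"
        _write_sam(sam, ref, frags)
        _write_fastq(fastq, ((f.read_id, f.query_seq, f.base_qualities) for f in frags))
        paths[f"sam_{condition}"] = sam
        paths[f"fastq_{condition}"] = fastq

    if barcode_reads:
        rng = np.random.default_rng(config.seed + 1)
        for condition in ("before", "after"):
            reads = simulate_barcode_reads(truth, config, condition, barcode_reads, rng)
            path = outdir / f"barcodes_{condition}.fastq"
            _write_fastq(path, ((f"bc.{condition}.{i}", s, None) for i, s in enumerate(reads)))
            paths[f"barcodes_{condition}"] = path

    paths["truth"] = outdir / "truth.tsv"
    _write_truth(paths["truth"], truth)

    paths["config"] = outdir / "config.yaml"
    cfg = dataclasses.asdict(config)
    cfg["critical_residues"] = sorted(truth.critical_residues)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
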