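"""End-to-end screen analysis: call reads, quantify, score, report.

``analyze_screen`` is the library entry point used by the CLI, the test
suite and the acceptance script: it takes called read sets for the before
and after libraries and returns the per-residue score table plus all
intermediate tables and per-stage read accounting.

Out-of-frame reads are filtered out before any frequency is computed, so
coverage denominators are taken over the frame-acceptable read pool
(wild-type, substitution-only and in-frame-indel reads).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .extraction import AaEffect, AlignedFragment, SamStats, call_fragment, quality_filter, read_sam
from .quantify import FragmentPool, aa_coverage, effect_frequencies, substitution_frequency
from .reference import CdsReference, load_cds
from .scoring import (
    aggregate_combo_fc,
    aggregate_deletion_fc,
    essential_scores,
    fold_changes,
    score_cutoff,
    substitution_cutoff,
)

__all__ = [
    "ScreenParams",
    "CallSet",
    "ScreenResult",
    "call_fragments",
    "analyze_screen",
    "analyze_gene",
    "CombinedScores",
    "combine_replicate_scores",
    "RunConfig",
    "GeneConfig",
    "run_pipeline",
    "render_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the scoring pipeline (defaults follow the workflow's
    printed values: Q30 read filter, count>=9 for scoring, count>=5 for the
    mutagenesis-variety profile, mutations spanning at most 3 residues)."""

    min_mean_q: float = 30.0
    quality_mode: str = "mean"
    min_count_scoring: int = 9
    min_count_variety: int = 5
    max_affected: int = 3
    w: float = 1.0
    k_sd: float = 3.0
    sub_k_sd: float = 3.0


@dataclass
class CallSet:
    """Frame-acceptable read pool for one condition, with per-read effects."""

    pool: FragmentPool
    effects: list[AaEffect]
    calls: list[tuple[tuple[int, int], AaEffect | None]]
    accounting: dict[str, int] = field(default_factory=dict)


def call_fragments(
    fragments: Iterable[AlignedFragment], ref: CdsReference, params: ScreenParams = ScreenParams()
) -> CallSet:
    """Quality-filter, frame-classify and effect-call a fragment stream."""
    spans: list[tuple[int, int]] = []
    effects: list[AaEffect] = []
    calls: list[tuple[tuple[int, int], AaEffect | None]] = []
    acc = {
        "input": 0,
        "dropped_quality": 0,
        "dropped_frameshift": 0,
        "dropped_stop_gain": 0,
        "dropped_uncallable": 0,
        "used": 0,
    }
    for frag in fragments:
        acc["input"] += 1
        if not quality_filter(frag, params.min_mean_q, params.quality_mode):
            acc["dropped_quality"] += 1
            continue
        rc = call_fragment(frag, ref)
        if rc.status == "frameshift":
            acc["dropped_frameshift"] += 1
            continue
        if rc.status == "stop_gain":
            acc["dropped_stop_gain"] += 1
            continue
        if rc.status == "uncallable":
            acc["dropped_uncallable"] += 1
            continue
        acc["used"] += 1
        span = frag.ref_span
        spans.append(span)
        calls.append((span, rc.effect))
        if rc.effect is not None:
            effects.append(rc.effect)
    return CallSet(
        pool=FragmentPool.from_spans(spans), effects=effects, calls=calls, accounting=acc
    )


@dataclass
class ScreenResult:
    scores: pd.DataFrame
    cutoff: float
    hits: list[int]
    before_table: pd.DataFrame
    after_table: pd.DataFrame
    fold_changes: pd.DataFrame
    freq_sub: pd.Series
    sub_cutoff: float
    coverage_fraction: float
    accounting: dict[str, dict[str, int]]


def _as_callset(obj, ref: CdsReference, params: ScreenParams) -> CallSet:
    return obj if isinstance(obj, CallSet) else call_fragments(obj, ref, params)


def analyze_screen(
    ref: CdsReference,
    before,
    after,
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Score every residue from before/after read sets.

    ``before``/``after`` may be fragment iterables or pre-built
    :class:`CallSet` objects.  Substitution frequencies are taken from the
    after-selection library (the pre-selection substitution signal is not
    distinguishable from sequencing error, so substitutions are assessed
    qualitatively against the after-library noise threshold).
    """
    before = _as_callset(before, ref, params)
    after = _as_callset(after, ref, params)
    n = ref.protein_length

    before_table = effect_frequencies(
        before.effects, before.pool, min_count=params.min_count_scoring
    )
    after_table = effect_frequencies(
        after.effects, after.pool, min_count=params.min_count_scoring
    )
    fcs = fold_changes(before_table, after_table)
    dfc_aa = aggregate_deletion_fc(fcs, n, w=params.w, max_affected=params.max_affected)
    cmfc_aa = aggregate_combo_fc(fcs, n, max_affected=params.max_affected)

    freq_sub = substitution_frequency(
        after.effects, after.pool, ref, min_count=params.min_count_scoring
    )
    sub_cut, sf = substitution_cutoff(freq_sub, k_sd=params.sub_k_sd)

    scores = essential_scores(dfc_aa, cmfc_aa, sf, freq_sub=freq_sub, ref=ref)
    cutoff, hits = score_cutoff(scores, k_sd=params.k_sd)
    scores["above_cutoff"] = scores["essential_score"] > cutoff
    coverage, _ = aa_coverage(before_table, n, max_affected=params.max_affected)
    return ScreenResult(
        scores=scores,
        cutoff=cutoff,
        hits=hits,
        before_table=before_table,
        after_table=after_table,
        fold_changes=fcs,
        freq_sub=freq_sub,
        sub_cutoff=sub_cut,
        coverage_fraction=coverage,
        accounting={"before": before.accounting, "after": after.accounting},
    )


@dataclass
class CombinedScores:
    """Replicate-averaged per-residue scores (the screening protocol this
    models runs two replicate selections; per-residue essential scores are
    averaged across replicates before ranking)."""

    scores: pd.DataFrame
    cutoff: float
    hits: list[int]


def combine_replicate_scores(results: list[ScreenResult], k_sd: float = 3.0) -> CombinedScores:
    if not results:
        raise ValueError("no replicate results to combine")
    base = results[0].scores
    stacked = np.vstack([r.scores["essential_score"].to_numpy(dtype=float) for r in results])
    mean_scores = stacked.mean(axis=0)
    n = len(mean_scores)
    order = sorted(range(n), key=lambda i: (-mean_scores[i], i))
    rank = np.empty(n, dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    combined = pd.DataFrame({"residue": base["residue"], "essential_score": mean_scores, "rank": rank})
    if "ref_aa" in base.columns:
        combined.insert(1, "ref_aa", base["ref_aa"])
    cutoff, hits = score_cutoff(combined, k_sd=k_sd)
    combined["above_cutoff"] = combined["essential_score"] > cutoff
    return CombinedScores(scores=combined, cutoff=cutoff, hits=hits)


# ---------------------------------------------------------------------------
# configured pipeline


@dataclass
class GeneConfig:
    gene_id: str
    fasta: Path
    sam_before: Path
    sam_after: Path
    sam_mock: Path | None = None
    amplicon_offset: int = 0


@dataclass
class RunConfig:
    genes: list[GeneConfig]
    params: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0
    outdir: Path = Path("pastmus_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "genes" not in raw:
            raise ValueError(f"{path}: config must define a 'genes' list")
        genes = []
        for entry in raw["genes"]:
            for required in ("gene_id", "fasta", "sam_before", "sam_after"):
                if required not in entry:
                    raise ValueError(
                        f"{path}: gene entry missing required field {required!r}"
                    )
            genes.append(
                GeneConfig(
                    gene_id=entry["gene_id"],
                    fasta=Path(entry["fasta"]),
                    sam_before=Path(entry["sam_before"]),
                    sam_after=Path(entry["sam_after"]),
                    sam_mock=Path(entry["sam_mock"]) if entry.get("sam_mock") else None,
                    amplicon_offset=int(entry.get("amplicon_offset", 0)),
                )
            )
        thresholds = raw.get("thresholds", {})
        params = ScreenParams(**thresholds)
        config = cls(
            genes=genes,
            params=params,
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "pastmus_out")),
        )
        config.validate()
        return config

    def validate(self) -> None:
        for gene in self.genes:
            for name in ("fasta", "sam_before", "sam_after", "sam_mock"):
                path = getattr(gene, name)
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"gene {gene.gene_id}: {name} not found: {path}")
        for name in ("min_count_scoring", "min_count_variety", "max_affected"):
            if getattr(self.params, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def analyze_gene(gene: GeneConfig, params: ScreenParams) -> ScreenResult:
    ref = load_cds(gene.fasta, gene_id=gene.gene_id)
    stats_before, stats_after = SamStats(), SamStats()
    before = call_fragments(
        read_sam(gene.sam_before, ref, offset=gene.amplicon_offset, stats=stats_before),
        ref,
        params,
    )
    after = call_fragments(
        read_sam(gene.sam_after, ref, offset=gene.amplicon_offset, stats=stats_after),
        ref,
        params,
    )
    before.accounting["skipped_unmapped"] = stats_before.skipped_unmapped
    after.accounting["skipped_unmapped"] = stats_after.skipped_unmapped
    return analyze_screen(ref, before, after, params)


def run_pipeline(config: RunConfig) -> dict[str, ScreenResult]:
    """Run every configured gene; failures abort that gene but not the run."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ScreenResult] = {}
    failures: dict[str, str] = {}
    manifest: dict = {
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.params),
        "genes": {},
    }
    for gene in config.genes:
        try:
            result = analyze_gene(gene, config.params)
        except Exception as exc:  # keep processing the other genes
            logger.error("gene %s failed: %s", gene.gene_id, exc)
            failures[gene.gene_id] = str(exc)
            continue
        results[gene.gene_id] = result
        score_path = outdir / f"{gene.gene_id}.scores.tsv"
        result.scores.to_csv(score_path, sep="\t", index=False, float_format="%.6g")
        result.before_table.to_csv(
            outdir / f"{gene.gene_id}.effects_before.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.after_table.to_csv(
            outdir / f"{gene.gene_id}.effects_after.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["genes"][gene.gene_id] = {
            "score_tsv": score_path.name,
            "score_cutoff": result.cutoff,
            "substitution_cutoff_log10": None
            if np.isnan(result.sub_cutoff)
            else result.sub_cutoff,
            "hits": result.hits,
            "aa_coverage": result.coverage_fraction,
            "accounting": result.accounting,
        }
    manifest["failed"] = failures
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failures:
        raise RuntimeError(f"{len(failures)} gene(s) failed: {sorted(failures)}")
    return results


def render_map(
    scores: pd.DataFrame | str | Path,
    out_prefix: str | Path | None = None,
    plot: bool = False,
) -> pd.DataFrame:
    """Per-residue linear map track (scores + cutoff flag), optionally plotted."""
    if not isinstance(scores, pd.DataFrame):
        scores = pd.read_csv(scores, sep="\t")
    if scores.empty:
        raise ValueError("empty score table")
    cutoff, _ = score_cutoff(scores)
    columns = [
        c
        for c in ("residue", "ref_aa", "dfc_aa", "cmfc_aa", "freq_sub", "sf_score", "essential_score")
        if c in scores.columns
    ]
    track = scores[columns].copy()
    track["above_cutoff"] = scores["essential_score"] > cutoff
    if out_prefix is not None:
        track.to_csv(f"{out_prefix}.track.tsv", sep="\t", index=False, float_format="%.6g")
    if plot and out_prefix is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 1, figsize=(10, 6), sharex=True)
        axes[0].bar(track["residue"], track["dfc_aa"], color="#3b6fb6")
        axes[0].set_ylabel("dfc")
        axes[1].bar(track["residue"], track["cmfc_aa"], color="#7b4fa6")
        axes[1].set_ylabel("cmfc")
        axes[2].bar(track["residue"], track["essential_score"], color="#444444")
        axes[2].axhline(cutoff, linestyle="--", color="red", linewidth=1)
        axes[2].set_ylabel("essential score")
        axes[2].set_xlabel("residue")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}.map.png", dpi=150)
        plt.close(fig)
    return track
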