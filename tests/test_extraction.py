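"""CIGAR-level variant extraction, frame classification and effect translation."""

import numpy as np
import pytest

from pastmus.extraction import (
    AlignedFragment,
    NtVariant,
    SamStats,
    UncoveredVariantError,
    call_fragment,
    classify_frame,
    extract_nt_variants,
    mutagenesis_window_profile,
    quality_filter,
    read_sam,
    translate_effect,
)
from pastmus.reference import CdsReference

from conftest import random_cds_protein


def frag(cds_start, cigar, query, quals=40, read_id="r1"):
    q = bytes([quals]) * len(query) if isinstance(quals, int) else bytes(quals)
    return AlignedFragment(read_id=read_id, cds_start=cds_start, cigar=tuple(cigar), query_seq=query, base_qualities=q)


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:toy\tLN:12\n"


class TestReadSam:
    def test_identity_alignment_and_skips(self, tmp_path, toy_ref):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + "r1\t0\ttoy\t1\t60\t12M\t*\t0\t0\tATGGCTGGTTAA\tIIIIIIIIIIII\n"
            + "r2\t4\t*\t0\t0\t*\t*\t0\t0\tATGGCTGGTTAA\tIIIIIIIIIIII\n"
            + "r3\t0\ttoy\t1\t60\t5M3D7M\t*\t0\t0\tATGGCGGTTAAA\tIIIIIIIIIIII\n"
        )
        stats = SamStats()
        frags = list(read_sam(sam, toy_ref, stats=stats))
        assert [f.read_id for f in frags] == ["r1", "r3"]
        assert frags[0].cds_start == 0  # SAM POS is 1-based
        assert frags[0].cigar == (("M", 12),)
        assert frags[1].cigar == (("M", 5), ("D", 3), ("M", 7))
        assert frags[1].ref_span == (0, 15)
        assert stats.skipped_unmapped == 1
        assert stats.used == 2

    def test_reference_name_mismatch_is_hard_error(self, tmp_path, toy_ref):
        sam = tmp_path / "b.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:12\n")
        with pytest.raises(ValueError, match="other"):
            list(read_sam(sam, toy_ref))


class TestQualityFilter:
    @pytest.mark.parametrize(
        "quals,keep",
        [
            (bytes([40]) * 10, True),
            (bytes([20]) * 10, False),
            (bytes([40] * 5 + [22] * 5), True),  # mean 31 >= 30
        ],
    )
    def test_mean_mode(self, quals, keep):
        f = frag(0, [("M", 10)], "A" * 10, quals=quals)
        assert quality_filter(f, 30) is keep

    def test_min_mode_requires_every_base(self):
        f = frag(0, [("M", 4)], "ACGT", quals=bytes([40, 40, 29, 40]))
        assert quality_filter(f, 30, mode="min") is False
        assert quality_filter(f, 30, mode="mean") is True

    def test_missing_qualities_pass(self):
        f = AlignedFragment("r", 0, (("M", 4),), "ACGT", None)
        assert quality_filter(f, 30) is True


class TestExtractVariants:
    def test_perfect_match_has_no_variants(self, toy_ref):
        ref2 = random_cds_protein(8, seed=1)
        f = frag(0, [("M", 24)], ref2.sequence)
        assert extract_nt_variants(f, ref2) == []

    def test_single_deletion(self, toy_ref):
        # toy CDS ATGGCTGGTTAA: 6M3D3M from 0 removes [6, 9)
        f = frag(0, [("M", 6), ("D", 3), ("M", 3)], "ATGGCT" + "TAA")
        assert extract_nt_variants(f, toy_ref) == [NtVariant("deletion", 6, 3, "")]

    def test_single_mismatch_in_m_block(self, toy_ref):
        query = "ATGGATGGTTAA"  # position 4 C->A
        f = frag(0, [("M", 12)], query)
        assert extract_nt_variants(f, toy_ref) == [NtVariant("substitution", 4, 1, "A")]

    def test_consecutive_mismatches_merge(self, toy_ref):
        query = "ATGGAAGGTTAA"  # positions 4-5 CT->AA
        f = frag(0, [("M", 12)], query)
        assert extract_nt_variants(f, toy_ref) == [NtVariant("substitution", 4, 2, "AA")]

    def test_insertion_and_softclip(self, toy_ref):
        f = frag(0, [("S", 2), ("M", 3), ("I", 2), ("M", 9)], "GG" + "ATG" + "CC" + "GCTGGTTAA")
        assert extract_nt_variants(f, toy_ref) == [NtVariant("insertion", 3, 0, "CC")]

    def test_unsupported_cigar_op_rejected(self, toy_ref):
        f = frag(0, [("M", 3), ("N", 3), ("M", 3)], "ATGGCT")
        with pytest.raises(ValueError, match="CIGAR"):
            extract_nt_variants(f, toy_ref)


class TestClassifyFrame:
    @pytest.mark.parametrize("length", range(1, 13))
    def test_single_deletion_lengths_exhaustive(self, length):
        cls = classify_frame([NtVariant("deletion", 0, length, "")])
        assert cls == ("in_frame_indel" if length % 3 == 0 else "frameshift")

    @pytest.mark.parametrize("length", range(1, 13))
    def test_single_insertion_lengths_exhaustive(self, length):
        cls = classify_frame([NtVariant("insertion", 0, 0, "A" * length)])
        assert cls == ("in_frame_indel" if length % 3 == 0 else "frameshift")

    def test_net_of_mixed_indels(self):
        # net = +2 - 4 = -2 -> frameshift
        variants = [NtVariant("deletion", 0, 4, ""), NtVariant("insertion", 10, 0, "AA")]
        assert classify_frame(variants) == "frameshift"

    def test_substitutions_only_and_empty(self):
        assert classify_frame([NtVariant("substitution", 3, 1, "A")]) == "sub_only"
        assert classify_frame([]) == "wildtype"


class TestTranslateEffect:
    def test_codon_aligned_deletion(self, toy_ref):
        eff = translate_effect([NtVariant("deletion", 3, 3, "")], toy_ref)
        assert (eff.category, eff.residue_start, eff.affected_length, eff.alt_residues) == (
            "aa_deletion",
            2,
            1,
            "",
        )

    def test_cross_codon_deletion_gives_combo(self, mkp_ref):
        # M K P * ; deleting nt [4, 7) leaves ATG ACC TAA = M T *
        eff = translate_effect([NtVariant("deletion", 4, 3, "")], mkp_ref)
        assert (eff.category, eff.residue_start, eff.affected_length, eff.alt_residues) == (
            "combo",
            2,
            2,
            "T",
        )

    def test_missense_substitution(self, toy_ref):
        eff = translate_effect([NtVariant("substitution", 4, 1, "A")], toy_ref)
        assert (eff.category, eff.residue_start, eff.affected_length, eff.alt_residues) == (
            "substitution",
            2,
            1,
            "D",
        )

    def test_silent_substitution(self, toy_ref):
        # GCT -> GCC, both alanine
        eff = translate_effect([NtVariant("substitution", 5, 1, "C")], toy_ref)
        assert eff.category == "silent"

    def test_in_frame_insertion_is_combo(self, toy_ref):
        eff = translate_effect([NtVariant("insertion", 6, 0, "AAA")], toy_ref)
        assert eff.category == "combo"
        assert eff.has_insertion

    def test_fragment_not_covering_window_raises(self, toy_ref):
        with pytest.raises(UncoveredVariantError):
            translate_effect([NtVariant("deletion", 3, 3, "")], toy_ref, frag_span=(4, 12))

    def test_frameshift_set_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            translate_effect([NtVariant("deletion", 3, 4, "")], toy_ref)

    def test_padding_idempotence(self):
        """Extending a fragment with matching flanks never changes the call.

        A fragment too short to anchor the canonical window (repeat run at
        the read edge) is rejected rather than called differently.
        """
        ref = random_cds_protein(60, seed=3)
        rng = np.random.default_rng(3)
        compared = 0
        for _ in range(50):
            pos = int(rng.integers(30, 120))
            d = int(rng.choice([3, 6]))
            v = NtVariant("deletion", pos, d, "")
            wide = translate_effect([v], ref, frag_span=(0, len(ref.sequence)))
            try:
                narrow = translate_effect([v], ref, frag_span=(pos - 12, pos + d + 12))
            except UncoveredVariantError:
                continue
            assert narrow.key == wide.key
            compared += 1
        assert compared >= 40

    def test_footprint_anchored_to_variant_window(self):
        """The canonical footprint starts inside the variant's codon window,
        never grows beyond the variant's residue span, and only shifts right
        (repeat-run canonicalization), never left."""
        ref = random_cds_protein(80, seed=4)
        rng = np.random.default_rng(4)
        for _ in range(100):
            pos = int(rng.integers(6, 200))
            d = int(rng.choice([3, 6, 9]))
            eff = translate_effect([NtVariant("deletion", pos, d, "")], ref)
            ws = (pos // 3) * 3
            a, b = eff.footprint
            if eff.category == "silent":
                continue
            assert a >= ws
            assert eff.affected_length <= d // 3 + 1
            assert b <= len(ref.sequence)


class TestCallFragment:
    def test_wildtype_fast_path(self, toy_ref):
        rc = call_fragment(frag(0, [("M", 12)], toy_ref.sequence), toy_ref)
        assert rc.status == "wildtype" and rc.effect is None

    def test_frameshift_filtered(self, toy_ref):
        rc = call_fragment(frag(0, [("M", 4), ("D", 4), ("M", 4)], "ATGG" + "TTAA"), toy_ref)
        assert rc.status == "frameshift"

    def test_stop_gain_substitution_filtered(self, mkp_ref):
        # AAA -> TAA at residue 2 creates a premature stop
        rc = call_fragment(frag(0, [("M", 12)], "ATGTAACCCTAA"), mkp_ref)
        assert rc.status == "stop_gain"


class TestWindowProfile:
    def make_reads(self, ref, n_wt, n_del, del_pos=30):
        out = [frag(0, [("M", 90)], ref.sequence[:90], read_id=f"wt{i}") for i in range(n_wt)]
        q = ref.sequence[:del_pos] + ref.sequence[del_pos + 3 : 90]
        out += [
            frag(0, [("M", del_pos), ("D", 3), ("M", 90 - del_pos - 3)], q, read_id=f"d{i}")
            for i in range(n_del)
        ]
        return out

    def test_all_wildtype_gives_empty_profile(self):
        ref = random_cds_protein(40, seed=5)
        table = mutagenesis_window_profile(self.make_reads(ref, 10, 0), ref, cut_site=30)
        assert table.empty

    def test_single_signature_counted(self):
        ref = random_cds_protein(40, seed=5)
        table = mutagenesis_window_profile(self.make_reads(ref, 0, 100), ref, cut_site=30)
        assert len(table) == 1
        assert table.loc[0, "count"] == 100
        assert bool(table.loc[0, "in_frame"])

    def test_min_count_threshold(self):
        ref = random_cds_protein(40, seed=5)
        reads = self.make_reads(ref, 0, 6, del_pos=30) + self.make_reads(ref, 0, 4, del_pos=33)
        table = mutagenesis_window_profile(reads, ref, cut_site=30, min_count=5)
        assert len(table) == 1
        assert table.loc[0, "count"] == 6

    def test_variants_outside_window_ignored(self):
        ref = random_cds_protein(40, seed=5)
        reads = self.make_reads(ref, 0, 10, del_pos=60)
        table = mutagenesis_window_profile(reads, ref, cut_site=10, window_nt=20)
        assert table.empty
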