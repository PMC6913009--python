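"""Synthetic screen generator: genotype rules, sampling and file round trips."""

import itertools

import numpy as np
import pytest

from pastmus.extraction import NtVariant, read_sam
from pastmus.pipeline import call_fragments
from pastmus.quantify import effect_frequencies
from pastmus.simulate import (
    SimulationConfig,
    allele_class,
    classify_resistance,
    random_cds,
    simulate_fragments,
    simulate_population,
    simulate_screen,
    write_outputs,
)

SMALL = dict(protein_length=80, n_cells=2000, depth=20_000, n_critical=3)


def small_config(**kw):
    merged = {**SMALL, **kw}
    return SimulationConfig(**merged)


def oracle_resistant(classes, inheritance, essential):
    """Independent statement of the genotype->phenotype rules."""
    if inheritance == "dominant":
        return any(c == "function_altering" for c in classes)
    if essential and all(c == "null" for c in classes):
        return None  # cell death
    # recessive loss of function: no functional allele may remain
    return not any(c == "functional" for c in classes)


class TestResistanceRules:
    @pytest.mark.parametrize("ploidy", [1, 2, 3])
    @pytest.mark.parametrize("inheritance", ["recessive", "dominant"])
    @pytest.mark.parametrize("essential", [False, True])
    def test_exhaustive_genotype_enumeration(self, ploidy, inheritance, essential):
        config = small_config(
            ploidy=ploidy, inheritance=inheritance, gene_essential=essential
        )
        states = ["functional", "function_altering", "null"]
        for classes in itertools.product(states, repeat=ploidy):
            assert classify_resistance(list(classes), config) == oracle_resistant(
                classes, inheritance, essential
            )

    def test_spec_cases(self):
        recessive = small_config()
        dominant = small_config(inheritance="dominant")
        essential = small_config(gene_essential=True)
        assert classify_resistance(["null"], small_config(ploidy=1)) is True
        assert classify_resistance(["function_altering", "null"], recessive) is True
        assert classify_resistance(["functional", "functional"], recessive) is False
        assert classify_resistance(["function_altering", "functional"], recessive) is False
        assert classify_resistance(["function_altering", "functional"], dominant) is True
        assert classify_resistance(["null", "null"], essential) is None


class TestAlleleClass:
    def setup_method(self):
        rng = np.random.default_rng(31)
        self.ref = random_cds(60, rng)
        self.critical = frozenset({10})

    def test_wildtype_is_functional(self):
        assert allele_class(None, self.ref, self.critical) == "functional"

    def test_frameshift_is_null(self):
        v = NtVariant("deletion", 30, 4, "")
        assert allele_class(v, self.ref, self.critical) == "null"

    def test_inframe_deletion_at_critical_is_function_altering(self):
        v = NtVariant("deletion", 27, 3, "")  # codon 10 = nt [27, 30)
        assert allele_class(v, self.ref, self.critical) == "function_altering"

    def test_inframe_deletion_elsewhere_is_functional(self):
        v = NtVariant("deletion", 90, 3, "")
        assert allele_class(v, self.ref, self.critical) == "functional"

    def test_stop_gain_substitution_is_null(self):
        # find a position where a single change creates TAA
        seq = self.ref.sequence
        for codon_i in range(1, 55):
            codon = seq[3 * codon_i : 3 * codon_i + 3]
            if codon[1:] == "AA" and codon[0] != "T":
                v = NtVariant("substitution", 3 * codon_i, 1, "T")
                assert allele_class(v, self.ref, self.critical) == "null"
                return
        pytest.skip("no TAA-one-away codon in this sequence")


class TestPopulation:
    def test_edit_rate_zero_gives_wildtype_sensitive_population(self):
        truth = simulate_population(small_config(edit_rate=0.0))
        assert all(a.variant is None for c in truth.cells for a in c.alleles)
        assert not any(c.resistant for c in truth.cells)

    def test_truth_resistance_recomputable(self):
        config = small_config()
        truth = simulate_population(config)
        for cell in truth.cells:
            classes = [a.cls for a in cell.alleles]
            assert classify_resistance(classes, config) == cell.resistant

    def test_essential_gene_removes_all_null_cells(self):
        config = small_config(gene_essential=True)
        truth = simulate_population(config)
        assert truth.n_dead > 0
        assert len(truth.cells) + truth.n_dead == config.n_cells
        for cell in truth.cells:
            assert not all(a.cls == "null" for a in cell.alleles)

    def test_critical_residues_auto_planted_in_protein(self):
        config = small_config()
        truth = simulate_population(config)
        assert len(truth.critical_residues) == config.n_critical
        assert all(1 <= r <= config.protein_length for r in truth.critical_residues)


class TestSequencing:
    def test_no_edit_no_error_reads_match_reference(self):
        config = small_config(edit_rate=0.0, seq_error_rate=0.0)
        screen = simulate_screen(config, conditions=("before",))
        ref = screen.ref
        for frag in screen.fragments["before"][:500]:
            assert frag.cigar == (("M", len(frag.query_seq)),)
            assert frag.query_seq == ref.sequence[frag.cds_start : frag.cds_start + len(frag.query_seq)]

    def test_determinism_identical_outputs(self, tmp_path):
        config = small_config(depth=5000)
        p1 = write_outputs(simulate_screen(config), tmp_path / "a", barcode_reads=1000)
        p2 = write_outputs(simulate_screen(config), tmp_path / "b", barcode_reads=1000)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_sam_round_trip_preserves_calls(self, tmp_path):
        config = small_config(depth=5000)
        screen = simulate_screen(config, conditions=("before",))
        paths = write_outputs(screen, tmp_path / "rt")
        in_memory = call_fragments(screen.fragments["before"], screen.ref)
        from_sam = call_fragments(read_sam(paths["sam_before"], screen.ref), screen.ref)
        assert in_memory.accounting == from_sam.accounting
        assert [e.key for e in in_memory.effects] == [e.key for e in from_sam.effects]

    def test_no_selection_null_frequencies_agree(self):
        """With enrichment 1 the before/after frequencies of every retained key
        agree within 3 binomial standard deviations."""
        config = small_config(depth=60_000, enrichment=1.0, seed=41)
        screen = simulate_screen(config)
        ref = screen.ref
        before = call_fragments(screen.fragments["before"], ref)
        after = call_fragments(screen.fragments["after"], ref)
        tb = effect_frequencies(before.effects, before.pool, min_count=9)
        ta = effect_frequencies(after.effects, after.pool, min_count=1)
        ta_map = {
            (r.category, r.residue_start, r.affected_length, r.alt_residues): r
            for r in ta.itertuples()
        }
        checked = 0
        for row in tb.itertuples():
            key = (row.category, row.residue_start, row.affected_length, row.alt_residues)
            after_row = ta_map.get(key)
            f_after = after_row.frequency if after_row is not None else 0.0
            n_after = after_row.covering_reads if after_row is not None else row.covering_reads
            p = row.frequency
            sd = np.sqrt(p * (1 - p) * (1 / row.covering_reads + 1 / n_after))
            assert abs(f_after - p) <= 4 * max(sd, 1e-9), key
            checked += 1
        assert checked >= 5

    def test_planted_deletion_keys_enrich_under_selection(self):
        """Keys touching a planted critical residue enrich strongly relative to
        neutral in-frame keys."""
        config = SimulationConfig(seed=1)
        screen = simulate_screen(config)
        ref = screen.ref
        before = call_fragments(screen.fragments["before"], ref)
        after = call_fragments(screen.fragments["after"], ref)
        tb = effect_frequencies(before.effects, before.pool, min_count=9)
        ta = effect_frequencies(after.effects, after.pool, min_count=1)
        from pastmus.scoring import fold_changes

        fcs = fold_changes(tb, ta)
        critical = screen.truth.critical_residues
        def touches(row):
            span = range(row.residue_start, row.residue_start + max(row.affected_length, 1))
            return any(r in critical for r in span)

        crit = fcs[[touches(r) for r in fcs.itertuples()]]
        neut = fcs[[not touches(r) for r in fcs.itertuples()]]
        assert crit["fc"].max() > 5 * max(neut["fc"].median(), 1e-6)
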