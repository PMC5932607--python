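"""Channel classification, duplicate filtering and spectrum construction."""

import itertools

import numpy as np
import pytest

from mmrsig import catalog, channels as ch
from mmrsig.io import VariantRecord


def make_genome(seq, chrom="c"):
    return {chrom: seq}


class TestSubstitutionClassification:
    def test_att_context(self):
        # T>A with 5' A and 3' T lands in the A[T>A]T channel
        genome = make_genome("AATTT")
        rec = VariantRecord("S", "c", 3, "T", "A")
        idx = catalog.classify_substitution(rec, genome)
        assert ch.SUBSTITUTION_CHANNELS[idx] == "A[T>A]T"

    def test_purine_strand_collapse(self):
        # G>A in a C_T context is the reverse-complement of A[C>T]G
        genome = make_genome("ACGTA")
        rec = VariantRecord("S", "c", 3, "G", "A")
        idx = catalog.classify_substitution(rec, genome)
        assert ch.SUBSTITUTION_CHANNELS[idx] == "A[C>T]G"

    def test_all_192_descriptions_cover_96_channels_twice(self):
        """Brute-force enumeration: every (context, alt) description maps
        into the 96 channels, each hit exactly twice (once per strand)."""
        hits = np.zeros(96, dtype=int)
        for five, ref, three in itertools.product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                genome = make_genome(five + ref + three)
                idx = catalog.classify_substitution(
                    VariantRecord("S", "c", 2, ref, alt), genome
                )
                hits[idx] += 1
        assert np.array_equal(hits, np.full(96, 2))

    def test_strand_collapse_involution(self):
        # classifying a variant and its reverse-complement description agree
        rng = np.random.default_rng(0)
        for _ in range(50):
            five, ref, three = rng.choice(list("ACGT"), 3)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = catalog.classify_substitution(
                VariantRecord("S", "c", 2, ref, alt), make_genome(five + ref + three)
            )
            rc = ch.reverse_complement
            rev = catalog.classify_substitution(
                VariantRecord("S", "c", 2, rc(ref), rc(alt)),
                make_genome(rc(five + ref + three)),
            )
            assert fwd == rev

    def test_edge_and_ambiguous_context_skipped(self):
        genome = make_genome("CGT")
        assert catalog.classify_substitution(VariantRecord("S", "c", 1, "C", "T"), genome) is None
        genome_n = make_genome("NCT")
        assert catalog.classify_substitution(VariantRecord("S", "c", 2, "C", "T"), genome_n) is None

    def test_reference_mismatch_skipped(self):
        genome = make_genome("ACT")
        assert catalog.classify_substitution(VariantRecord("S", "c", 2, "G", "A"), genome) is None


class TestIndelClassification:
    def test_one_bp_deletion_base_class(self):
        genome = make_genome("GAAAAAG")
        rec = VariantRecord("S", "c", 2, "AA", "A")  # deletes one A of the run
        idx = catalog.classify_indel(rec, genome)
        assert ch.CHANNELS_104[idx] == "del1_AT"

    def test_two_bp_insertion_binned(self):
        genome = make_genome("GATTACA")
        rec = VariantRecord("S", "c", 3, "T", "TCG")
        idx = catalog.classify_indel(rec, genome)
        assert ch.CHANNELS_104[idx] == "ins_2to5"

    def test_sv_boundary(self):
        # indels are small events < 400 bp; anything longer is a structural
        # variant and is not classified
        seq = "G" + "A" * 450 + "G"
        genome = make_genome(seq)
        del399 = VariantRecord("S", "c", 1, seq[0 : 1 + 399], "G")
        assert catalog.classify_indel(del399, genome) == ch.CHANNEL_INDEX["del_gt5"]
        del400 = VariantRecord("S", "c", 1, seq[0 : 1 + 400], "G")
        assert catalog.classify_indel(del400, genome) is None

    def test_left_alignment_in_repeat(self):
        # deleting any A of a run normalizes to the run start
        genome = make_genome("GGAAAAGG")
        for pos in (3, 4, 5):
            rec = VariantRecord("S", "c", pos, genome["c"][pos - 1] + "A", genome["c"][pos - 1])
            norm = catalog.normalize_indel(rec, genome)
            assert (norm.start0, norm.kind, norm.seq) == (2, "del", "A")


class TestDedupe:
    def test_shared_substitution_removed_everywhere(self):
        recs = [
            VariantRecord("A", "chrI", 100, "C", "T"),
            VariantRecord("B", "chrI", 100, "C", "T"),
            VariantRecord("A", "chrI", 200, "G", "A"),
        ]
        kept = catalog.dedupe_shared_sites(recs)
        assert [(r.sample_id, r.pos) for r in kept] == [("A", 200)]

    def test_different_alleles_same_site_kept(self):
        recs = [
            VariantRecord("A", "chrI", 100, "C", "T"),
            VariantRecord("B", "chrI", 100, "C", "A"),
        ]
        assert len(catalog.dedupe_shared_sites(recs)) == 2

    def test_indels_keyed_by_position_only(self):
        # two different-length deletions left-aligning to the same start are
        # both removed; the substitutions rule does not apply to them
        genome = make_genome("GGAAAAAAGG")
        recs = [
            VariantRecord("A", "c", 2, "GA", "G"),
            VariantRecord("B", "c", 4, "AAA", "A"),  # left-aligns to the run start
        ]
        assert catalog.dedupe_shared_sites(recs, genome) == []

    def test_same_sample_recurrence_not_removed(self):
        recs = [
            VariantRecord("A", "chrI", 100, "C", "T"),
            VariantRecord("A", "chrI", 100, "C", "T"),
        ]
        assert len(catalog.dedupe_shared_sites(recs)) == 2

    def test_idempotent(self, rng):
        recs = [
            VariantRecord(s, "chrI", int(p), "C", "T")
            for s in "ABC"
            for p in rng.integers(10, 30, size=8)
        ]
        once = catalog.dedupe_shared_sites(recs)
        assert catalog.dedupe_shared_sites(once) == once


class TestBuildSpectrum:
    def test_empty_input_zero_vector(self, tiny_genome):
        spec = catalog.build_spectrum([], tiny_genome, sample_id="S")
        assert spec.counts.sum() == 0 and spec.counts.shape == (104,)

    def test_three_variant_fixture(self):
        #            123456789012345
        genome = make_genome("GGATTCAAAAAGCCC")
        recs = [
            VariantRecord("S", "c", 4, "T", "C"),          # A[T>C]T
            VariantRecord("S", "c", 8, "A", "AA"),         # ins1_AT
            VariantRecord("S", "c", 12, "GCC", "G"),       # del_2to5 (CC)
        ]
        spec = catalog.build_spectrum(recs, genome)
        expected = np.zeros(104, dtype=int)
        expected[ch.CHANNEL_INDEX["A[T>C]T"]] = 1
        expected[ch.CHANNEL_INDEX["ins1_AT"]] = 1
        expected[ch.CHANNEL_INDEX["del_2to5"]] = 1
        assert np.array_equal(spec.counts, expected)

    def test_additivity(self, tiny_genome, rng):
        seq = tiny_genome["chrT"]
        recs = []
        for pos in range(5, 40, 3):
            ref = seq[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            recs.append(VariantRecord("S", "chrT", pos, ref, alt))
        half = len(recs) // 2
        full = catalog.build_spectrum(recs, tiny_genome, sample_id="S").counts
        a = catalog.build_spectrum(recs[:half], tiny_genome, sample_id="S").counts
        b = catalog.build_spectrum(recs[half:], tiny_genome, sample_id="S").counts
        assert np.array_equal(full, a + b)

    def test_conservation_classified_plus_skipped(self, tiny_genome):
        recs = [
            VariantRecord("S", "chrT", 1, "G", "A"),   # context off the edge: skipped
            VariantRecord("S", "chrT", 5, "T", "C"),
        ]
        with pytest.warns(UserWarning):
            spec = catalog.build_spectrum(recs, tiny_genome, sample_id="S")
        assert spec.counts.sum() + spec.n_skipped == len(recs)
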