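"""Mutation parsing, substitution classes and consequence annotation."""

import itertools

import numpy as np
import pytest

from conftest import make_transcript
from ssmdep._seq import complement, revcomp
from ssmdep.mutations import (
    SIX_CLASSES,
    ConsequenceAnnotator,
    MutationRecord,
    all_trinucleotide_classes,
    annotate_consequence,
    canonical_substitution_class,
    filter_synonymous,
    read_mutations,
    records_to_frame,
    trinucleotide_class,
)

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tTumor_Sample_Barcode\n"
)


class TestReading:
    def test_one_based_positions_are_converted(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(MAF_HEADER + "g1\tchr1\t100\tA\tG\tSilent\tSNP\tS1\n")
        (rec,) = read_mutations(maf)
        assert rec.pos == 99
        assert rec.consequence == "synonymous"
        assert rec.gene_id == "g1"

    def test_indels_are_dropped(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(
            MAF_HEADER
            + "g1\tchr1\t100\tA\tG\tSilent\tSNP\tS1\n"
            + "g1\tchr1\t200\t-\tGG\tFrame_Shift_Ins\tINS\tS1\n"
        )
        records = read_mutations(maf)
        assert len(records) == 1

    def test_column_map_dialect_equals_maf(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(MAF_HEADER + "g1\tchr1\t100\tA\tG\tSilent\tSNP\tS1\n")
        icgc = tmp_path / "icgc.tsv"
        icgc.write_text(
            "icgc_sample_id\tchromosome\tstart\tref\talt\tconsequence_type\tgene\n"
            "S1\tchr1\t100\tA\tG\tsynonymous\tg1\n"
        )
        colmap = {
            "sample_id": "icgc_sample_id", "chrom": "chromosome", "pos": "start",
            "ref": "ref", "alt": "alt", "consequence": "consequence_type",
            "gene_id": "gene",
        }
        assert read_mutations(maf) == read_mutations(icgc, "column_map", colmap)

    def test_missing_column_is_named(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("Chromosome\tStart_Position\nchr1\t5\n")
        with pytest.raises(ValueError, match="Tumor_Sample_Barcode"):
            read_mutations(bad)

    def test_ref_checked_against_genome(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(MAF_HEADER + "g1\tchr1\t3\tA\tG\tSilent\tSNP\tS1\n")
        with pytest.raises(ValueError, match="ref"):
            read_mutations(maf, genome={"chr1": "CCCCCC"})


class TestSubstitutionClasses:
    # the full 12-substitution map, derived by hand from the reverse
    # complement collapse
    EXPECTED = {
        ("A", "C"): "A>C", ("T", "G"): "A>C",
        ("A", "G"): "A>G", ("T", "C"): "A>G",
        ("A", "T"): "A>T", ("T", "A"): "A>T",
        ("C", "G"): "C>G", ("G", "C"): "C>G",
        ("C", "T"): "C>T", ("G", "A"): "C>T",
        ("G", "T"): "G>T", ("C", "A"): "G>T",
    }

    def test_all_twelve_substitutions(self):
        for (ref, alt), expected in self.EXPECTED.items():
            assert canonical_substitution_class(ref, alt) == expected

    def test_reverse_complement_invariance(self):
        for ref, alt in self.EXPECTED:
            assert canonical_substitution_class(ref, alt) == canonical_substitution_class(
                complement(ref), complement(alt)
            )

    def test_image_has_exactly_six_labels(self):
        image = {canonical_substitution_class(r, a) for r, a in self.EXPECTED}
        assert image == set(SIX_CLASSES)

    def test_invalid_base_raises(self):
        with pytest.raises(ValueError):
            canonical_substitution_class("A", "N")


class TestTrinucleotideClasses:
    def test_canonical_substitution_reads_context_as_is(self):
        genome = {"chr1": "TACGT"}
        assert trinucleotide_class(genome, "chr1", 2, "C", "T") == "A[C>T]G"

    def test_noncanonical_substitution_is_mirrored(self):
        # genomic C[G>A]T must collapse to A[C>T]G
        genome = {"chr1": "ACGTA"}
        assert trinucleotide_class(genome, "chr1", 2, "G", "A") == "A[C>T]G"

    def test_all_96_labels_reachable(self):
        labels = set()
        for five, ref, three in itertools.product("ACGT", repeat=3):
            genome = {"chr1": "T" + five + ref + three + "T"}
            for alt in "ACGT":
                if alt != ref:
                    labels.add(trinucleotide_class(genome, "chr1", 2, ref, alt))
        assert labels == set(all_trinucleotide_classes())
        assert len(labels) == 96

    def test_contig_edge_and_n_context_raise(self):
        with pytest.raises(ValueError):
            trinucleotide_class({"chr1": "ACG"}, "chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            trinucleotide_class({"chr1": "NCGT"}, "chr1", 1, "C", "T")


def _toy_locus(strand="+"):
    """One 2-exon transcript whose CDS reads ATG GGA CTG TAA in coding order."""
    cds = "ATGGGACTGTAA"
    if strand == "+":
        genome = {"chr1": "TT" + cds[:6] + "TTTT" + cds[6:] + "TT"}
        exons = [(2, 8), (12, 18)]
    else:
        genome = {"chr1": "TT" + revcomp(cds[6:]) + "TTTT" + revcomp(cds[:6]) + "TT"}
        exons = [(2, 8), (12, 18)]
    t = make_transcript(exons, strand=strand)
    return genome, t


class TestConsequences:
    def test_fourfold_site_is_synonymous(self):
        genome, t = _toy_locus("+")
        # GGA -> GGG at codon position 3 (genome pos 7): Gly -> Gly
        rec = MutationRecord("S1", "chr1", 7, "A", "G")
        assert annotate_consequence(rec, t, genome) == "synonymous"

    def test_first_codon_position_change_is_missense(self):
        genome, t = _toy_locus("+")
        # GGA -> AGA at codon position 1 (genome pos 5): Gly -> Arg
        rec = MutationRecord("S1", "chr1", 5, "G", "A")
        assert annotate_consequence(rec, t, genome) == "non_synonymous"

    def test_minus_strand_third_position_transition(self):
        """Hand oracle through the strand mirror: coding CTG->CTA (Leu)
        via a genomic C>T on the opposite strand."""
        genome, t = _toy_locus("-")
        # coding CTG occupies coding indices 6..8 -> second exon of the
        # coding order = genomic first exon (2,8) reversed; coding index 8
        # (the G of CTG) sits at genome position 2+ (8-1-(8-6)) ... locate it:
        annotator = ConsequenceAnnotator([t], genome)
        g_of_coding = {i: (annotator.chrom[i], int(annotator.pos[i])) for i in range(annotator.n_sites)}
        # coding index 8 is the 9th coding base
        chrom, gpos = g_of_coding[8]
        ref = genome[chrom][gpos]
        assert ref == "C"  # genome strand shows the complement of coding G
        rec = MutationRecord("S1", chrom, gpos, "C", "T")
        assert annotate_consequence(rec, t, genome) == "synonymous"

    def test_position_outside_cds_is_other(self):
        genome, t = _toy_locus("+")
        rec = MutationRecord("S1", "chr1", 9, genome["chr1"][9], "C" if genome["chr1"][9] != "C" else "G")
        assert annotate_consequence(rec, t, genome) == "other"

    def test_ref_mismatch_raises(self):
        genome, t = _toy_locus("+")
        with pytest.raises(ValueError):
            annotate_consequence(MutationRecord("S1", "chr1", 7, "C", "G"), t, genome)


class TestSynonymousFilter:
    def test_annotation_mode_keeps_silent_calls(self):
        records = [
            MutationRecord("S1", "chr1", 5, "A", "G", "synonymous"),
            MutationRecord("S1", "chr1", 6, "A", "G", "non_synonymous"),
            MutationRecord("S1", "chr1", 7, "A", "G", "synonymous"),
        ]
        assert len(filter_synonymous(records)) == 2
        assert filter_synonymous([]) == []

    def test_recompute_agrees_with_simulator_annotation(self):
        """Self-consistency: the simulator writes codon-table consequences;
        re-annotation from transcripts + genome must reproduce them."""
        from ssmdep.intervals import select_internal_coding_exons
        from ssmdep.simulate import (
            SimulationParams,
            generate_genome_and_transcripts,
            maf_to_frame,
            simulate_cohort,
        )

        params = SimulationParams(
            n_genes=8, exons_per_gene=4, n_tumours=10, mu=3e-3,
            ese_plant_rate=0.0, seed=2,
        )
        rng = np.random.default_rng(2)
        genome, transcripts, _ = generate_genome_and_transcripts(params, rng)
        maf, _ = simulate_cohort(genome, transcripts, params, rng=rng)
        muts = maf_to_frame(maf)
        records = [
            MutationRecord(r.sample_id, r.chrom, int(r.pos), r.ref, r.alt, r.consequence)
            for r in muts.itertuples(index=False)
        ]
        recomputed = filter_synonymous(records, "recompute", transcripts, genome)
        annotated = filter_synonymous(records, "annotation")
        assert {(r.chrom, r.pos, r.sample_id) for r in recomputed} == {
            (r.chrom, r.pos, r.sample_id) for r in annotated
        }
        assert len(recomputed) > 0

    def test_recompute_requires_genome(self):
        with pytest.raises(ValueError):
            filter_synonymous([], "recompute")
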