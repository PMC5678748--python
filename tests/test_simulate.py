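"""The synthetic cohort generator: structure, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ssmdep.intervals import build_flank_core_region_set, select_internal_coding_exons
from ssmdep.mutations import SIX_CLASSES, ConsequenceAnnotator, read_mutations
from ssmdep.simulate import (
    SimulationParams,
    build_purge_region_map,
    cohort_sample_ids,
    default_ese_hexamers,
    generate_genome_and_transcripts,
    make_covariate_fixtures,
    maf_to_frame,
    simulate_cohort,
    write_fasta,
    write_maf,
)


def small_params(**kw):
    defaults = dict(n_genes=10, exons_per_gene=5, n_tumours=20, mu=3e-3, seed=4)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestGenome:
    def test_internal_exon_count(self):
        params = small_params(ese_plant_rate=0.0)
        _, transcripts, _ = generate_genome_and_transcripts(params)
        exons = select_internal_coding_exons(transcripts)
        assert len(exons) == 10 * (5 - 2)

    def test_deterministic_under_seed(self):
        g1, t1, p1 = generate_genome_and_transcripts(small_params())
        g2, t2, p2 = generate_genome_and_transcripts(small_params())
        assert g1 == g2
        assert [t.coding_exons for t in t1] == [t.coding_exons for t in t2]
        assert [(iv.start, iv.end) for iv in p1] == [(iv.start, iv.end) for iv in p2]

    def test_short_exons_rejected(self):
        with pytest.raises(ValueError):
            small_params(exon_length=(100, 150))

    def test_planted_motifs_lie_in_end_zones(self):
        params = small_params(ese_plant_rate=2.0)
        genome, transcripts, planted = generate_genome_and_transcripts(params)
        exon_of = {}
        for t in transcripts:
            for i, (s, e) in enumerate(t.coding_exons):
                if 0 < i < t.n_exons - 1:
                    exon_of[(s, e)] = t.strand
        assert planted
        for iv in planted:
            home = [k for k in exon_of if k[0] <= iv.start and iv.end <= k[1]]
            assert len(home) == 1
            s, e = home[0]
            # within 69 bp of either exon end, whichever strand
            assert iv.start - s < 69 or e - iv.end < 69
            # planted motifs are purine runs on the coding strand
            seq = genome[params.chrom][iv.start : iv.end]
            bases = set(seq) if exon_of[home[0]] == "+" else set(seq)
            assert bases <= set("AGCT")

    def test_cds_length_is_codon_multiple(self):
        _, transcripts, _ = generate_genome_and_transcripts(small_params())
        for t in transcripts:
            assert sum(e - s for s, e in t.coding_exons) % 3 == 0


class TestCohort:
    def test_truth_conservation(self):
        params = small_params(purge_flank=0.3)
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        exons = select_internal_coding_exons(transcripts)
        annotator = ConsequenceAnnotator(transcripts, genome)
        codes = build_purge_region_map(
            annotator, build_flank_core_region_set(exons).intervals
        )
        maf, truth = simulate_cohort(
            genome, transcripts, params, region_codes=codes, annotator=annotator
        )
        for cls in truth.arisen:
            assert truth.retained(cls) == truth.arisen[cls] - truth.purged[cls]
        total_retained = sum(truth.retained(c) for c in truth.arisen)
        assert total_retained == len(maf)
        assert truth.purged["flank"] > 0
        assert truth.purged["core"] == 0

    def test_null_cohort_has_equal_flank_core_rates(self):
        params = small_params(n_genes=30, n_tumours=50, mu=5e-3, ese_plant_rate=0.0)
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        exons = select_internal_coding_exons(transcripts)
        annotator = ConsequenceAnnotator(transcripts, genome)
        codes = build_purge_region_map(
            annotator, build_flank_core_region_set(exons).intervals
        )
        _, truth = simulate_cohort(
            genome, transcripts, params, region_codes=codes, annotator=annotator
        )
        flank_bp = 40 * len(exons)
        core_bp = 40 * len(exons)
        rate_flank = truth.arisen["flank"] / flank_bp
        rate_core = truth.arisen["core"] / core_bp
        assert rate_flank / rate_core == pytest.approx(1.0, abs=0.12)

    def test_purge_thins_flank_by_expected_fraction(self):
        params = small_params(
            n_genes=40, n_tumours=60, mu=6e-3, purge_flank=0.17, ese_plant_rate=0.0
        )
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        exons = select_internal_coding_exons(transcripts)
        annotator = ConsequenceAnnotator(transcripts, genome)
        codes = build_purge_region_map(
            annotator, build_flank_core_region_set(exons).intervals
        )
        _, truth = simulate_cohort(
            genome, transcripts, params, region_codes=codes, annotator=annotator
        )
        assert truth.realized_depletion("flank") == pytest.approx(0.17, abs=0.03)

    def test_signature_governs_retained_core_class_mix(self):
        """Chi-square goodness of fit of retained core mutations (all
        consequences) against the generative signature."""
        skew = {"A>C": 0.05, "A>G": 0.25, "A>T": 0.05, "C>G": 0.1, "C>T": 0.45, "G>T": 0.1}
        params = small_params(
            n_genes=40, n_tumours=60, mu=6e-3, signature=skew, ese_plant_rate=0.0
        )
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        exons = select_internal_coding_exons(transcripts)
        annotator = ConsequenceAnnotator(transcripts, genome)
        codes = build_purge_region_map(
            annotator, build_flank_core_region_set(exons).intervals
        )
        _, truth = simulate_cohort(
            genome, transcripts, params, region_codes=codes, annotator=annotator
        )
        observed = np.array([truth.core_class_counts[c] for c in SIX_CLASSES])
        assert observed.sum() > 500
        expected = observed.sum() * np.array([skew[c] for c in SIX_CLASSES])
        _, p = sps.chisquare(observed, expected)
        assert p > 0.01

    def test_maf_roundtrip_through_reader(self, tmp_path):
        params = small_params()
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        maf, _ = simulate_cohort(genome, transcripts, params)
        path = tmp_path / "sim.maf"
        write_maf(maf, path)
        records = read_mutations(path, genome=genome)
        assert len(records) == len(maf)
        frame = maf_to_frame(maf)
        assert {r.pos for r in records} == set(frame["pos"])
        assert {r.consequence for r in records} <= {"synonymous", "non_synonymous", "other"}

    def test_cohort_determinism(self):
        params = small_params()
        genome, transcripts, _ = generate_genome_and_transcripts(params)
        maf1, _ = simulate_cohort(genome, transcripts, params)
        maf2, _ = simulate_cohort(genome, transcripts, params)
        pd.testing.assert_frame_equal(maf1, maf2)


class TestFixtures:
    def test_fixture_contract_and_determinism(self):
        params = small_params()
        _, transcripts, _ = generate_genome_and_transcripts(params)
        fx1 = make_covariate_fixtures(transcripts, seed=7, n_samples=20)
        fx2 = make_covariate_fixtures(transcripts, seed=7, n_samples=20)
        for key in fx1:
            pd.testing.assert_frame_equal(fx1[key], fx2[key])
        assert list(fx1["exon_scores"].columns) == [
            "exon", "nucleosome", "replication_timing", "mappability"
        ]
        assert set(fx1["gene_classes"]["cancer_class"]) <= {
            "oncogene", "tumour_suppressor", "non_cancer"
        }
        assert len(fx1["samples"]) == 20
        assert set(fx1["samples"]["sample_id"]) == set(cohort_sample_ids(params))

    def test_fasta_writer(self, tmp_path):
        genome = {"chr1": "ACGT" * 40}
        path = tmp_path / "g.fa"
        write_fasta(genome, path)
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)
        assert str(fa["chr1"][:]) == genome["chr1"]
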