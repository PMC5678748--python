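"""Region counting, CpG masking and normalized rates."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_exon
from ssmdep._seq import revcomp
from ssmdep.counting import (
    class_normalized_rates,
    count_mutations_in_regions,
    depletion_fraction,
    mask_cpg_positions,
    per_tumour_density_table,
    region_mean_score,
    ssm_density,
    trinuc_rates,
)
from ssmdep.intervals import GenomicInterval, RegionSet
from ssmdep.mutations import SIX_CLASSES, canonical_substitution_class


def muts_frame(rows):
    """rows: (sample, chrom, pos, ref, alt)"""
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    ).assign(consequence="synonymous", gene_id="g")


class TestCpgMask:
    def test_single_cg(self):
        genome = {"chr1": "AACGTT"}
        iv = GenomicInterval("chr1", 0, 6)
        assert mask_cpg_positions(genome, iv) == {2, 3}

    def test_overlapping_cgs(self):
        genome = {"chr1": "ACGCGT"}
        iv = GenomicInterval("chr1", 0, 6)
        assert mask_cpg_positions(genome, iv) == {1, 2, 3, 4}

    def test_boundary_context_beyond_interval(self):
        # interval ends on a C whose G lies just outside: the C is masked
        genome = {"chr1": "AAACGA"}
        iv = GenomicInterval("chr1", 0, 4)
        assert mask_cpg_positions(genome, iv) == {3}

    def test_contig_edge_has_no_context(self):
        genome = {"chr1": "CGTT"}
        iv = GenomicInterval("chr1", 0, 4)
        assert mask_cpg_positions(genome, iv) == {0, 1}


class TestCounting:
    def region_set(self):
        return RegionSet(intervals=[
            GenomicInterval("chr1", 0, 20, "+", "flank5"),
            GenomicInterval("chr1", 60, 100, "+", "core"),
        ])

    def test_role_assignment_and_outside_ignored(self):
        muts = muts_frame([
            ("S1", "chr1", 61, "A", "G"), ("S1", "chr1", 62, "A", "G"),
            ("S2", "chr1", 63, "A", "G"), ("S1", "chr1", 5, "A", "G"),
            ("S1", "chr1", 200, "A", "G"),
        ])
        counts = count_mutations_in_regions(muts, self.region_set())
        assert counts == {"flank5": (1, 20), "core": (3, 40)}

    def test_masked_position_excluded_from_count_and_bp(self):
        muts = muts_frame([("S1", "chr1", 61, "A", "G"), ("S1", "chr1", 62, "A", "G")])
        counts = count_mutations_in_regions(muts, self.region_set(), mask={("chr1", 61)})
        assert counts["core"] == (1, 39)

    def test_overlapping_regions_raise(self):
        rs = RegionSet(intervals=[
            GenomicInterval("chr1", 0, 20, "+", "flank5"),
            GenomicInterval("chr1", 10, 30, "+", "core"),
        ])
        with pytest.raises(ValueError, match="overlapping"):
            count_mutations_in_regions(muts_frame([]), rs)

    def test_density_arithmetic(self):
        assert ssm_density(10, 100, 5).rate == pytest.approx(0.02)
        assert ssm_density(0, 1000, 50).rate == 0.0
        with pytest.raises(ValueError):
            ssm_density(1, 0, 5)

    def test_pooled_rate_equals_mean_of_per_tumour_rates(self):
        # algebraic identity when every tumour shares the denominator
        muts = muts_frame([
            ("S1", "chr1", 61, "A", "G"), ("S2", "chr1", 62, "A", "G"),
            ("S2", "chr1", 63, "A", "G"),
        ])
        table = per_tumour_density_table(muts, self.region_set())
        core = table[table["role"] == "core"]
        pooled = ssm_density(int(core["count"].sum()), 40, 2)
        assert pooled.rate == pytest.approx(core["rate"].mean())

    def test_per_tumour_table_has_explicit_zeros(self):
        muts = muts_frame([("S1", "chr1", 61, "A", "G")])
        table = per_tumour_density_table(
            muts, self.region_set(), samples=["S1", "S2"]
        )
        assert len(table) == 4
        s2 = table[(table["sample_id"] == "S2")]
        assert (s2["count"] == 0).all() and (s2["rate"] == 0).all()

    def test_per_tumour_counts_sum_to_pooled(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"S{rng.integers(5)}", "chr1", int(rng.integers(0, 120)), "A", "G")
            for _ in range(60)
        ]
        muts = muts_frame(rows)
        rs = self.region_set()
        pooled = count_mutations_in_regions(muts, rs)
        table = per_tumour_density_table(muts, rs)
        for role, (count, _bp) in pooled.items():
            assert table.loc[table["role"] == role, "count"].sum() == count


class TestNormalizedRates:
    def test_toy_class_rate(self):
        # region with 10 A and 10 T; two A>C-class SSMs; one tumour -> 2/20
        genome = {"chr1": "AT" * 10 + "CG" * 5}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 0, 20, "+", "core")])
        muts = muts_frame([("S1", "chr1", 0, "A", "C"), ("S1", "chr1", 3, "T", "G")])
        rates = class_normalized_rates(muts, rs, genome, n_tumours=1)
        row = rates[(rates["role"] == "core") & (rates["subst_class"] == "A>C")].iloc[0]
        assert row["count"] == 2 and row["denom_bases"] == 20
        assert row["rate"] == pytest.approx(0.1)

    def test_class_counts_partition_total(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 200))}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 20, 180, "+", "core")])
        rows = []
        for i in range(50):
            pos = int(rng.integers(20, 180))
            ref = genome["chr1"][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((f"S{i % 4}", "chr1", pos, ref, alt))
        muts = muts_frame(rows)
        rates = class_normalized_rates(muts, rs, genome, n_tumours=4)
        assert rates["count"].sum() == 50

    def test_denominators_match_bruteforce_tally(self):
        """Oracle: per-position base tally over a 60 bp toy region."""
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 80))
        genome = {"chr1": seq}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 10, 70, "+", "core")])
        rates = class_normalized_rates(muts_frame([]), rs, genome, n_tumours=3)
        tally = {b: sum(1 for p in range(10, 70) if seq[p] == b) for b in "ACGT"}
        expected = {
            "A>C": tally["A"] + tally["T"], "A>G": tally["A"] + tally["T"],
            "A>T": tally["A"] + tally["T"], "C>G": tally["C"] + tally["G"],
            "C>T": tally["C"] + tally["G"], "G>T": tally["G"] + tally["C"],
        }
        for cls in SIX_CLASSES:
            row = rates[rates["subst_class"] == cls].iloc[0]
            assert row["denom_bases"] == expected[cls]

    def test_trinuc_numerator_and_label(self):
        genome = {"chr1": "AACGTA"}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 0, 6, "+", "core")])
        muts = muts_frame([("S1", "chr1", 2, "C", "T")])
        rates = trinuc_rates(muts, rs, genome, n_tumours=1)
        row = rates[rates["trinuc_class"] == "A[C>T]G"].iloc[0]
        assert row["count"] == 1
        assert rates["count"].sum() == 1

    def test_trinuc_denominators_match_sliding_window(self):
        """Oracle: explicit sliding-window triplet tally with reverse
        complement collapse."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 100))
        genome = {"chr1": seq}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 10, 70, "+", "core")])
        rates = trinuc_rates(muts_frame([]), rs, genome, n_tumours=2)
        window = {}
        for p in range(10, 70):
            tri = seq[p - 1 : p + 2]
            window[tri] = window.get(tri, 0) + 1
        for _, row in rates.iterrows():
            label = row["trinuc_class"]
            ref_tri = label[0] + label[2] + label[6]
            expected = window.get(ref_tri, 0) + window.get(revcomp(ref_tri), 0)
            assert row["denom_trinucs"] == expected

    def test_masking_is_consistent_between_numerator_and_denominator(self):
        genome = {"chr1": "ACGA" * 10}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 0, 40, "+", "core")])
        mask = {("chr1", p) for p in range(40) if genome["chr1"][p] in "CG"}
        muts = muts_frame([("S1", "chr1", 1, "C", "T"), ("S1", "chr1", 0, "A", "G")])
        rates = class_normalized_rates(muts, rs, genome, n_tumours=1, mask=mask)
        ct = rates[rates["subst_class"] == "C>T"].iloc[0]
        assert ct["count"] == 0 and ct["denom_bases"] == 0 and not ct["defined"]
        ag = rates[rates["subst_class"] == "A>G"].iloc[0]
        assert ag["count"] == 1 and ag["denom_bases"] == 20


class TestDepletionAndScores:
    def test_depletion_examples(self):
        assert depletion_fraction(0.83, 1.0) == pytest.approx(0.17)
        assert depletion_fraction(1.0, 1.0) == 0.0
        assert depletion_fraction(1.2, 1.0) == pytest.approx(-0.2)
        with pytest.raises(ValueError):
            depletion_fraction(1.0, 0.0)

    def test_region_mean_score(self):
        rs = RegionSet(intervals=[
            GenomicInterval("chr1", 0, 10, "+", "flank5"),
            GenomicInterval("chr1", 20, 30, "+", "core"),
        ])
        scores = pd.DataFrame({
            "chrom": ["chr1"] * 30, "pos": list(range(30)),
            "score": [0.0] * 10 + [0.5] * 10 + [1.0] * 10,
        })
        means, table = region_mean_score(scores, rs)
        assert means == {"flank5": 0.0, "core": 1.0}
        # per-role mean equals bp-weighted mean of per-interval means
        for role in means:
            sub = table[table["role"] == role]
            weighted = (sub["mean_score"] * sub["covered_bp"]).sum() / sub["covered_bp"].sum()
            assert means[role] == pytest.approx(weighted)

    def test_uncovered_bases_excluded(self):
        rs = RegionSet(intervals=[GenomicInterval("chr1", 0, 10, "+", "core")])
        scores = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": range(5), "score": [1.0] * 5})
        means, table = region_mean_score(scores, rs)
        assert means["core"] == 1.0
        assert table["covered_bp"].iloc[0] == 5


class TestInvariances:
    def test_rates_invariant_under_renaming_and_translation(self):
        genome = {"chr1": "ACGTAGCTAGGATCGATCGA" * 5}
        rs = RegionSet(intervals=[GenomicInterval("chr1", 10, 60, "+", "core")])
        rows = [("S1", "chr1", p, genome["chr1"][p], "A" if genome["chr1"][p] != "A" else "G")
                for p in (12, 20, 33)]
        muts = muts_frame(rows)
        base = class_normalized_rates(muts, rs, genome, 1)

        shift = 7
        genome2 = {"chrX": "T" * shift + genome["chr1"]}
        rs2 = RegionSet(intervals=[GenomicInterval("chrX", 10 + shift, 60 + shift, "+", "core")])
        muts2 = muts.assign(chrom="chrX", pos=muts["pos"] + shift)
        shifted = class_normalized_rates(muts2, rs2, genome2, 1)
        pd.testing.assert_frame_equal(
            base.drop(columns="role"), shifted.drop(columns="role")
        )
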