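"""Stack building, locus merging, catalogue construction and summary stats."""

import numpy as np
import pytest

import radsites as r
from radsites.assembly import CatalogueLocus, RadCatalogue, build_catalogue


def reads_of(*seqs: str, prefix: str = "rd") -> list[tuple[str, str]]:
    return [(f"{prefix}{i}", s) for i, s in enumerate(seqs)]


P321 = r.AssemblyParams(3, 2, 1)


class TestBuildStacks:
    def test_identical_reads_one_primary(self):
        result = r.build_stacks(reads_of(*["ACGTACGT"] * 10), P321)
        assert len(result.primary) == 1
        assert result.primary[0].depth == 10

    def test_below_threshold_yields_no_primary(self):
        result = r.build_stacks(reads_of("AAAAAAAA", "AAAAAAAA", "AAAAAAAC", "AAAAAAAC"), P321)
        assert result.primary == []

    def test_secondary_assignment_and_drop(self):
        reads = reads_of(*["AAAAAAAA"] * 5, "AAAAAAAC", "CCCCCCCC")
        result = r.build_stacks(reads, P321)
        assert len(result.primary) == 1
        assert result.assigned == [("AAAAAAAC", 1, 0)]  # 1 mismatch <= M
        assert result.n_dropped == 1  # 8 mismatches > M

    def test_assignment_tie_breaks_to_deeper_stack(self):
        reads = reads_of(*["AACAAAAA"] * 5, *["AAAAAAAA"] * 4, "AATAAAAA")
        # secondary AATAAAAA is 1 mismatch from both primaries (by construction
        # of positions 2): distance to AACAAAAA is 1, to AAAAAAAA is 1
        result = r.build_stacks(reads, r.AssemblyParams(3, 2, 1))
        assert len(result.primary) == 2
        seq, count, idx = result.assigned[0]
        assert result.primary[idx].consensus == "AACAAAAA"  # depth 5 beats depth 4

    def test_short_reads_discarded(self):
        reads = reads_of(*["ACGTACGT"] * 4, "ACGT")
        result = r.build_stacks(reads, P321)
        assert result.n_short_discarded == 1
        assert result.primary[0].depth == 4

    def test_dereplication_matches_hash_oracle(self, clean_cohort):
        from collections import Counter

        reads = clean_cohort["reads"]["ind_01"]
        result = r.build_stacks(reads, P321, individual="ind_01")
        oracle = Counter(seq for _rid, seq in reads)
        expected = sorted(
            (depth, seq) for seq, depth in oracle.items() if depth >= P321.m
        )
        got = sorted((s.depth, s.consensus) for s in result.primary)
        assert got == expected


class TestMergeStacksToLoci:
    def test_one_mismatch_merges_to_single_locus(self):
        reads = reads_of(*["AAAAAAAA"] * 5, *["AAACAAAA"] * 4)
        loci = r.assemble_individual(reads, r.AssemblyParams(3, 2, 1))
        assert len(loci) == 1
        locus = loci[0]
        assert locus.depth == 9
        # one variant column (two observed bases), all others fixed
        poly = np.count_nonzero((locus.counts > 0).sum(axis=0) == 2)
        assert poly == 1
        assert locus.consensus == "AAAAAAAA"  # majority A at the variant column

    def test_three_mismatches_stay_separate(self):
        reads = reads_of(*["AAAAAAAA"] * 5, *["CCCAAAAA"] * 4)
        loci = r.assemble_individual(reads, r.AssemblyParams(3, 2, 1))
        assert len(loci) == 2

    def test_majority_tie_resolves_alphabetically(self):
        reads = reads_of(*["AAAATAAA"] * 4, *["AAAACAAA"] * 4)
        loci = r.assemble_individual(reads, r.AssemblyParams(3, 2, 1))
        assert len(loci) == 1
        assert loci[0].consensus == "AAAACAAA"  # C < T at the tied column

    def test_heterozygous_site_one_locus_one_variant_column(self, poly_cohort):
        """Error-free two-allele simulation: each flank assembles into one
        locus whose counts expose exactly the SNP column."""
        truth = poly_cohort["truth"]
        snp = truth.snps.iloc[0]
        ind = "ind_01"
        site_reads = [
            (rid, seq)
            for rid, seq in poly_cohort["reads"][ind]
            if rid.split("|")[2] == str(snp["site_start"]) and rid.split("|")[3] == snp["side"]
        ]
        loci = r.assemble_individual(site_reads, r.AssemblyParams(3, 1, 1), individual=ind)
        assert len(loci) == 1
        variant_cols = np.flatnonzero((loci[0].counts > 0).sum(axis=0) >= 2)
        genotype_has_both = any(
            rid.split("|")[4] == "alt" for rid, _ in site_reads
        ) and any(rid.split("|")[4] == "ref" for rid, _ in site_reads)
        if genotype_has_both:
            assert list(variant_cols) == [snp["offset"]]
        else:
            assert len(variant_cols) == 0


class TestBuildCatalogue:
    def test_shared_locus_across_individuals(self):
        per_ind = [
            (f"ind_{i}", r.assemble_individual(reads_of(*["ACGTACGT"] * 5), P321, f"ind_{i}"))
            for i in range(5)
        ]
        catalogue = build_catalogue(per_ind, P321)
        assert len(catalogue) == 1
        assert catalogue.loci[0].n_individuals == 5

    @pytest.mark.parametrize("n,expected", [(1, 1), (0, 2)])
    def test_allelic_split_depends_on_n(self, n, expected):
        params = r.AssemblyParams(3, 2, n)
        a = r.assemble_individual(reads_of(*["AAAAAAAA"] * 5), params, "i1")
        b = r.assemble_individual(reads_of(*["AAAACAAA"] * 5), params, "i2")
        catalogue = build_catalogue([("i1", a), ("i2", b)], params)
        assert len(catalogue) == expected

    def test_catalogue_consensus_fixed_by_founder(self):
        params = r.AssemblyParams(3, 2, 1)
        a = r.assemble_individual(reads_of(*["AAAACAAA"] * 5), params, "i1")
        b = r.assemble_individual(reads_of(*["AAAAAAAA"] * 9), params, "i2")
        catalogue = build_catalogue([("i1", a), ("i2", b)], params)
        assert catalogue.loci[0].consensus == "AAAACAAA"

    def test_two_loci_per_site_on_clean_cohort(self, clean_cohort):
        """Error-free complete digestion recovers exactly two catalogue loci
        per planted site, with consensus equal to the true flanks."""
        catalogue = r.assemble_cohort(clean_cohort["reads"], P321)
        assert len(catalogue) == 2 * len(clean_cohort["sites"])
        genome = clean_cohort["genome"]
        truth = clean_cohort["truth"]
        true_flanks = {
            genome[contig][start:end] if strand == "+" else r.revcomp(genome[contig][start:end])
            for _lid, contig, start, end, strand in truth.locus_alignments
        }
        assert {loc.consensus for loc in catalogue.loci} == true_flanks


class TestAssemblyStats:
    @staticmethod
    def _locus(members):
        length = 8
        data = {}
        for ind, bases in members.items():
            counts = np.zeros((4, length), dtype=np.int64)
            for base, depth in bases:
                col = np.full(length, "ACGT".index(base[0]))
                col[3] = "ACGT".index(base[1])  # column 3 carries the genotype
                counts[col, np.arange(length)] += depth
            data[ind] = (counts, sum(d for _b, d in bases))
        return CatalogueLocus(0, "A" * length, data)

    def test_heterozygosity_worked_example(self):
        # one variant column; 4 genotyped individuals, 2 heterozygous
        locus = self._locus(
            {
                "i1": [("AA", 5), ("AC", 5)],
                "i2": [("AA", 10)],
                "i3": [("AA", 6), ("AC", 4)],
                "i4": [("AC", 10)],
            }
        )
        catalogue = RadCatalogue([locus], P321)
        stats = r.assembly_stats(catalogue)
        assert stats["observed_heterozygosity"] == pytest.approx(0.5)
        assert stats["loci_in_ge2_individuals"] == 1

    def test_monomorphic_catalogue_flags_zero_heterozygosity(self):
        locus = self._locus({"i1": [("AA", 10)], "i2": [("AA", 8)]})
        stats = r.assembly_stats(RadCatalogue([locus], P321))
        assert stats["observed_heterozygosity"] == 0.0
        assert stats["no_variant_columns"] == 1.0

    def test_heterozygosity_recovers_simulated_allele_frequency(self, poly_cohort):
        """With Hardy-Weinberg genotypes at alternate-allele frequency q the
        expected heterozygote fraction is 2q(1-q)."""
        catalogue = r.assemble_cohort(poly_cohort["reads"], P321)
        stats = r.assembly_stats(catalogue)
        q = poly_cohort["spec"].maf
        expected = 2 * q * (1 - q)
        n_calls = len(poly_cohort["sites"]) * poly_cohort["spec"].n_individuals
        se = np.sqrt(expected * (1 - expected) / n_calls)
        assert abs(stats["observed_heterozygosity"] - expected) <= 3 * se


class TestInvariants:
    def test_raising_m_never_increases_primary_stacks(self, clean_cohort):
        reads = clean_cohort["reads"]["ind_02"]
        counts = [
            len(r.build_stacks(reads, r.AssemblyParams(m, 2, 1)).primary)
            for m in (1, 2, 3, 4, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_raising_n_never_increases_catalogue_size(self, poly_cohort):
        sizes = [
            len(r.assemble_cohort(poly_cohort["reads"], r.AssemblyParams(3, 2, n)))
            for n in (0, 1, 2, 3)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_read_order_invariance(self, clean_cohort):
        params = P321
        cat_a = r.assemble_cohort(clean_cohort["reads"], params)
        rng = np.random.default_rng(99)
        shuffled = {}
        for ind, reads in clean_cohort["reads"].items():
            order = rng.permutation(len(reads))
            shuffled[ind] = [reads[i] for i in order]
        cat_b = r.assemble_cohort(shuffled, params)
        assert cat_a.to_frame().to_csv() == cat_b.to_frame().to_csv()

    def test_invalid_params_rejected(self):
        for m, M, n in ((0, 2, 1), (3, -1, 1), (3, 2, -1)):
            with pytest.raises(ValueError):
                r.AssemblyParams(m, M, n)

    def test_parameter_grid_shape(self):
        assert len(r.PARAMETER_GRID) == 7
        assert r.AssemblyParams(3, 2, 1) in r.PARAMETER_GRID
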