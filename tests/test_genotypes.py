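"""SNP QC: frequencies, minor-allele orientation, MAF filter, imputation, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import selftraingp as sg
from selftraingp.genotypes import GenotypeError, _round_half_up


def matrix(values, oriented=False):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return sg.GenotypeMatrix(
        [f"a{i}" for i in range(n)], [f"m{j}" for j in range(m)], values, oriented
    )


genotype_columns = hnp.arrays(
    dtype=float,
    shape=st.tuples(st.integers(2, 12), st.integers(1, 8)),
    elements=st.sampled_from([0.0, 1.0, 2.0, np.nan]),
)


class TestValidation:
    def test_rejects_bad_entries(self):
        with pytest.raises(GenotypeError, match="0/1/2"):
            matrix([[0, 3]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(GenotypeError, match="duplicate"):
            sg.GenotypeMatrix(["a", "a"], ["m"], [[0.0], [1.0]])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(GenotypeError):
            sg.GenotypeMatrix(["a"], ["m1", "m2"], [[0.0]])


class TestAlleleFrequencies:
    @pytest.mark.parametrize("column, expected", [
        ([0, 0, 0, 0], 0.0),
        ([0, 1, 2, 2], 5 / 8),          # 5 copies over 8 alleles
        ([1, np.nan, 1], 0.5),          # 2 copies over 4 non-missing alleles
    ])
    def test_hand_counts(self, column, expected):
        G = matrix(np.asarray(column, dtype=float)[:, None])
        freqs = sg.compute_allele_frequencies(G)
        assert freqs.frequency[0] == pytest.approx(expected)

    def test_all_missing_marker_is_flagged_not_given_a_value(self):
        G = matrix([[np.nan, 0.0], [np.nan, 1.0]])
        freqs = sg.compute_allele_frequencies(G)
        assert freqs.all_missing.tolist() == [True, False]
        assert np.isnan(freqs.frequency[0])


class TestRecodeMinorAllele:
    def test_major_oriented_column_is_flipped(self):
        G = matrix(np.array([[2.0], [2.0], [2.0], [1.0]]))  # freq 7/8
        out = sg.recode_minor_allele(G)
        assert out.values[:, 0].tolist() == [0.0, 0.0, 0.0, 1.0]
        assert out.oriented_minor

    def test_minor_oriented_column_unchanged(self):
        G = matrix(np.array([[0.0], [1.0], [0.0]]))  # freq 1/6
        out = sg.recode_minor_allele(G)
        assert out.values[:, 0].tolist() == [0.0, 1.0, 0.0]

    def test_frequency_exactly_half_left_unflipped(self):
        G = matrix(np.array([[0.0], [2.0]]))
        out = sg.recode_minor_allele(G)
        assert out.values[:, 0].tolist() == [0.0, 2.0]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(genotype_columns)
    def test_involution_and_heterozygote_preservation(self, values):
        G = matrix(values)
        once = sg.recode_minor_allele(G)
        twice = sg.recode_minor_allele(once)
        np.testing.assert_array_equal(once.values, twice.values)
        het_before = np.nansum(values == 1.0, axis=0)
        het_after = np.nansum(once.values == 1.0, axis=0)
        np.testing.assert_array_equal(het_before, het_after)
        freqs = sg.compute_allele_frequencies(once)
        assert np.all((freqs.frequency <= 0.5) | np.isnan(freqs.frequency))


class TestFilterMaf:
    def test_strictly_lower_than_threshold_removed(self):
        # over 20 animals (40 alleles): 1 het → freq 0.025 < 0.05 removed;
        # 2 hets → freq exactly 0.05 retained (strict "lower than")
        col_low = np.zeros(20); col_low[0] = 1.0
        col_at = np.zeros(20); col_at[:2] = 1.0
        G = matrix(np.column_stack([col_low, col_at]), oriented=True)
        out = sg.filter_maf(G, 0.05)
        assert list(out.marker_ids) == ["m1"]

    def test_zero_threshold_removes_only_all_missing(self):
        values = np.array([[0.0, np.nan], [1.0, np.nan]])
        G = matrix(values, oriented=True)
        out = sg.filter_maf(G, 0.0)
        assert list(out.marker_ids) == ["m0"]

    def test_requires_minor_orientation(self):
        with pytest.raises(GenotypeError, match="recode_minor_allele"):
            sg.filter_maf(matrix([[0.0]]), 0.05)

    def test_threshold_out_of_range(self):
        with pytest.raises(GenotypeError, match="threshold"):
            sg.filter_maf(matrix([[0.0]], oriented=True), 0.7)


class TestImputeMissing:
    @pytest.mark.parametrize("n_hom_alt, fill", [
        (1, 0.0),   # p = 2/20 = 0.10 → round(0.2) = 0
        (4, 1.0),   # p = 8/20 = 0.40 → round(0.8) = 1
    ])
    def test_rounded_expected_count(self, n_hom_alt, fill):
        col = np.zeros(10)
        col[:n_hom_alt] = 2.0
        col = np.append(col, np.nan)
        G = matrix(col[:, None], oriented=True)
        out = sg.impute_missing(G)
        assert out.values[-1, 0] == fill
        assert out.n_missing == 0

    def test_half_rounds_up(self):
        assert _round_half_up(np.array([0.5, 1.5, 0.49])).tolist() == [1.0, 2.0, 0.0]

    def test_no_missing_is_identity(self):
        G = matrix([[0.0, 1.0], [2.0, 1.0]], oriented=True)
        out = sg.impute_missing(G)
        np.testing.assert_array_equal(out.values, G.values)

    def test_all_missing_marker_without_external_frequency_errors(self):
        G = matrix([[np.nan], [np.nan]], oriented=True)
        with pytest.raises(GenotypeError, match="filter"):
            sg.impute_missing(G)

    def test_external_frequencies_override_internal(self):
        G = matrix([[np.nan], [0.0]], oriented=True)
        ext = sg.AlleleFrequencies(np.array(["m0"], dtype=object),
                                   np.array([0.4]), np.array([1]))
        out = sg.impute_missing(G, ext)
        assert out.values[0, 0] == 1.0


class TestPipeline:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(genotype_columns)
    def test_idempotence_and_no_missing(self, values):
        G = matrix(values)
        once, _ = sg.qc_pipeline(G, 0.05)
        twice, _ = sg.qc_pipeline(once, 0.05)
        assert once.n_missing == 0
        np.testing.assert_array_equal(once.values, twice.values)
        assert list(once.marker_ids) == list(twice.marker_ids)

    def test_surviving_frequencies_at_least_threshold(self, small_population):
        G, _ = sg.qc_pipeline(small_population.genotypes, 0.05)
        # frequencies recomputed after imputation can only move by the
        # imputed entries; check the filter contract on pre-imputation stats
        oriented = sg.recode_minor_allele(small_population.genotypes)
        kept = sg.filter_maf(oriented, 0.05)
        freqs = sg.compute_allele_frequencies(kept)
        assert (freqs.frequency >= 0.05).all()


class TestIO:
    def test_tsv_round_trip(self, tmp_path, small_population):
        G = small_population.genotypes
        path = tmp_path / "geno.tsv"
        sg.write_genotypes(G, path)
        back = sg.read_genotypes(path, "tsv")
        np.testing.assert_array_equal(G.values, back.values)
        assert list(G.animal_ids) == list(back.animal_ids)
        assert list(G.marker_ids) == list(back.marker_ids)

    def test_tsv_parse_small(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("animal_id\tm1\tm2\tm3\nA\t0\t1\t2\nB\tNA\t0\t2\n")
        G = sg.read_genotypes(path, "tsv")
        assert G.n_missing == 1
        assert G.values[0].tolist() == [0.0, 1.0, 2.0]

    def test_tsv_malformed_entry_reports_position(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("animal_id\tm1\nA\t5\n")
        with pytest.raises(GenotypeError, match="m1"):
            sg.read_genotypes(path, "tsv")

    def test_vcf_coding_and_multiallelic_skip(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
            "1\t200\tsnp2\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0\n"
            "1\t300\tsnp3\tC\tT\t.\t.\t.\tGT\t./.\t0/0\n"
        )
        G = sg.read_genotypes(vcf, "vcf")
        assert list(G.marker_ids) == ["snp1", "snp3"]  # multi-allelic skipped
        assert G.values[0, 0] == 1.0 and G.values[1, 0] == 2.0
        assert np.isnan(G.values[0, 1]) and G.values[1, 1] == 0.0
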