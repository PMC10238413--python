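import numpy as np
import pytest

from msyphylo.variant_matrix import (
    MISSING,
    FilterConfig,
    PolarizedMatrix,
    Variant,
    filter_stringent,
    haplotype_strings,
    polarize,
    read_vcf,
    write_vcf,
)

from helpers import make_matrix, make_variants

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=Y,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_text_vcf(path, samples, records):
    lines = [VCF_HEADER.format(samples="\t".join(samples))]
    lines += ["\t".join(r) + "\n" for r in records]
    path.write_text("".join(lines))


class TestReadVcf:
    def test_simple_haploid(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, ["s1", "s2", "s3"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0", "1", "0"),
            ("Y", "200", "m2", "C", "T", ".", ".", ".", "GT", "1", "1", "0"),
        ])
        m = read_vcf(p)
        assert m.samples == ["s1", "s2", "s3"]
        assert [v.id for v in m.variants] == ["m1", "m2"]
        np.testing.assert_array_equal(m.calls, [[0, 1], [1, 1], [0, 0]])

    def test_heterozygous_becomes_missing(self, tmp_path):
        p = tmp_path / "het.vcf"
        write_text_vcf(p, ["s1", "s2"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0/1", "1/1"),
        ])
        m = read_vcf(p)
        np.testing.assert_array_equal(m.calls, [[MISSING], [1]])

    def test_multiallelic_split(self, tmp_path):
        # hand-split oracle for A -> C,T over five samples
        p = tmp_path / "multi.vcf"
        write_text_vcf(p, ["s1", "s2", "s3", "s4", "s5"], [
            ("Y", "100", "m1", "A", "C,T", ".", ".", ".", "GT",
             "0", "1", "2", ".", "2"),
        ])
        m = read_vcf(p)
        assert [(v.ref_allele, v.alt_allele) for v in m.variants] == [
            ("A", "C"), ("A", "T")]
        # allele 2 (T) codes ref on the A->C record and alt on the A->T record
        np.testing.assert_array_equal(
            m.calls,
            [[0, 0], [1, 0], [0, 1], [MISSING, MISSING], [0, 1]],
        )

    def test_missing_dot_call(self, tmp_path):
        p = tmp_path / "m.vcf"
        write_text_vcf(p, ["s1", "s2"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", ".", "1"),
        ])
        m = read_vcf(p)
        np.testing.assert_array_equal(m.calls, [[MISSING], [1]])

    def test_sample_subset_unknown(self, tmp_path):
        p = tmp_path / "s.vcf"
        write_text_vcf(p, ["s1"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0"),
        ])
        with pytest.raises(ValueError, match="not in VCF"):
            read_vcf(p, sample_subset=["nope"])


class TestPolarize:
    def test_outgroup_ref_means_alt_derived(self, tmp_path):
        p = tmp_path / "p.vcf"
        write_text_vcf(p, ["og", "s1", "s2"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0", "1", "0"),
        ])
        pm = polarize(read_vcf(p), "og")
        assert pm.samples == ["s1", "s2"]
        assert pm.variants[0].ancestral == "ref"
        np.testing.assert_array_equal(pm.states, [[1], [0]])

    def test_truth_table_four_variants(self, tmp_path):
        # outgroup pattern (ref, alt, missing, ref) over two ingroup samples
        p = tmp_path / "t.vcf"
        write_text_vcf(p, ["og", "s1", "s2"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0", "1", "0"),
            ("Y", "200", "m2", "A", "G", ".", ".", ".", "GT", "1", "1", "0"),
            ("Y", "300", "m3", "A", "G", ".", ".", ".", "GT", ".", "1", "0"),
            ("Y", "400", "m4", "A", "G", ".", ".", ".", "GT", "0", "0", "."),
        ])
        pm = polarize(read_vcf(p), "og")
        assert [v.ancestral for v in pm.variants] == ["ref", "alt", "unknown", "ref"]
        # m2: outgroup carries alt, so alt is ancestral and ref is derived
        np.testing.assert_array_equal(
            pm.states, [[1, 0, 1, 0], [0, 1, 0, MISSING]]
        )

    def test_missing_outgroup_flags_unpolarized(self, tmp_path):
        p = tmp_path / "u.vcf"
        write_text_vcf(p, ["og", "s1"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", ".", "1"),
        ])
        pm = polarize(read_vcf(p), "og")
        assert pm.variants[0].ancestral == "unknown"

    def test_absent_outgroup_errors(self, tmp_path):
        p = tmp_path / "e.vcf"
        write_text_vcf(p, ["s1"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "0"),
        ])
        with pytest.raises(KeyError):
            polarize(read_vcf(p), "donkey")

    def test_polarize_is_idempotent(self, tmp_path):
        """Re-polarizing against an all-ancestral outgroup changes nothing."""
        p = tmp_path / "i.vcf"
        write_text_vcf(p, ["og", "s1", "s2"], [
            ("Y", "100", "m1", "A", "G", ".", ".", ".", "GT", "1", "1", "0"),
            ("Y", "200", "m2", "C", "T", ".", ".", ".", "GT", "0", "1", "1"),
        ])
        pm = polarize(read_vcf(p), "og")
        from msyphylo.variant_matrix import AlleleMatrix

        derived_is_alt = np.array([v.ancestral == "ref" for v in pm.variants])
        og_row = np.where(derived_is_alt, 0, 1).astype(np.int8)
        ingroup = np.where(derived_is_alt, pm.states, 1 - pm.states).astype(np.int8)
        am = AlleleMatrix(samples=["og2", "s1", "s2"], variants=pm.variants,
                          calls=np.vstack([og_row, ingroup]))
        pm2 = polarize(am, "og2")
        np.testing.assert_array_equal(pm2.states, pm.states)
        assert [v.ancestral for v in pm2.variants] == \
            [v.ancestral for v in pm.variants]


class TestFilterStringent:
    def test_high_missing_site_removed(self):
        m = make_matrix([[1, 0], [MISSING, 0], [MISSING, 1], [0, 1]])
        out, rep = filter_stringent(m, FilterConfig(max_site_missing=0.2,
                                                    max_sample_missing=1.0))
        assert rep.removed_site_missing == 1
        assert out.n_variants == 1

    def test_identity_when_all_pass(self):
        m = make_matrix([[1, 0], [0, 1]])
        out, rep = filter_stringent(m)
        np.testing.assert_array_equal(out.states, m.states)
        assert rep.removed_site_missing == rep.removed_unpolarized == 0
        assert rep.retained_variants == 2

    def test_engineered_failures_17_of_20(self):
        # 20 variants: one unpolarized, one high-missing, one STR -> 17 retained
        variants = make_variants(20)
        variants[3] = Variant(id="v003", contig="Y", pos=40, ref_allele="A",
                              alt_allele="G", ancestral="unknown")
        variants[7] = Variant(id="v007", contig="Y", pos=80, ref_allele="A",
                              alt_allele="AG", vclass="STR", ancestral="ref")
        rows = np.zeros((10, 20), dtype=np.int8)
        rows[0, :] = 1
        rows[:6, 11] = MISSING  # 60% missing at variant 11
        m = PolarizedMatrix(samples=[f"S{i}" for i in range(10)],
                            variants=variants, states=rows)
        out, rep = filter_stringent(m, FilterConfig(max_site_missing=0.5,
                                                    max_sample_missing=1.0))
        assert out.n_variants == 17
        assert rep.removed_not_biallelic == 1
        assert rep.removed_unpolarized == 1
        assert rep.removed_site_missing == 1
        rep.check()

    def test_counts_reconcile(self):
        m = make_matrix([[1, 0, MISSING], [0, 1, MISSING]])
        _, rep = filter_stringent(m, FilterConfig(max_site_missing=0.4))
        assert (rep.removed_not_biallelic + rep.removed_unpolarized
                + rep.removed_site_missing + rep.retained_variants
                ) == rep.input_variants

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(max_site_missing=1.5)

    def test_singletons_flagged_not_removed(self):
        m = make_matrix([[1, 1], [0, 1], [0, 1]])
        out, rep = filter_stringent(m)
        assert out.n_variants == 2
        assert rep.singleton_variant_ids == ["v000"]

    def test_never_increases_missingness(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        rows[rng.random(rows.shape) < 0.2] = MISSING
        m = make_matrix(rows.tolist())
        out, _ = filter_stringent(m, FilterConfig(max_site_missing=0.5,
                                                  max_sample_missing=0.6))
        kept = [v.id for v in out.variants]
        for s in out.samples:
            i_out, i_in = out.sample_index(s), m.sample_index(s)
            for vid in kept:
                j_out, j_in = out.variant_index(vid), m.variant_index(vid)
                assert out.states[i_out, j_out] == m.states[i_in, j_in]


class TestHaplotypeStrings:
    def test_identical_rows_collapse(self):
        m = make_matrix([[1, 0], [1, 0]])
        _, n = haplotype_strings(m)
        assert n == 1

    def test_str_splits_tips(self):
        m = make_matrix([[1, 0], [1, 0]])
        m.str_alleles["str1"] = np.array([12, 13])
        haps, n = haplotype_strings(m)
        assert n == 2
        assert "[str1=12]" in haps["S1"]

    def test_require_complete_excludes(self):
        m = make_matrix([[1, 0], [1, MISSING]])
        haps, n = haplotype_strings(m, impute_policy="require_complete")
        assert set(haps) == {"S1"} and n == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(12, 9)).astype(np.int8)
        m = make_matrix(rows.tolist())
        _, n = haplotype_strings(m)
        perm_s = rng.permutation(12)
        perm_v = rng.permutation(9)
        m2 = PolarizedMatrix(
            samples=[m.samples[i] for i in perm_s],
            variants=[m.variants[j] for j in perm_v],
            states=m.states[np.ix_(perm_s, perm_v)],
        )
        assert haplotype_strings(m2)[1] == n

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            haplotype_strings(make_matrix([[1]]), impute_policy="bogus")


class TestRoundTrips:
    def test_tsv_round_trip(self, tmp_path):
        m = make_matrix([[1, 0, MISSING], [0, 1, 1]])
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = PolarizedMatrix.from_tsv(p, variants=m.variants)
        assert back.samples == m.samples
        assert [v.id for v in back.variants] == [v.id for v in m.variants]
        np.testing.assert_array_equal(back.states, m.states)

    def test_vcf_round_trip(self, tmp_path):
        m = make_matrix([[1, 0], [0, MISSING]])
        p = tmp_path / "m.vcf"
        write_vcf(m, p)
        am = read_vcf(p)
        assert [v.id for v in am.variants] == ["v000", "v001"]
        np.testing.assert_array_equal(am.calls, m.states)  # ancestral=ref here


class TestVariantValidation:
    def test_bad_pos(self):
        with pytest.raises(ValueError):
            Variant(id="x", contig="Y", pos=0, ref_allele="A", alt_allele="G")

    def test_identical_alleles(self):
        with pytest.raises(ValueError):
            Variant(id="x", contig="Y", pos=1, ref_allele="A", alt_allele="A")

    def test_snp_length(self):
        with pytest.raises(ValueError):
            Variant(id="x", contig="Y", pos=1, ref_allele="AT", alt_allele="G",
                    vclass="SNP")
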