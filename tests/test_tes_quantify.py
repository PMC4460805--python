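"""TES coverage, per-gene fractions, histograms, Fisher exact test."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, fisher_exact as scipy_fisher

from lincte import (
    ContingencyTable,
    GeneModel,
    GenomicInterval,
    RegionClass,
    RegionSet,
    TEAnnotation,
    coverage,
    fisher_exact_two_sided,
    genome_fraction,
    histogram_fractions,
    make_contingency,
    make_contingency_per_class,
    tes_fraction_per_gene,
)
from lincte.io_formats import TEClass

from conftest import fisher_exact_oracle, per_base_coverage_oracle


def _te(s, e, te_id=0, family="LINE/L1", score=1000, chrom="chr1"):
    return TEAnnotation(
        GenomicInterval(chrom, s, e, "+"), score, 10.0, 1.0, 1.0,
        "rep", family, te_id,
    )


def _regions(pairs, chrom="chr1", rc=RegionClass.EXON):
    return RegionSet(rc, {chrom: list(pairs)})


class TestCoverage:
    def test_union_of_overlapping_tes(self):
        res = coverage(_regions([(0, 100)]), [_te(10, 30, 0), _te(20, 50, 1)])
        assert res.te_nt == 40
        assert res.fraction == pytest.approx(0.40)

    def test_no_tes_gives_zero(self):
        res = coverage(_regions([(0, 100)]), [])
        assert res.fraction == 0.0

    def test_empty_region_fraction_is_undefined_not_zero(self):
        res = coverage(_regions([]), [_te(10, 30)])
        assert res.fraction is None

    def test_non_te_records_excluded(self):
        res = coverage(_regions([(0, 100)]), [_te(10, 30, family="Simple_repeat")])
        assert res.te_nt == 0
        res2 = coverage(_regions([(0, 100)]),
                        [_te(10, 30, family="Simple_repeat")],
                        include_non_te=True)
        assert res2.te_nt == 20

    def test_boundary_spanning_te_contributes_overlap_only(self):
        res = coverage(_regions([(50, 100)]), [_te(40, 60)])
        assert res.te_nt == 10

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_r = rng.integers(1, 6)
            n_t = rng.integers(0, 8)
            import lincte.intervals as ivl
            region_pairs = ivl.merge(
                (int(s), int(s + rng.integers(1, 40)))
                for s in rng.integers(0, 150, size=n_r)
            )
            te_pairs = [
                (int(s), int(s + rng.integers(1, 30)))
                for s in rng.integers(0, 150, size=n_t)
            ]
            tes = [_te(s, e, i) for i, (s, e) in enumerate(te_pairs)]
            got = coverage(_regions(region_pairs), tes).te_nt
            assert got == per_base_coverage_oracle(region_pairs, te_pairs)

    def test_monotone_in_te_additions(self):
        rng = np.random.default_rng(7)
        tes = []
        prev = 0
        regions = _regions([(0, 500)])
        for i in range(20):
            s = int(rng.integers(0, 480))
            tes.append(_te(s, s + int(rng.integers(1, 20)), i))
            cur = coverage(regions, tes).te_nt
            assert cur >= prev
            prev = cur

    def test_scale_invariance_on_duplicated_chromosome(self):
        regions = RegionSet(RegionClass.EXON,
                            {"chr1": [(0, 100)], "chr2": [(0, 100)]})
        tes = [_te(10, 40, 0, chrom="chr1"), _te(10, 40, 1, chrom="chr2")]
        res = coverage(regions, tes)
        single = coverage(_regions([(0, 100)]), [_te(10, 40, 0)])
        assert res.te_nt == 2 * single.te_nt
        assert res.fraction == single.fraction

    def test_per_class_attribution_by_score(self):
        # SINE outscores LINE on the shared 10 bases
        tes = [_te(0, 30, 0, "LINE/L1", score=500),
               _te(20, 50, 1, "SINE/Alu", score=900)]
        res = coverage(_regions([(0, 100)]), tes)
        assert res.per_class_nt[TEClass.SINE] == 30
        assert res.per_class_nt[TEClass.LINE] == 20
        assert sum(res.per_class_nt.values()) == res.te_nt

    def test_per_class_tie_goes_to_earlier_record(self):
        tes = [_te(0, 30, 0, "LINE/L1", score=700),
               _te(20, 50, 1, "SINE/Alu", score=700)]
        res = coverage(_regions([(0, 100)]), tes)
        assert res.per_class_nt[TEClass.LINE] == 30
        assert res.per_class_nt[TEClass.SINE] == 20


class TestPerGeneFraction:
    def _gene(self, exon_pairs):
        return GeneModel("g", "chr1", "+", tuple(
            GenomicInterval("chr1", s, e, "+") for s, e in exon_pairs
        ))

    def test_quarter_covered(self):
        g = self._gene([(0, 400), (1000, 1600)])  # mature 1000
        assert tes_fraction_per_gene(g, [_te(100, 350)]) == pytest.approx(0.25)

    def test_intronic_te_contributes_nothing(self):
        g = self._gene([(0, 400), (1000, 1600)])
        assert tes_fraction_per_gene(g, [_te(500, 900)]) == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            exons = []
            pos = 0
            for _e in range(3):
                pos += int(rng.integers(1, 200))
                L = int(rng.integers(10, 80))
                exons.append((pos, pos + L))
                pos += L
            g = self._gene(exons)
            te_pairs = [
                (int(s), int(s + rng.integers(5, 100)))
                for s in rng.integers(0, 2000, size=5)
            ]
            tes = [_te(s, e, i) for i, (s, e) in enumerate(te_pairs)]
            expect = per_base_coverage_oracle(exons, te_pairs) / g.mature_length
            assert tes_fraction_per_gene(g, tes) == pytest.approx(expect)


class TestHistogram:
    def test_basic_binning(self):
        assert histogram_fractions([0.1, 0.15, 0.5]) == [2, 0, 1, 0, 0]

    def test_last_bin_closed_at_one(self):
        assert histogram_fractions([1.0]) == [0, 0, 0, 0, 1]

    def test_empty_input(self):
        assert histogram_fractions([]) == [0, 0, 0, 0, 0]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            histogram_fractions([1.2])


class TestContingency:
    def test_te_vs_free_counts(self):
        cov_a = CovStub(100, 40)
        cov_b = CovStub(100, 10)
        t = make_contingency(cov_a, cov_b)
        assert (t.a, t.b, t.c, t.d) == (40, 60, 10, 90)

    def test_identical_inputs_identical_rows(self):
        c = CovStub(100, 25)
        t = make_contingency(c, c)
        assert (t.a, t.b) == (t.c, t.d)

    def test_per_class_variant_uses_class_nt(self):
        cov = coverage(_regions([(0, 100)]),
                       [_te(0, 30, 0, "SINE/Alu"), _te(50, 70, 1, "LINE/L1")])
        t = make_contingency_per_class(cov, TEClass.SINE, TEClass.LINE)
        assert (t.a, t.b, t.c, t.d) == (30, 50, 20, 50)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class CovStub:
    def __init__(self, total, te):
        self.total_nt, self.te_nt = total, te


class TestFisherExact:
    def test_diagonal_table(self):
        p = fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_modal_table_p_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(10, 90, 10, 90)) == 1.0

    def test_zero_margin_convention(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0
        assert fisher_exact_two_sided(ContingencyTable(0, 3, 0, 4)) == 1.0

    def test_matches_exact_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            got = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            want = float(fisher_exact_oracle(a, b, c, d))
            assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            want = scipy_fisher([[a, b], [c, d]]).pvalue
            assert got == pytest.approx(float(want), rel=1e-6)

    def test_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4) + 1)
            p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(
                fisher_exact_two_sided(ContingencyTable(c, d, a, b)), rel=1e-9)
            assert p == pytest.approx(
                fisher_exact_two_sided(ContingencyTable(b, a, d, c)), rel=1e-9)

    def test_chi_square_same_order_of_magnitude_on_large_tables(self):
        t = ContingencyTable(400, 600, 300, 700)
        p_f = fisher_exact_two_sided(t)
        p_c = chi2_contingency([[400, 600], [300, 700]]).pvalue
        assert abs(np.log10(p_f) - np.log10(p_c)) < 1.0


class TestGenomeFraction:
    def test_no_tes(self):
        frac, per = genome_fraction([], 1000)
        assert frac == 0.0 and per == {}

    def test_single_te(self):
        frac, per = genome_fraction([_te(100, 300)], 10_000)
        assert frac == pytest.approx(0.02)
        assert per[TEClass.LINE] == pytest.approx(0.02)

    def test_matches_per_base_oracle_on_synthetic_genome(self):
        rng = np.random.default_rng(5)
        te_pairs = [
            (int(s), int(s + rng.integers(20, 200)))
            for s in rng.integers(0, 9500, size=40)
        ]
        tes = [_te(s, e, i) for i, (s, e) in enumerate(te_pairs)]
        frac, _ = genome_fraction(tes, 10_000)
        assert frac == pytest.approx(
            per_base_coverage_oracle([(0, 10_000)], te_pairs) / 10_000)
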