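"""The generator's planted-truth contracts: determinism, density recovery,
ortholog structure, expression correlation."""

import math

import numpy as np
import pytest

from lincte import (
    AnalysisParams,
    BlockIndex,
    RegionClass,
    SimConfig,
    build_region_sets,
    coverage,
    parse_repeatmasker_out,
    project_te_alignment,
    select_intergenic_lincRNAs,
    simulate_expression,
    simulate_genome_annotation,
    simulate_ortholog_alignments,
    tes_fraction_per_gene,
)
from lincte.association import ExpressionRecord, median_log2_expression


def _region_sets(sim, params):
    linc = select_intergenic_lincRNAs(sim.linc_genes, sim.pc_genes, params)
    return linc, build_region_sets(linc, params, sim.chrom_lens)


class TestGenomeAnnotation:
    def test_zero_density_plants_nothing(self):
        cfg = SimConfig(seed=1, n_linc_genes=10, n_pc_genes=2,
                        te_density={})
        sim = simulate_genome_annotation(cfg)
        assert sim.tes == []
        assert len(sim.truth) == 0

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_linc_genes=15, n_pc_genes=4)
        for sub in ("a", "b"):
            simulate_genome_annotation(cfg).write(tmp_path / sub)
        for name in ("genome.fa", "linc.bed", "pc.bed", "te.out", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_genome_annotation(SimConfig(seed=1, n_linc_genes=10,
                                                 n_pc_genes=2))
        b = simulate_genome_annotation(SimConfig(seed=2, n_linc_genes=10,
                                                 n_pc_genes=2))
        assert a.genome != b.genome

    def test_out_file_round_trips_planted_intervals(self, tmp_path,
                                                    small_sim):
        _cfg, sim, _ = small_sim
        sim.write(tmp_path)
        with open(tmp_path / "te.out", encoding="utf-8") as fh:
            parsed = parse_repeatmasker_out(fh)
        got = [(t.interval.chrom, t.interval.start, t.interval.end)
               for t in parsed]
        want = list(sim.truth[["chrom", "start", "end"]].itertuples(
            index=False, name=None))
        assert got == want

    def test_planted_tes_are_nonoverlapping(self, small_sim):
        _cfg, sim, _ = small_sim
        t = sim.truth.sort_values(["chrom", "start"])
        for chrom, grp in t.groupby("chrom"):
            ends = grp.end.to_numpy()
            starts = grp.start.to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_planted_densities_recovered(self, small_sim, params):
        """Coverage measured by the quantifier matches the configured
        per-compartment densities within 3 binomial SE."""
        cfg, sim, _ = small_sim
        _linc, rs = _region_sets(sim, params)
        for rc, want in ((RegionClass.PROMOTER, 0.10),
                         (RegionClass.EXON, 0.20),
                         (RegionClass.INTRON, 0.35)):
            cov = coverage(rs[rc], sim.tes)
            se = math.sqrt(want * (1 - want) / cov.total_nt)
            assert abs(cov.fraction - want) < 3 * se, rc

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(te_density={"EXON": {"LINE": 0.6, "SINE": 0.5}})

    def test_tata_planted_at_configured_rate(self, params):
        cfg = SimConfig(seed=21, n_linc_genes=120, n_pc_genes=10,
                        te_density={}, tata_frac=0.3)
        sim = simulate_genome_annotation(cfg)
        from lincte import extract_promoters, tata_containing_fraction

        promoters = extract_promoters(sim.linc_genes, sim.genome, params)
        frac = tata_containing_fraction(promoters)
        se = math.sqrt(0.3 * 0.7 / len(promoters))
        assert abs(frac - 0.3) < 3 * se + 0.02


class TestOrthologAlignments:
    def test_no_mutation_no_gap_classifies_every_ancient_te(self, params):
        cfg = SimConfig(seed=5, n_linc_genes=25, n_pc_genes=5,
                        ortho_P=0.0, ortho_Q=0.0, ancient_gap_frac=0.0)
        sim = simulate_genome_annotation(cfg)
        idx = BlockIndex(simulate_ortholog_alignments(cfg, sim))
        anc = sim.truth[sim.truth.ancient]
        by_id = {t.te_id: t for t in sim.tes}
        for r in anc.itertuples():
            aln = project_te_alignment(by_id[r.te_id], idx)
            assert aln is not None
            assert aln.indel_fraction == 0.0
            assert aln.columns == r.length
            assert aln.columns > params.ancient_min_cols

    def test_lineage_specific_tes_project_absent(self, small_sim):
        _cfg, sim, blocks = small_sim
        idx = BlockIndex(blocks)
        by_id = {t.te_id: t for t in sim.tes}
        lineage = sim.truth[~sim.truth.ancient]
        # lineage TEs inside exons are carved out of the exon blocks too
        for r in lineage.head(40).itertuples():
            assert project_te_alignment(by_id[r.te_id], idx) is None

    def test_same_seed_alignments_identical(self):
        cfg = SimConfig(seed=6, n_linc_genes=12, n_pc_genes=3)
        sim = simulate_genome_annotation(cfg)
        b1 = simulate_ortholog_alignments(cfg, sim)
        b2 = simulate_ortholog_alignments(cfg, sim)
        assert b1 == b2

    def test_substitution_rates_recovered_in_exons(self, small_sim, params):
        """Pooled site patterns over all genes estimate (P, Q) = (0.1, 0.05)."""
        from lincte.evodist import count_site_patterns
        from lincte.ancient_te import project_interval_alignment

        _cfg, sim, blocks = small_sim
        idx = BlockIndex(blocks)
        n = ts = tv = 0
        for g in sim.linc_genes:
            for e in g.exons:
                aln = project_interval_alignment(e, idx)
                if aln is None:
                    continue
                c = count_site_patterns(aln.ref_gapped, aln.query_gapped)
                n, ts, tv = n + c.n, ts + c.ts, tv + c.tv
        assert n > 10_000
        assert abs(ts / n - 0.1) < 3 * math.sqrt(0.1 * 0.9 / n)
        assert abs(tv / n - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n)


class TestExpression:
    @staticmethod
    def _fractions(n, seed):
        rng = np.random.default_rng(seed)
        return {f"g{i}": float(f) for i, f in enumerate(rng.beta(2, 5, n))}

    def test_zero_rho_gives_near_zero_correlation(self):
        cfg = SimConfig(seed=3, expr_rho=0.0)
        fr = self._fractions(2000, 100)
        arr, _ = simulate_expression(cfg, fr)
        tissue_cols = [c for c in arr.columns if c != "gene_id"]
        summ = np.median(np.log2(arr[tissue_cols].to_numpy()), axis=1)
        r = np.corrcoef(list(fr.values()), summ)[0, 1]
        assert abs(r) < 0.07

    def test_planted_negative_rho_recovered(self):
        cfg = SimConfig(seed=4, expr_rho=-0.25)
        fr = self._fractions(2000, 101)
        arr, counts = simulate_expression(cfg, fr)
        tissue_cols = [c for c in arr.columns if c != "gene_id"]
        summ = np.median(np.log2(arr[tissue_cols].to_numpy()), axis=1)
        r = np.corrcoef(list(fr.values()), summ)[0, 1]
        assert abs(r - (-0.25)) < 0.07
        # RNA-seq counts carry the same ordering (sign check only)
        lib = counts["count"].sum()
        rpkms = 1e9 * counts["count"] / (lib * counts["length"])
        r2 = np.corrcoef(list(fr.values()), np.log2(rpkms + 1e-9))[0, 1]
        assert r2 < 0

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(seed=5)
        fr = self._fractions(50, 102)
        a1, c1 = simulate_expression(cfg, fr)
        a2, c2 = simulate_expression(cfg, fr)
        assert a1.equals(a2) and c1.equals(c2)

    def test_extreme_rho_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(expr_rho=1.0)


class TestEndToEndIdentifiability:
    def test_density_ordering_preserved_with_significance(self, small_sim,
                                                          params):
        """Planted intron > exon > promoter densities must come out of the
        full quantification with Fisher support."""
        from lincte import fisher_exact_two_sided, make_contingency

        _cfg, sim, _ = small_sim
        _linc, rs = _region_sets(sim, params)
        covs = {rc: coverage(rs[rc], sim.tes) for rc in RegionClass}
        assert covs[RegionClass.INTRON].fraction > \
            covs[RegionClass.EXON].fraction > \
            covs[RegionClass.PROMOTER].fraction
        for rc in (RegionClass.PROMOTER, RegionClass.EXON):
            p = fisher_exact_two_sided(
                make_contingency(covs[rc], covs[RegionClass.INTRON]))
            assert p < 1e-5
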