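"""End-to-end orchestration: simulate (or load) inputs, partition genes,
quantify TES, classify ancient elements, estimate evolutionary rates,
correlate, scan promoters, and emit one report directory.

The report mirrors the analysis figures: compartment TES fractions with
pairwise Fisher tests, per-TE-class fractions, TES-rate and TES-expression
correlations, ancient-TE fractions under both thresholds, the per-gene TES
histogram, and the TATA positional profile. ``manifest.json`` snapshots the
config, seed, input digests and per-stage row counts; it contains nothing
volatile, so a rerun with the same config and seed reproduces the report
directory byte for byte (stage timings go to the log instead).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancient_te import (
    BlockIndex,
    ancient_fraction_by_region,
    assign_region_class,
    classify_ancient,
    project_te_alignment,
)
from .association import (
    ExpressionRecord,
    median_log2_expression,
    rpkm,
    run_association,
)
from .evodist import gene_evolutionary_rate
from .gene_partition import (
    AnalysisParams,
    RegionClass,
    build_region_sets,
    select_intergenic_lincRNAs,
)
from .io_formats import (
    TEClass,
    parse_bed12,
    parse_maf,
    parse_repeatmasker_out,
    read_fasta,
    write_report_tsv,
)
from .promoter_scan import (
    extract_promoters,
    tata_containing_fraction,
    tata_positional_profile,
)
from .synthetic_data import (
    SimConfig,
    simulate_expression,
    simulate_genome_annotation,
    simulate_ortholog_alignments,
)
from .tes_quantify import (
    coverage,
    fisher_exact_two_sided,
    genome_fraction,
    histogram_fractions,
    make_contingency,
    make_contingency_per_class,
    tes_fraction_per_gene,
)

logger = logging.getLogger(__name__)

__all__ = ["run_full", "load_config"]

_REPORT_FILES = (
    "fig1_fractions.tsv",
    "fig34_classes.tsv",
    "fig2_correlation.tsv",
    "figS2_expression.tsv",
    "fig5_ancient.tsv",
    "figS1_histogram.tsv",
    "figS3_tata.tsv",
    "manifest.json",
)

_N_FISHER_TESTS = 2  # promoter-vs-intron and exon-vs-intron per family


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager logging a stage's wall time and recording row counts."""

    def __init__(self, manifest: dict, name: str) -> None:
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def count(self, **counts) -> None:
        self.manifest["stages"].setdefault(self.name, {}).update(counts)

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s failed after %.1fs: %s", self.name, dt, exc)
            return False
        logger.info("stage %s: done in %.1fs", self.name, dt)
        return False


def _load_inputs(config: dict, outdir: Path):
    """Either run the synthetic generator or read the configured files.
    Returns (genome, linc_candidates, pc_genes, tes, blocks, expr_array,
    expr_counts, input_digests)."""
    if config.get("mode", "synthetic") == "synthetic":
        sim_kwargs = dict(config.get("sim", {}))
        sim_kwargs.setdefault("seed", int(config.get("seed", 0)))
        if "exons_per_gene" in sim_kwargs:
            sim_kwargs["exons_per_gene"] = tuple(sim_kwargs["exons_per_gene"])
        for key in ("exon_len", "intron_len", "te_len"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        cfg = SimConfig(**sim_kwargs)
        sim = simulate_genome_annotation(cfg)
        blocks = simulate_ortholog_alignments(cfg, sim)
        return sim, cfg, sim.genome, sim.linc_genes, sim.pc_genes, sim.tes, blocks, {}
    paths = config["inputs"]
    genome = read_fasta(paths["genome_fa"])
    with open(paths["linc_bed"], encoding="utf-8") as fh:
        linc = parse_bed12(fh)
    with open(paths["pc_bed"], encoding="utf-8") as fh:
        pc = parse_bed12(fh)
    with open(paths["te_out"], encoding="utf-8") as fh:
        tes = parse_repeatmasker_out(fh)
    with open(paths["maf"], encoding="utf-8") as fh:
        blocks = parse_maf(fh)
    digests = {k: _sha256(Path(v)) for k, v in paths.items()}
    return None, None, genome, linc, pc, tes, blocks, digests


def run_full(config: dict, outdir) -> Path:
    """Run every stage and write the report directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = AnalysisParams(**config.get("params", {}))
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "tool_version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    with _Stage(manifest, "inputs") as st:
        (sim, sim_cfg, genome, linc_cand, pc, tes, blocks,
         digests) = _load_inputs(config, outdir)
        manifest["inputs"] = digests
        st.count(linc_candidates=len(linc_cand), pc_genes=len(pc),
                 te_records=len(tes), alignment_blocks=len(blocks))

    with _Stage(manifest, "partition") as st:
        chrom_lens = {c: len(s) for c, s in genome.items()}
        linc = select_intergenic_lincRNAs(linc_cand, pc, params)
        region_sets = build_region_sets(linc, params, chrom_lens)
        st.count(linc_kept=len(linc), **{
            rc.value.lower() + "_nt": region_sets[rc].total_nt
            for rc in RegionClass
        })

    with _Stage(manifest, "quantify") as st:
        covs = {
            rc: coverage(region_sets[rc], tes,
                         include_non_te=params.include_non_te)
            for rc in RegionClass
        }
        fisher_p = {}
        for rc in (RegionClass.PROMOTER, RegionClass.EXON):
            fisher_p[rc] = fisher_exact_two_sided(
                make_contingency(covs[rc], covs[RegionClass.INTRON])
            )
        rows = []
        for rc in RegionClass:
            c = covs[rc]
            p = fisher_p.get(rc)
            rows.append((
                rc.value, c.total_nt, c.te_nt,
                c.fraction if c.fraction is not None else float("nan"),
                p if p is not None else float("nan"),
                min(1.0, p * _N_FISHER_TESTS) if p is not None else float("nan"),
            ))
        write_report_tsv(
            rows, outdir / "fig1_fractions.tsv",
            header=["region_class", "total_nt", "te_nt", "fraction",
                    "fisher_p_vs_intron", "fisher_p_vs_intron_bonferroni"],
        )

        genome_nt = sum(chrom_lens.values())
        g_frac, g_per_class = genome_fraction(
            tes, genome_nt, include_non_te=params.include_non_te
        )
        cls_order = [TEClass.LINE, TEClass.SINE, TEClass.LTR, TEClass.DNA,
                     TEClass.OTHER]
        rows = []
        for rc in RegionClass:
            c = covs[rc]
            p_sl = fisher_exact_two_sided(
                make_contingency_per_class(c, TEClass.SINE, TEClass.LINE)
            )
            p_ll = fisher_exact_two_sided(
                make_contingency_per_class(c, TEClass.LTR, TEClass.LINE)
            )
            rows.append(
                [rc.value, c.total_nt]
                + [c.class_fraction(k) or 0.0 for k in cls_order]
                + [p_sl, p_ll]
            )
        rows.append(
            ["GENOME", genome_nt]
            + [g_per_class.get(k, 0.0) for k in cls_order]
            + [float("nan"), float("nan")]
        )
        write_report_tsv(
            rows, outdir / "fig34_classes.tsv",
            header=["region_class", "total_nt"]
            + [f"frac_{k.value}" for k in cls_order]
            + ["fisher_p_SINE_vs_LINE", "fisher_p_LTR_vs_LINE"],
        )
        st.count(genome_nt=genome_nt)

        fractions = {
            g.gene_id: tes_fraction_per_gene(
                g, tes, include_non_te=params.include_non_te
            )
            for g in linc
        }
        counts = histogram_fractions(list(fractions.values()), params)
        width = params.histogram_bin
        write_report_tsv(
            [(round(i * width, 6), round((i + 1) * width, 6), c)
             for i, c in enumerate(counts)],
            outdir / "figS1_histogram.tsv",
            header=["bin_low", "bin_high", "count"],
        )

    with _Stage(manifest, "ancient") as st:
        index = BlockIndex(blocks)
        calls = []
        for te in tes:
            if te.te_class is TEClass.NON_TE and not params.include_non_te:
                continue
            rc = assign_region_class(te, region_sets)
            if rc is None:
                continue
            aln = project_te_alignment(te, index)
            calls.append(classify_ancient(aln, rc, params, te_id=te.te_id))
        rows = []
        for mode in ("stringent", "relaxed"):
            res = ancient_fraction_by_region(calls, mode)
            for rc in RegionClass:
                anc, lin, frac = res["by_class"][rc]
                p = res["fisher"].get(f"{rc.value}_vs_INTRON", float("nan"))
                rows.append((
                    mode, rc.value, anc, lin,
                    frac if frac is not None else float("nan"), p,
                ))
        write_report_tsv(
            rows, outdir / "fig5_ancient.tsv",
            header=["mode", "region_class", "ancient", "lineage_specific",
                    "fraction_ancient", "fisher_p_vs_intron"],
        )
        st.count(te_calls=len(calls))

    with _Stage(manifest, "rates") as st:
        rates = {}
        for g in linc:
            res = gene_evolutionary_rate(g, index, params)
            if res is not None and res.defined:
                rates[g.gene_id] = res.d
        st.count(genes_with_rate=len(rates))

    with _Stage(manifest, "associate") as st:
        if sim_cfg is not None:
            lengths = {g.gene_id: g.mature_length for g in linc}
            expr_array, expr_counts = simulate_expression(
                sim_cfg, fractions, lengths
            )
        else:
            expr_array = expr_counts = None
            ep = config.get("inputs", {})
            if "expr_array_tsv" in ep:
                expr_array = pd.read_csv(ep["expr_array_tsv"], sep="\t")
            if "expr_counts_tsv" in ep:
                expr_counts = pd.read_csv(ep["expr_counts_tsv"], sep="\t")

        table = pd.DataFrame({
            "gene_id": list(fractions),
            "tes_fraction": list(fractions.values()),
        })
        table["evo_rate"] = table["gene_id"].map(rates)
        rate_rep = run_association(table[["gene_id", "tes_fraction",
                                          "evo_rate"]])
        write_report_tsv(rate_rep, outdir / "fig2_correlation.tsv")

        expr_rows = []
        if expr_array is not None:
            tissue_cols = [c for c in expr_array.columns if c != "gene_id"]
            summary = {
                r.gene_id: median_log2_expression(ExpressionRecord(
                    r.gene_id,
                    tissue_values=tuple(getattr(r, c) for c in tissue_cols),
                ))
                for r in expr_array.itertuples(index=False)
            }
            tab = table[["gene_id", "tes_fraction"]].copy()
            tab["expression_summary"] = tab["gene_id"].map(summary)
            rep = run_association(tab)
            for r in rep.itertuples(index=False):
                expr_rows.append(("microarray", r.n, r.r, r.p))
        if expr_counts is not None:
            lib = int(expr_counts["count"].sum())
            summary = {
                r.gene_id: rpkm(ExpressionRecord(
                    r.gene_id, read_count=int(r.count),
                    gene_length_nt=int(r.length), library_size=lib,
                ))
                for r in expr_counts.itertuples(index=False)
            }
            tab = table[["gene_id", "tes_fraction"]].copy()
            tab["expression_summary"] = np.log2(
                tab["gene_id"].map(summary) + 1e-9
            )
            rep = run_association(tab)
            for r in rep.itertuples(index=False):
                expr_rows.append(("rnaseq_rpkm", r.n, r.r, r.p))
        write_report_tsv(
            expr_rows, outdir / "figS2_expression.tsv",
            header=["assay", "n", "r", "p"],
        )
        st.count(expr_pairings=len(expr_rows))

    with _Stage(manifest, "tata") as st:
        promoters = extract_promoters(linc, genome, params)
        rows = []
        if promoters:
            profile = tata_positional_profile(promoters)
            for off in sorted(profile):
                rows.append((off, profile[off]))
            frac = tata_containing_fraction(promoters, params)
            rows.append(("FRACTION_TATA_CONTAINING", frac))
        write_report_tsv(
            rows, outdir / "figS3_tata.tsv", header=["offset", "frequency"]
        )
        st.count(promoters=len(promoters))

    for name in _REPORT_FILES:
        if name != "manifest.json":
            manifest["outputs"][name] = _sha256(outdir / name)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return outdir
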