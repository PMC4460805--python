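"""Gene-architecture partitioning: promoters, exons, introns and the
intergenic-lincRNA selection filters.

A lincRNA here is an intergenic non-coding transcript of mature length at
least 200 nt whose genomic span overlaps no protein-coding gene span. The
analysis compartments are the concatenated core promoters (100 bp upstream
of the TSS, strand-aware), exons, and introns of the retained genes; a base
falling into more than one compartment across genes is assigned once, with
precedence EXON > INTRON > PROMOTER, so the Fisher denominators never double
count a nucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from . import intervals as iv
from .io_formats import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "RegionClass",
    "RegionSet",
    "AnalysisParams",
    "derive_introns",
    "derive_promoter",
    "select_intergenic_lincRNAs",
    "build_region_sets",
    "region_sets_to_bed6",
]


class RegionClass(Enum):
    PROMOTER = "PROMOTER"
    EXON = "EXON"
    INTRON = "INTRON"


@dataclass(frozen=True)
class RegionSet:
    """Merged, disjoint intervals of one analysis compartment."""

    region_class: RegionClass
    intervals: dict  # chrom -> sorted disjoint (start, end) pairs

    @property
    def total_nt(self) -> int:
        return iv.by_chrom_total(self.intervals)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis thresholds, all in the units noted.

    promoter_len
        Core promoter size in nt upstream of the TSS (default 100).
    min_linc_len
        Minimum mature (spliced) lincRNA length in nt; shorter candidates
        are removed (default 200, strict "shorter than").
    ancient_min_cols
        Minimum alignment columns for an ancient call; strict "longer
        than" (default 100).
    ancient_max_indel_stringent / ancient_max_indel_relaxed
        Gap-column fraction bounds: stringent is strict (< 0.05), relaxed
        inclusive (<= 0.25).
    tata_region
        Offset window (relative to TSS) in which a TATA match start counts
        a promoter as TATA-containing (default -35..-25).
    histogram_bin
        Width of per-gene TES-fraction histogram bins (default 0.2).
    low_conf_sites
        Comparable-site count below which a per-gene evolutionary rate is
        flagged low-confidence (default 50).
    include_non_te
        Whether simple repeats / low-complexity records count as TES
        (default False: only transposable elements are counted).
    """

    promoter_len: int = 100
    min_linc_len: int = 200
    ancient_min_cols: int = 100
    ancient_max_indel_stringent: float = 0.05
    ancient_max_indel_relaxed: float = 0.25
    tata_region: tuple[int, int] = (-35, -25)
    histogram_bin: float = 0.2
    low_conf_sites: int = 50
    include_non_te: bool = False

    def __post_init__(self) -> None:
        if self.promoter_len <= 0 or self.min_linc_len <= 0:
            raise ValueError("lengths must be positive")
        if self.ancient_max_indel_stringent > self.ancient_max_indel_relaxed:
            raise ValueError("stringent indel bound must not exceed relaxed")


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Intervals between adjacent exons; empty for single-exon genes."""
    out = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if b.start > a.end:
            out.append(GenomicInterval(gene.chrom, a.end, b.start, gene.strand))
    return out


def derive_promoter(gene: GeneModel, params: AnalysisParams,
                    chrom_len: int) -> GenomicInterval | None:
    """The core promoter immediately upstream of the TSS, clipped to the
    chromosome; ``None`` (gene flagged in the log) if fully off-chromosome."""
    L = params.promoter_len
    if gene.strand == "+":
        tss = gene.exons[0].start
        start, end = max(0, tss - L), tss
    else:
        tss = gene.exons[-1].end
        start, end = tss, min(chrom_len, tss + L)
    if start >= end:
        logger.warning("gene %s: promoter fully off-chromosome", gene.gene_id)
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def select_intergenic_lincRNAs(candidates: Sequence[GeneModel],
                               pc_genes: Sequence[GeneModel],
                               params: AnalysisParams) -> list[GeneModel]:
    """Keep candidates that lie between protein-coding genes and whose
    mature (spliced) length reaches ``min_linc_len``.

    Intergenicity is a span test: any overlap between a candidate's genomic
    span and any protein-coding gene span excludes the candidate.
    Overlaps among candidates themselves are logged but kept.
    """
    pc_spans = iv.merge_by_chrom(
        (g.chrom, g.span.start, g.span.end) for g in pc_genes
    )
    kept: list[GeneModel] = []
    n_short = n_genic = 0
    for g in candidates:
        if g.mature_length < params.min_linc_len:
            n_short += 1
            continue
        span = [(g.span.start, g.span.end)]
        if iv.overlap_length(span, pc_spans.get(g.chrom, [])) > 0:
            n_genic += 1
            continue
        kept.append(g)
    # candidates overlapping each other are retained; flag for auditability
    spans = sorted((g.chrom, g.span.start, g.span.end) for g in kept)
    n_mutual = sum(
        1 for a, b in zip(spans, spans[1:]) if a[0] == b[0] and b[1] < a[2]
    )
    logger.info(
        "lincRNA selection: %d kept, %d removed (<%d nt), %d removed "
        "(overlap protein-coding span), %d mutually overlapping kept",
        len(kept), n_short, params.min_linc_len, n_genic, n_mutual,
    )
    return kept


def build_region_sets(genes: Sequence[GeneModel], params: AnalysisParams,
                      chrom_lens: Mapping[str, int]
                      ) -> dict[RegionClass, RegionSet]:
    """Union the per-gene promoters/exons/introns over all genes and resolve
    cross-gene conflicts so every base belongs to exactly one compartment
    (EXON > INTRON > PROMOTER)."""
    exon = iv.merge_by_chrom(
        (e.chrom, e.start, e.end) for g in genes for e in g.exons
    )
    intron_raw = iv.merge_by_chrom(
        (i.chrom, i.start, i.end) for g in genes for i in derive_introns(g)
    )
    prom_list = []
    for g in genes:
        p = derive_promoter(g, params, chrom_lens[g.chrom])
        if p is not None:
            prom_list.append((p.chrom, p.start, p.end))
    prom_raw = iv.merge_by_chrom(prom_list)

    intron = {
        c: iv.subtract(pairs, exon.get(c, []))
        for c, pairs in intron_raw.items()
    }
    prom = {
        c: iv.subtract(
            iv.subtract(pairs, exon.get(c, [])), intron.get(c, [])
        )
        for c, pairs in prom_raw.items()
    }
    return {
        RegionClass.EXON: RegionSet(RegionClass.EXON, exon),
        RegionClass.INTRON: RegionSet(RegionClass.INTRON, intron),
        RegionClass.PROMOTER: RegionSet(RegionClass.PROMOTER, prom),
    }


def region_sets_to_bed6(region_sets: Mapping[RegionClass, RegionSet]) -> str:
    """Serialize region sets as BED6 text with the class in the name column."""
    lines = []
    for rc in RegionClass:
        rs = region_sets[rc]
        for chrom in sorted(rs.intervals):
            for s, e in rs.intervals[chrom]:
                lines.append(f"{chrom}\t{s}\t{e}\t{rc.value}\t0\t.")
    return "\n".join(lines) + ("\n" if lines else "")
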