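"""Nucleotide-level quantification of TE-derived sequence (TES).

Coverage is computed as an interval union — overlapping repeat records never
double-count a base, so ``te_nt <= total_nt`` always holds. Per-TE-class
attribution of bases shared between overlapping records of different classes
goes to the higher Smith-Waterman score (ties to the earlier record), the
same preference RepeatMasker itself applies.

Enrichment between compartments is tested with the two-sided Fisher exact
test on 2x2 tables of TES vs. TE-free nucleotide counts, using the
probability-mass definition: the p-value sums hypergeometric probabilities
of all tables sharing the margins whose probability does not exceed the
observed one (relative tie tolerance 1e-7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from . import intervals as iv
from .gene_partition import AnalysisParams, RegionClass, RegionSet
from .io_formats import GeneModel, TEAnnotation, TEClass

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageResult",
    "ContingencyTable",
    "coverage",
    "tes_fraction_per_gene",
    "histogram_fractions",
    "make_contingency",
    "make_contingency_per_class",
    "fisher_exact_two_sided",
    "fisher_exact_log10p",
    "genome_fraction",
]

#: Smallest reportable p-value: nucleotide-scale tables routinely produce
#: probabilities below double-precision range; the log-space sum is floored
#: here so the (0, 1] contract survives underflow.
_MIN_P = 5e-324


@dataclass(frozen=True)
class CoverageResult:
    """TES accounting for one compartment.

    ``fraction`` is ``None`` (undefined, distinct from 0) when the
    compartment is empty.
    """

    region_class: RegionClass | None
    total_nt: int
    te_nt: int
    per_class_nt: dict

    @property
    def fraction(self) -> float | None:
        if self.total_nt == 0:
            return None
        return self.te_nt / self.total_nt

    def class_fraction(self, te_class: TEClass) -> float | None:
        if self.total_nt == 0:
            return None
        return self.per_class_nt.get(te_class, 0) / self.total_nt


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are the two groups, columns (in-category, not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have a positive count")


def _active_tes(tes: Sequence[TEAnnotation],
                te_class_filter: TEClass | None = None,
                include_non_te: bool = False) -> list[TEAnnotation]:
    out = []
    for te in tes:
        if te.te_class is TEClass.NON_TE and not include_non_te:
            continue
        if te_class_filter is not None and te.te_class is not te_class_filter:
            continue
        out.append(te)
    return out


def coverage(regions: RegionSet, tes: Sequence[TEAnnotation],
             te_class_filter: TEClass | None = None,
             include_non_te: bool = False,
             per_class_union: bool = True) -> CoverageResult:
    """Union TES coverage of a compartment, overall and per TE class.

    ``per_class_union=True`` (default) resolves bases covered by records of
    different classes to a single class by score; ``False`` counts each
    class's own union independently (per-class totals may then exceed
    ``te_nt`` where classes overlap).
    """
    active = _active_tes(tes, te_class_filter, include_non_te)
    region_iv = regions.intervals
    all_te = iv.merge_by_chrom(
        (t.interval.chrom, t.interval.start, t.interval.end) for t in active
    )
    te_nt = iv.by_chrom_overlap_length(all_te, region_iv)

    per_class: dict[TEClass, int] = {}
    if per_class_union:
        claimed: dict[str, list] = {}
        for te in sorted(active, key=lambda t: (-t.sw_score, t.te_id)):
            c = te.interval.chrom
            mine = iv.subtract(
                [(te.interval.start, te.interval.end)], claimed.get(c, [])
            )
            got = iv.overlap_length(mine, region_iv.get(c, []))
            if got:
                per_class[te.te_class] = per_class.get(te.te_class, 0) + got
            claimed[c] = iv.merge(claimed.get(c, []) + mine)
    else:
        for cls in TEClass:
            sub = [t for t in active if t.te_class is cls]
            if not sub:
                continue
            u = iv.merge_by_chrom(
                (t.interval.chrom, t.interval.start, t.interval.end)
                for t in sub
            )
            n = iv.by_chrom_overlap_length(u, region_iv)
            if n:
                per_class[cls] = n

    total = regions.total_nt
    if total == 0:
        logger.warning("coverage over empty compartment %s", regions.region_class)
    return CoverageResult(regions.region_class, total, te_nt, per_class)


def tes_fraction_per_gene(gene: GeneModel, tes: Sequence[TEAnnotation],
                          include_non_te: bool = False) -> float:
    """Union TES coverage of the gene's exons over its mature length."""
    exon_iv = {gene.chrom: iv.merge((e.start, e.end) for e in gene.exons)}
    active = _active_tes(tes, include_non_te=include_non_te)
    te_iv = iv.merge_by_chrom(
        (t.interval.chrom, t.interval.start, t.interval.end) for t in active
    )
    return iv.by_chrom_overlap_length(te_iv, exon_iv) / gene.mature_length


def histogram_fractions(fractions: Sequence[float],
                        params: AnalysisParams | None = None) -> list[int]:
    """Bin per-gene TES fractions into [0,b), [b,2b), ..., last bin closed."""
    width = params.histogram_bin if params is not None else 0.2
    nbins = int(round(1.0 / width))
    counts = [0] * nbins
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        idx = min(int(f / width), nbins - 1)
        counts[idx] += 1
    return counts


def make_contingency(cov_a: CoverageResult,
                     cov_b: CoverageResult) -> ContingencyTable:
    """TES vs. TE-free nucleotide counts for two compartments."""
    return ContingencyTable(
        cov_a.te_nt, cov_a.total_nt - cov_a.te_nt,
        cov_b.te_nt, cov_b.total_nt - cov_b.te_nt,
    )


def make_contingency_per_class(cov: CoverageResult, class_a: TEClass,
                               class_b: TEClass) -> ContingencyTable:
    """Class-vs-class table within one compartment (e.g. SINE vs LINE
    nucleotides, each against the TE-free count)."""
    free = cov.total_nt - cov.te_nt
    return ContingencyTable(
        cov.per_class_nt.get(class_a, 0), free,
        cov.per_class_nt.get(class_b, 0), free,
    )


def _fisher_log_p(t: ContingencyTable) -> float:
    """Natural-log two-sided Fisher p by hypergeometric enumeration."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        logger.info("degenerate contingency margins, p = 1 by convention")
        return 0.0
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    lp = hypergeom.logpmf(ks, n_total, col1, row1)
    lp_obs = lp[a - lo]
    mask = lp <= lp_obs + np.log1p(1e-7)
    return min(0.0, float(logsumexp(lp[mask])))


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums, in log space, the probabilities of every table with the observed
    margins whose probability is <= the observed table's (relative tolerance
    1e-7 for float ties). A zero row or column margin makes the table
    degenerate: p = 1 by convention. Probabilities below double-precision
    range are floored at the smallest positive float; use
    :func:`fisher_exact_log10p` when the magnitude itself matters.
    """
    p = float(np.exp(_fisher_log_p(t)))
    return min(1.0, max(p, _MIN_P))


def fisher_exact_log10p(t: ContingencyTable) -> float:
    """Base-10 log of the two-sided Fisher p, without underflow flooring."""
    return _fisher_log_p(t) / np.log(10.0)


def genome_fraction(tes: Sequence[TEAnnotation], genome_total_nt: int,
                    include_non_te: bool = False
                    ) -> tuple[float, dict[TEClass, float]]:
    """Union TE-covered fraction of the whole genome, overall and per class."""
    if genome_total_nt <= 0:
        raise ValueError("genome_total_nt must be positive")
    active = _active_tes(tes, include_non_te=include_non_te)
    u = iv.merge_by_chrom(
        (t.interval.chrom, t.interval.start, t.interval.end) for t in active
    )
    overall = iv.by_chrom_total(u) / genome_total_nt
    per_class: dict[TEClass, float] = {}
    claimed: dict[str, list] = {}
    for te in sorted(active, key=lambda t: (-t.sw_score, t.te_id)):
        ch = te.interval.chrom
        mine = iv.subtract(
            [(te.interval.start, te.interval.end)], claimed.get(ch, [])
        )
        got = iv.total_length(mine)
        if got:
            per_class[te.te_class] = (
                per_class.get(te.te_class, 0) + got
            )
        claimed[ch] = iv.merge(claimed.get(ch, []) + mine)
    return overall, {k: v / genome_total_nt for k, v in per_class.items()}
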