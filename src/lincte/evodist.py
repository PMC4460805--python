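"""Kimura two-parameter (K2P) evolutionary distances from pairwise
alignments.

The K2P model distinguishes transitions (A<->G, C<->T; observed proportion
P) from transversions (all other mismatches; proportion Q) and estimates
substitutions per site as

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns containing a gap or any non-ACGT character in either row are
excluded from the comparable-site count n. The estimator is undefined
(saturated) when 1 - 2P - Q <= 0 or 1 - 2Q <= 0; that state is signalled
explicitly, never as a silent infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .ancient_te import project_interval_alignment
from .gene_partition import AnalysisParams
from .io_formats import AlignmentBlock, GeneModel

__all__ = [
    "SitePatternCounts",
    "DistanceResult",
    "count_site_patterns",
    "kimura_k2p",
    "gene_evolutionary_rate",
]

_VALID = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class SitePatternCounts:
    """Comparable sites n, transition differences ts, transversions tv."""

    n: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if self.ts + self.tv > self.n:
            raise ValueError("ts + tv cannot exceed n")

    def __add__(self, other: "SitePatternCounts") -> "SitePatternCounts":
        return SitePatternCounts(
            self.n + other.n, self.ts + other.ts, self.tv + other.tv
        )


@dataclass(frozen=True)
class DistanceResult:
    P: float
    Q: float
    d: float | None
    defined: bool
    n: int = 0
    low_confidence: bool = False


def count_site_patterns(ref_gapped: str, query_gapped: str) -> SitePatternCounts:
    if len(ref_gapped) != len(query_gapped):
        raise ValueError("gapped rows have unequal length")
    n = ts = tv = 0
    for r, q in zip(ref_gapped.upper(), query_gapped.upper()):
        if r not in _VALID or q not in _VALID:
            continue
        n += 1
        if r != q:
            if (r, q) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return SitePatternCounts(n, ts, tv)


def kimura_k2p(counts: SitePatternCounts) -> DistanceResult:
    """K2P distance from site-pattern counts; n must be positive."""
    if counts.n <= 0:
        raise ValueError("no comparable sites: distance undefined, not zero")
    P = counts.ts / counts.n
    Q = counts.tv / counts.n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return DistanceResult(P, Q, None, False, counts.n)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceResult(P, Q, d, True, counts.n)


def gene_evolutionary_rate(gene: GeneModel,
                           blocks: Sequence[AlignmentBlock],
                           params: AnalysisParams | None = None
                           ) -> DistanceResult | None:
    """One K2P distance per gene from the concatenated exon projections.

    Site-pattern counts are pooled over all exons before the single distance
    is computed. Genes with no aligned exon bases return ``None`` (missing);
    genes with fewer comparable sites than ``params.low_conf_sites`` are
    flagged low-confidence but still reported.
    """
    params = params or AnalysisParams()
    pooled = SitePatternCounts(0, 0, 0)
    for exon in gene.exons:
        aln = project_interval_alignment(exon, blocks)
        if aln is not None:
            pooled = pooled + count_site_patterns(
                aln.ref_gapped, aln.query_gapped
            )
    if pooled.n == 0:
        return None
    res = kimura_k2p(pooled)
    if pooled.n < params.low_conf_sites:
        res = DistanceResult(res.P, res.Q, res.d, res.defined, res.n, True)
    return res
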