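"""Ancient vs. lineage-specific TE classification from cross-species
pairwise alignments.

A TE insertion is "ancient" — i.e. predates the divergence of the two
aligned species — when its projected orthologous alignment is longer than
``ancient_min_cols`` columns (strictly, default 100) with a gap-column
fraction below the stringent (< 5%) or within the relaxed (<= 25%) bound.
A TE with no qualifying alignment in the other species is lineage-specific.
"Insertions/deletions" are measured as gap columns of the projection (a
column where either row is a gap), the quantity a pairwise alignment file
exposes directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import intervals as iv
from .gene_partition import AnalysisParams, RegionClass, RegionSet
from .io_formats import AlignmentBlock, GenomicInterval, TEAnnotation
from .tes_quantify import ContingencyTable, fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologAlignment",
    "AncientCall",
    "BlockIndex",
    "project_interval_alignment",
    "project_te_alignment",
    "classify_ancient",
    "assign_region_class",
    "ancient_fraction_by_region",
]


@dataclass(frozen=True)
class OrthologAlignment:
    """A TE's (or any interval's) alignment columns in the other species."""

    te_id: int
    ref_gapped: str
    query_gapped: str

    def __post_init__(self) -> None:
        if len(self.ref_gapped) != len(self.query_gapped):
            raise ValueError("projection rows have unequal length")

    @property
    def columns(self) -> int:
        return len(self.ref_gapped)

    @property
    def gap_cols(self) -> int:
        return sum(
            1 for r, q in zip(self.ref_gapped, self.query_gapped)
            if r == "-" or q == "-"
        )

    @property
    def indel_fraction(self) -> float:
        return self.gap_cols / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class AncientCall:
    te_id: int
    region_class: RegionClass | None
    columns: int
    indel_fraction: float
    ancient_stringent: bool
    ancient_relaxed: bool


def _project_one_block(block: AlignmentBlock, start: int,
                       end: int) -> tuple[str, str] | None:
    """Columns of one block whose reference coordinate falls in [start, end),
    plus query-insertion (ref-gap) columns strictly between the first and
    last selected reference columns."""
    ref = np.frombuffer(block.ref_text.encode(), dtype="S1")
    nongap = ref != b"-"
    # reference coordinate of each non-gap column
    pos = np.cumsum(nongap) - 1 + block.ref_start
    sel = nongap & (pos >= start) & (pos < end)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return None
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    return block.ref_text[lo:hi], block.query_text[lo:hi]


class BlockIndex:
    """Sorted per-chromosome index over reference-nonoverlapping blocks,
    for bisection instead of linear scans when projecting many intervals."""

    def __init__(self, blocks: Sequence[AlignmentBlock]) -> None:
        self._by_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            self._by_chrom.setdefault(b.ref_chrom, []).append(b)
        self._starts: dict[str, list[int]] = {}
        for chrom, bs in self._by_chrom.items():
            bs.sort(key=lambda b: b.ref_start)
            for a, b in zip(bs, bs[1:]):
                if b.ref_start < a.ref_end:
                    raise ValueError(
                        f"blocks overlap on reference at {chrom}:{b.ref_start}"
                    )
            self._starts[chrom] = [b.ref_start for b in bs]

    def overlapping(self, chrom: str, start: int, end: int
                    ) -> list[AlignmentBlock]:
        from bisect import bisect_right

        bs = self._by_chrom.get(chrom, [])
        if not bs:
            return []
        i = bisect_right(self._starts[chrom], start) - 1
        if i < 0 or bs[i].ref_end <= start:
            i += 1
        out = []
        while i < len(bs) and bs[i].ref_start < end:
            out.append(bs[i])
            i += 1
        return out


def project_interval_alignment(interval: GenomicInterval,
                               blocks: "Sequence[AlignmentBlock] | BlockIndex",
                               te_id: int = -1) -> OrthologAlignment | None:
    """Project a reference interval through pairwise blocks.

    Blocks must be sorted and reference-nonoverlapping (``blocks`` may be a
    plain sequence or a :class:`BlockIndex`). Intervals spanning several
    blocks concatenate their per-block projections; unaligned stretches
    between blocks contribute no columns. Returns ``None`` when no block
    overlaps the interval.
    """
    if isinstance(blocks, BlockIndex):
        cand = blocks.overlapping(interval.chrom, interval.start, interval.end)
    else:
        cand = [
            b for b in blocks
            if b.ref_chrom == interval.chrom
            and b.ref_end > interval.start and b.ref_start < interval.end
        ]
    parts_r: list[str] = []
    parts_q: list[str] = []
    n_blocks_hit = 0
    for b in cand:
        got = _project_one_block(b, interval.start, interval.end)
        if got is not None:
            parts_r.append(got[0])
            parts_q.append(got[1])
            n_blocks_hit += 1
    if not parts_r:
        return None
    if n_blocks_hit > 1:
        logger.debug(
            "interval %s:%d-%d spans %d alignment blocks; inter-block "
            "stretches contribute no columns",
            interval.chrom, interval.start, interval.end, n_blocks_hit,
        )
    return OrthologAlignment(te_id, "".join(parts_r), "".join(parts_q))


def project_te_alignment(te: TEAnnotation,
                         blocks: Sequence[AlignmentBlock]
                         ) -> OrthologAlignment | None:
    return project_interval_alignment(te.interval, blocks, te_id=te.te_id)


def classify_ancient(aln: OrthologAlignment | None,
                     region_class: RegionClass | None,
                     params: AnalysisParams,
                     te_id: int | None = None) -> AncientCall:
    """Apply the length and indel thresholds; an absent alignment is
    lineage-specific (both flags false)."""
    if aln is None:
        return AncientCall(
            te_id if te_id is not None else -1, region_class, 0, 0.0,
            False, False,
        )
    cols = aln.columns
    frac = aln.indel_fraction
    long_enough = cols > params.ancient_min_cols
    return AncientCall(
        aln.te_id,
        region_class,
        cols,
        frac,
        long_enough and frac < params.ancient_max_indel_stringent,
        long_enough and frac <= params.ancient_max_indel_relaxed,
    )


_TIE_PRIORITY = [RegionClass.PROMOTER, RegionClass.EXON, RegionClass.INTRON]


def assign_region_class(te: TEAnnotation,
                        region_sets: Mapping[RegionClass, RegionSet]
                        ) -> RegionClass | None:
    """Compartment with maximal base overlap with the TE; exact ties break
    PROMOTER > EXON > INTRON; ``None`` if the TE touches no compartment."""
    ch = te.interval.chrom
    mine = [(te.interval.start, te.interval.end)]
    best: RegionClass | None = None
    best_ov = 0
    for rc in _TIE_PRIORITY:
        ov = iv.overlap_length(mine, region_sets[rc].intervals.get(ch, []))
        if ov > best_ov:
            best, best_ov = rc, ov
    return best


def ancient_fraction_by_region(calls: Sequence[AncientCall],
                               mode: str = "stringent") -> dict:
    """Per-compartment ancient counts/fractions and the pairwise Fisher tests
    on ancient vs. lineage-specific TE counts.

    Returns ``{"by_class": {RegionClass: (ancient, lineage, fraction|None)},
    "fisher": {"PROMOTER_vs_INTRON": p, "EXON_vs_INTRON": p}}``; a
    comparison involving an empty compartment is omitted.
    """
    if mode not in ("stringent", "relaxed"):
        raise ValueError("mode must be 'stringent' or 'relaxed'")
    flag = (
        (lambda c: c.ancient_stringent) if mode == "stringent"
        else (lambda c: c.ancient_relaxed)
    )
    by_class: dict[RegionClass, tuple[int, int, float | None]] = {}
    for rc in RegionClass:
        anc = sum(1 for c in calls if c.region_class is rc and flag(c))
        lin = sum(1 for c in calls if c.region_class is rc and not flag(c))
        frac = anc / (anc + lin) if (anc + lin) else None
        by_class[rc] = (anc, lin, frac)

    fisher: dict[str, float] = {}
    for a_rc in (RegionClass.PROMOTER, RegionClass.EXON):
        a_anc, a_lin, a_frac = by_class[a_rc]
        i_anc, i_lin, i_frac = by_class[RegionClass.INTRON]
        if a_frac is None or i_frac is None:
            logger.info("empty compartment; skipping %s vs INTRON", a_rc.value)
            continue
        fisher[f"{a_rc.value}_vs_INTRON"] = fisher_exact_two_sided(
            ContingencyTable(a_anc, a_lin, i_anc, i_lin)
        )
    return {"by_class": by_class, "fisher": fisher}
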