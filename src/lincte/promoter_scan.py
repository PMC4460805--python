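"""TATA-box scanning of core promoter sequences.

Promoters are addressed by negative offsets relative to the transcription
start site: the base immediately upstream of the TSS is -1, the 5'-most
base of a length-L promoter is -L. The default motif is the IUPAC consensus
TATAWAW (W = A or T); the scanning and profiling machinery is
motif-agnostic. A match is located by its 5'-most base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .gene_partition import AnalysisParams, derive_promoter
from .io_formats import GeneModel

__all__ = [
    "PromoterSeq",
    "extract_promoters",
    "find_tata",
    "tata_positional_profile",
    "tata_containing_fraction",
    "DEFAULT_TATA_MOTIF",
]

DEFAULT_TATA_MOTIF = "TATAWAW"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterSeq:
    """A promoter read 5'->3' on the gene's sense strand; its last base sits
    at offset -1 (immediately upstream of the TSS)."""

    gene_id: str
    sequence: str

    def offset_to_index(self, offset: int) -> int:
        return len(self.sequence) + offset


def extract_promoters(genes: Sequence[GeneModel], genome: Mapping[str, str],
                      params: AnalysisParams) -> list[PromoterSeq]:
    """Slice each gene's core promoter out of the genome, reverse-
    complementing for minus-strand genes so all sequences read sense."""
    out = []
    for g in genes:
        p = derive_promoter(g, params, len(genome[g.chrom]))
        if p is None or len(p) != params.promoter_len:
            continue  # clipped promoters would break uniform offsets
        raw = genome[g.chrom][p.start:p.end].upper()
        if g.strand == "-":
            raw = reverse_complement(raw)
        out.append(PromoterSeq(g.gene_id, raw))
    return out


def _matches_at(seq: str, i: int, motif: str) -> bool:
    for j, code in enumerate(motif):
        allowed = _IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} in motif")
        if seq[i + j] not in allowed:  # N in the sequence never matches
            return False
    return True


def find_tata(p: PromoterSeq, motif: str = DEFAULT_TATA_MOTIF) -> list[int]:
    """All offsets (of the match's 5'-most base, relative to the TSS) where
    the IUPAC motif matches, including overlapping matches."""
    seq = p.sequence.upper()
    motif = motif.upper()
    L = len(seq)
    m = len(motif)
    return [i - L for i in range(0, L - m + 1) if _matches_at(seq, i, motif)]


def tata_positional_profile(promoters: Sequence[PromoterSeq],
                            motif: str = DEFAULT_TATA_MOTIF
                            ) -> dict[int, float]:
    """Fraction of promoters with a match starting at each offset
    (-L .. -len(motif))."""
    if not promoters:
        raise ValueError("empty promoter list")
    L = len(promoters[0].sequence)
    if any(len(p.sequence) != L for p in promoters):
        raise ValueError("promoters must have uniform length")
    counts = {off: 0 for off in range(-L, -len(motif) + 1)}
    for p in promoters:
        for off in set(find_tata(p, motif)):
            counts[off] += 1
    n = len(promoters)
    return {off: c / n for off, c in counts.items()}


def tata_containing_fraction(promoters: Sequence[PromoterSeq],
                             params: AnalysisParams | None = None,
                             motif: str = DEFAULT_TATA_MOTIF) -> float:
    """Fraction of promoters with at least one match starting inside the
    canonical TATA window (default -35..-25, inclusive)."""
    if not promoters:
        return 0.0
    lo, hi = (params or AnalysisParams()).tata_region
    hit = sum(
        1 for p in promoters
        if any(lo <= off <= hi for off in find_tata(p, motif))
    )
    return hit / len(promoters)
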