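"""Sorted-interval algebra on (start, end) pairs grouped by chromosome.

These primitives back every nucleotide-level computation in the package
(region building, TES coverage, region attribution). All intervals are
0-based half-open; functions return merged, sorted, disjoint lists.
"""

from __future__ import annotations

from typing import Iterable, Mapping

Pair = tuple[int, int]
ByChrom = dict[str, list[Pair]]


def merge(pairs: Iterable[Pair]) -> list[Pair]:
    """Merge possibly-overlapping pairs into sorted disjoint pairs."""
    pairs = sorted(pairs)
    out: list[Pair] = []
    for s, e in pairs:
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(pairs: Iterable[Pair]) -> int:
    return sum(e - s for s, e in pairs)


def intersect(a: list[Pair], b: list[Pair]) -> list[Pair]:
    """Intersection of two sorted disjoint pair lists (two-pointer sweep)."""
    out: list[Pair] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: list[Pair], b: list[Pair]) -> list[Pair]:
    """Bases of sorted disjoint ``a`` not covered by sorted disjoint ``b``."""
    out: list[Pair] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def overlap_length(a: list[Pair], b: list[Pair]) -> int:
    return total_length(intersect(a, b))


def merge_by_chrom(items: Iterable[tuple[str, int, int]]) -> ByChrom:
    acc: dict[str, list[Pair]] = {}
    for chrom, s, e in items:
        acc.setdefault(chrom, []).append((s, e))
    return {c: merge(v) for c, v in acc.items()}


def by_chrom_total(bc: Mapping[str, list[Pair]]) -> int:
    return sum(total_length(v) for v in bc.values())


def by_chrom_intersect(a: Mapping[str, list[Pair]],
                       b: Mapping[str, list[Pair]]) -> ByChrom:
    return {
        c: intersect(a[c], b[c]) for c in a.keys() & b.keys()
        if intersect(a[c], b[c])
    }


def by_chrom_overlap_length(a: Mapping[str, list[Pair]],
                            b: Mapping[str, list[Pair]]) -> int:
    return sum(overlap_length(a[c], b[c]) for c in a.keys() & b.keys())
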