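"""Shared fixtures: small synthetic studies and independent oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from lincte import (
    AnalysisParams,
    SimConfig,
    build_region_sets,
    select_intergenic_lincRNAs,
    simulate_genome_annotation,
    simulate_ortholog_alignments,
)


@pytest.fixture(scope="session")
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=11, n_linc_genes=60, n_pc_genes=12)
    sim = simulate_genome_annotation(cfg)
    blocks = simulate_ortholog_alignments(cfg, sim)
    return cfg, sim, blocks


@pytest.fixture(scope="session")
def small_regions(small_sim, params):
    cfg, sim, _ = small_sim
    linc = select_intergenic_lincRNAs(sim.linc_genes, sim.pc_genes, params)
    return linc, build_region_sets(linc, params, sim.chrom_lens)


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation)
# ---------------------------------------------------------------------------


def per_base_coverage_oracle(region_pairs, te_pairs) -> int:
    """Boolean per-base marking: bases inside any region AND any TE."""
    if not region_pairs and not te_pairs:
        return 0
    hi = max([e for _s, e in list(region_pairs) + list(te_pairs)] + [1])
    in_region = np.zeros(hi, dtype=bool)
    in_te = np.zeros(hi, dtype=bool)
    for s, e in region_pairs:
        in_region[s:e] = True
    for s, e in te_pairs:
        in_te[s:e] = True
    return int(np.sum(in_region & in_te))


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by full table enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        return Fraction(1)
    denom = comb(n, col1)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    probs = {
        k: Fraction(comb(row1, k) * comb(row2, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def pearson_oracle(x, y) -> float:
    """Direct product-moment summation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5
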