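"""Expression summarization and TES-content correlations.

Expression enters in one of two modes: microarray intensities across
tissues, summarized as the median of log2 intensities per gene, or RNA-seq
read counts converted to RPKM = 1e9 * C / (N * L) with C the gene's pooled
read count, N the library size and L the mature transcript length in nt.
Associations between per-gene TES fraction and evolutionary rate or
expression are Pearson correlations with two-sided t-test p-values,
using pairwise-complete rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionRecord",
    "median_log2_expression",
    "rpkm",
    "pearson_with_p",
    "run_association",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression in microarray mode (tissue_values) or RNA-seq
    mode (read_count, gene_length_nt, library_size)."""

    gene_id: str
    tissue_values: tuple = ()
    read_count: int = 0
    gene_length_nt: int = 0
    library_size: int = 0


def median_log2_expression(rec: ExpressionRecord) -> float:
    """Median of log2-transformed tissue intensities.

    Intensities must be strictly positive — a non-positive value is an
    input error, not something to patch with a pseudo-count.
    """
    if not rec.tissue_values:
        raise ValueError(f"{rec.gene_id}: no tissue values")
    vals = np.asarray(rec.tissue_values, dtype=float)
    if np.any(vals <= 0):
        raise ValueError(f"{rec.gene_id}: non-positive intensity")
    return float(np.median(np.log2(vals)))


def rpkm(rec: ExpressionRecord) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if rec.gene_length_nt <= 0:
        raise ValueError(f"{rec.gene_id}: gene length must be positive")
    if rec.library_size <= 0:
        raise ValueError(f"{rec.gene_id}: library size must be positive")
    return 1e9 * rec.read_count / (rec.library_size * rec.gene_length_nt)


def pearson_with_p(x: Sequence[float], y: Sequence[float]
                   ) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value
    (t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def run_association(table: pd.DataFrame) -> pd.DataFrame:
    """Correlate tes_fraction against evo_rate and expression_summary.

    ``table`` needs columns ``gene_id``, ``tes_fraction`` and at least one
    of ``evo_rate`` / ``expression_summary``. Rows with a missing member
    are dropped pairwise (per pairing, not listwise). Pairings with fewer
    than 3 complete rows are skipped with a log entry.

    Returns a frame with columns pairing, n, r, p.
    """
    rows = []
    for col, pairing in (
        ("evo_rate", "tes_fraction_vs_evo_rate"),
        ("expression_summary", "tes_fraction_vs_expression"),
    ):
        if col not in table.columns:
            continue
        sub = table[["tes_fraction", col]].dropna()
        if len(sub) < 3:
            logger.warning("pairing %s skipped: %d complete rows", pairing,
                           len(sub))
            continue
        r, p = pearson_with_p(sub["tes_fraction"].to_numpy(),
                              sub[col].to_numpy())
        rows.append({"pairing": pairing, "n": len(sub), "r": r, "p": p})
    return pd.DataFrame(rows, columns=["pairing", "n", "r", "p"])
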