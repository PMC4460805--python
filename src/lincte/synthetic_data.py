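"""Synthetic genomes with planted truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome genome carrying intergenic lincRNA and protein-coding gene
models laid out without span overlap; transposable elements planted
non-overlapping per compartment (promoter / exon / intron / intergenic) at
configured per-class coverage densities; a second species produced by
per-site substitution at transition rate ``ortho_P`` and transversion rate
``ortho_Q``, with gap columns planted inside "ancient" TEs and
lineage-specific TEs dropped from the alignment entirely; and expression
values constructed so their correlation with per-gene TES fraction equals a
configured target.

Everything is a pure function of (config, seed): identical seeds give
byte-identical output files. A planted truth table records each TE's
compartment, class and ancient flag so downstream estimates can be checked
against what was planted.

Promoter TEs deserve a note: a 100 bp core promoter cannot contain a
full-length element, so promoter elements are planted covering part of the
promoter and extending upstream into a reserved stretch of intergenic
sequence (reserved so intergenic planting cannot collide with them). This
keeps promoter elements long enough to be classifiable as ancient while the
in-promoter coverage still hits the configured promoter density; the
spilled-over bases are charged against the intergenic density budget.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as ivl
from .io_formats import (
    AlignmentBlock,
    GeneModel,
    GenomicInterval,
    TEAnnotation,
    TEClass,
    write_bed12,
    write_fasta,
    write_maf,
    write_repeatmasker_out,
    write_report_tsv,
)

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "simulate_genome_annotation",
    "simulate_ortholog_alignments",
    "simulate_expression",
    "simulate_feature_table",
]

_CLASS_FAMILY = {
    "LINE": ("L1Syn", "LINE/L1"),
    "SINE": ("B1Syn", "SINE/B1"),
    "LTR": ("ERVSyn", "LTR/ERVK"),
    "DNA": ("TigSyn", "DNA/hAT"),
    "NON_TE": ("(TA)n", "Simple_repeat"),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# index order A,C,G,T: transition partner and the two transversion partners
_TS_MAP = np.array([2, 3, 0, 1])
_TV_MAP = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimConfig:
    """All planted truths for one synthetic study.

    Densities are target covered fractions per compartment and TE class;
    ``ortho_P``/``ortho_Q`` are per-site transition/transversion
    probabilities on the branch to the second species;
    ``ancient_gap_frac`` the per-site gap-column rate inside ancient TEs;
    ``expr_rho`` the target correlation between per-gene TES fraction and
    the latent (log2) expression level.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int | None = None  # None: auto-sized to fit the genes
    n_linc_genes: int = 1100
    n_pc_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (300, 700)
    intron_len: tuple[int, int] = (700, 1500)
    promoter_len: int = 100
    te_len: tuple[int, int] = (120, 300)
    te_density: dict = field(default_factory=lambda: {
        "PROMOTER": {"SINE": 0.06, "LINE": 0.04},
        "EXON": {"LINE": 0.08, "SINE": 0.08, "LTR": 0.04},
        "INTRON": {"LINE": 0.20, "SINE": 0.10, "LTR": 0.05},
        "INTERGENIC": {"LINE": 0.15, "SINE": 0.10, "LTR": 0.05,
                       "NON_TE": 0.01},
    })
    ancient_prob: dict = field(default_factory=lambda: {
        "PROMOTER": 0.5, "EXON": 0.35, "INTRON": 0.15, "INTERGENIC": 0.25,
    })
    ortho_P: float = 0.1
    ortho_Q: float = 0.05
    ancient_gap_frac: float = 0.01
    expr_rho: float = -0.25
    n_tissues: int = 24
    noise_sd: float = 0.25
    tata_frac: float = 0.25
    tata_offset: int = -30
    tata_motif_seq: str = "TATAAAA"

    def __post_init__(self) -> None:
        for comp, dens in self.te_density.items():
            for cls, f in dens.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"density {comp}/{cls} outside [0,1]")
            if sum(dens.values()) > 0.95:
                raise ValueError(f"densities for {comp} sum above 0.95")
        for comp, p in self.ancient_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ancient_prob {comp} outside [0,1]")
        if abs(self.expr_rho) >= 1.0:
            raise ValueError("|expr_rho| must be < 1")
        if not (0.0 <= self.ortho_P and 0.0 <= self.ortho_Q
                and self.ortho_P + self.ortho_Q <= 1.0):
            raise ValueError("ortho_P/ortho_Q must be probabilities summing <= 1")


@dataclass
class SimulatedGenome:
    cfg: SimConfig
    genome: dict  # chrom -> sequence string
    linc_genes: list
    pc_genes: list
    tes: list
    truth: pd.DataFrame

    @property
    def chrom_lens(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_bed12(self.linc_genes, outdir / "linc.bed")
        write_bed12(self.pc_genes, outdir / "pc.bed")
        write_repeatmasker_out(self.tes, outdir / "te.out")
        write_report_tsv(self.truth, outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------


def _make_gene(rng, cfg: SimConfig, chrom: str, start: int, gene_id: str
               ) -> GeneModel:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for i in range(n_ex):
        L = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + L, strand))
        pos += L
        if i < n_ex - 1:
            pos += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
    return GeneModel(gene_id, chrom, strand, tuple(exons))


def _layout_genes(rng, cfg: SimConfig):
    """Place lincRNA and protein-coding genes sequentially with gaps big
    enough for two facing promoters plus promoter-TE spillover room."""
    te_max = cfg.te_len[1]
    gap_min = 2 * (cfg.promoter_len + te_max) + 100
    kinds = ["linc"] * cfg.n_linc_genes + ["pc"] * cfg.n_pc_genes
    rng.shuffle(kinds)
    per_chrom = int(np.ceil(len(kinds) / cfg.n_chroms))
    linc, pc, chrom_lens = [], [], {}
    k = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = cfg.promoter_len + te_max + 100
        placed = 0
        while k < len(kinds) and placed < per_chrom:
            kind = kinds[k]
            gid = f"{kind}_{k:05d}"
            gene = _make_gene(rng, cfg, chrom, cursor, gid)
            end_margin = cfg.promoter_len + te_max + 100
            if cfg.chrom_len is not None and gene.span.end + end_margin > cfg.chrom_len:
                break
            (linc if kind == "linc" else pc).append(gene)
            cursor = gene.span.end + gap_min + int(rng.integers(0, 400))
            placed += 1
            k += 1
        chrom_lens[chrom] = (
            cfg.chrom_len if cfg.chrom_len is not None
            else cursor + cfg.promoter_len + te_max + 100
        )
    if k < len(kinds):
        raise ValueError(
            f"chrom_len {cfg.chrom_len} too small: placed only {k} of "
            f"{len(kinds)} genes"
        )
    return linc, pc, chrom_lens


# ---------------------------------------------------------------------------
# TE planting
# ---------------------------------------------------------------------------


def _plant_in_intervals(rng, intervals, densities: Mapping[str, float],
                        te_len: tuple[int, int]):
    """Plant non-overlapping full-length TEs inside disjoint intervals.

    A per-class nucleotide budget accrues as ``density * interval_length``
    and is spent on whole elements, so realized coverage tracks the target
    to within one element length globally without creating truncated
    (unclassifiable) elements.
    """
    classes = sorted(densities)
    budget = {c: 0.0 for c in classes}
    placed = []  # (chrom, start, end, te_class)
    for chrom, s, e in intervals:
        L = e - s
        todo = []  # lengths with class labels for this interval
        for c in classes:
            budget[c] += densities[c] * L
            while True:
                tl = int(rng.integers(te_len[0], te_len[1] + 1))
                if budget[c] < tl:
                    break
                todo.append((tl, c))
                budget[c] -= tl
        if not todo:
            continue
        order = rng.permutation(len(todo))
        todo = [todo[i] for i in order]
        total = sum(t for t, _ in todo)
        while todo and total > L:  # not enough room: defer to later intervals
            tl, c = todo.pop()
            budget[c] += tl
            total -= tl
        if not todo:
            continue
        free = L - total
        gaps = rng.multinomial(free, np.full(len(todo) + 1, 1.0 / (len(todo) + 1)))
        pos = s
        for (tl, c), g in zip(todo, gaps[:-1]):
            pos += int(g)
            placed.append((chrom, pos, pos + tl, c))
            pos += tl
    return placed


def _plant_promoter_tes(rng, promoters, densities: Mapping[str, float],
                        te_len: tuple[int, int]):
    """One element per promoter at most, anchored at the promoter's outer
    (TSS-distal) edge and extending upstream into reserved spillover space.

    Returns (placed, spill_nt_per_class); ``placed`` entries carry the full
    element interval, whose in-promoter part realizes the density target.
    """
    d_total = sum(densities.values())
    classes = sorted(densities)
    probs = np.array([densities[c] / d_total for c in classes]) if d_total else None
    plen = None
    placed = []
    spill: dict[str, int] = {c: 0 for c in classes}
    m = len(promoters)
    R = sum(d_total * (e - s) for _c, s, e, _strand in promoters)
    for i, (chrom, s, e, strand) in enumerate(promoters):
        plen = e - s
        remaining = m - i
        ideal = R / remaining if remaining else 0.0
        c_nt = int(round(ideal + rng.uniform(-0.4, 0.4) * max(ideal, 1.0)))
        c_nt = max(0, min(plen, c_nt))
        if c_nt < 8:
            continue
        R -= c_nt
        cls = classes[int(rng.choice(len(classes), p=probs))]
        L = int(rng.integers(te_len[0], te_len[1] + 1))
        L = max(L, c_nt)
        if strand == "+":  # upstream (outer edge) is to the left
            te = (chrom, s - (L - c_nt), s + c_nt, cls)
        else:
            te = (chrom, e - c_nt, e + (L - c_nt), cls)
        placed.append(te)
        spill[cls] += L - c_nt
    return placed, spill


def simulate_genome_annotation(cfg: SimConfig) -> SimulatedGenome:
    """Generate genome sequence, gene models, planted TE annotation and the
    truth table; a pure function of the config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    linc, pc, chrom_lens = _layout_genes(rng, cfg)

    # linc compartment intervals (disjoint by construction of the layout)
    te_max = cfg.te_len[1]
    prom4 = []  # (chrom, start, end, strand)
    for g in linc:
        if g.strand == "+":
            tss = g.exons[0].start
            prom4.append((g.chrom, tss - cfg.promoter_len, tss, "+"))
        else:
            tss = g.exons[-1].end
            prom4.append((g.chrom, tss, tss + cfg.promoter_len, "-"))
    exon_iv = sorted((g.chrom, e.start, e.end) for g in linc for e in g.exons)
    intron_iv = sorted(
        (g.chrom, a.end, b.start)
        for g in linc for a, b in zip(g.exons, g.exons[1:]) if b.start > a.end
    )
    # intergenic = genome minus all gene spans and linc promoter+spill zones
    occupied = {}
    items = [(g.chrom, g.span.start, g.span.end) for g in linc + pc]
    for chrom, s, e, strand in prom4:
        if strand == "+":
            items.append((chrom, s - te_max, e))
        else:
            items.append((chrom, s, e + te_max))
    occupied = ivl.merge_by_chrom(items)
    intergenic_iv = []
    for chrom in sorted(chrom_lens):
        whole = [(0, chrom_lens[chrom])]
        for s, e in ivl.subtract(whole, occupied.get(chrom, [])):
            intergenic_iv.append((chrom, s, e))

    dens = cfg.te_density
    placed = []
    prom_placed, spill = _plant_promoter_tes(
        rng, prom4, dens.get("PROMOTER", {}), cfg.te_len
    )
    placed += [(c, s, e, cls, "PROMOTER") for c, s, e, cls in prom_placed]
    # charge promoter spillover against the intergenic per-class budgets
    ig_dens = dict(dens.get("INTERGENIC", {}))
    ig_total = sum(e - s for _c, s, e in intergenic_iv)
    for cls, nt in spill.items():
        if cls in ig_dens and ig_total:
            ig_dens[cls] = max(0.0, ig_dens[cls] - nt / ig_total)
    for comp, intervals, d in (
        ("EXON", exon_iv, dens.get("EXON", {})),
        ("INTRON", intron_iv, dens.get("INTRON", {})),
        ("INTERGENIC", intergenic_iv, ig_dens),
    ):
        placed += [
            (c, s, e, cls, comp)
            for c, s, e, cls in _plant_in_intervals(rng, intervals, d, cfg.te_len)
        ]

    # ancient flags: only elements long enough to ever satisfy the alignment
    # length threshold can be planted ancient
    rows = []
    for chrom, s, e, cls, comp in placed:
        eligible = cls != "NON_TE" and (e - s) > 110
        ancient = bool(eligible and rng.random() < cfg.ancient_prob.get(comp, 0.0))
        rows.append((chrom, s, e, cls, comp, ancient))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    tes = []
    truth_rows = []
    for te_id, (chrom, s, e, cls, comp, ancient) in enumerate(rows):
        name, fam = _CLASS_FAMILY[cls]
        tes.append(TEAnnotation(
            interval=GenomicInterval(chrom, s, e, "+" if rng.random() < 0.5 else "-"),
            sw_score=int(rng.integers(300, 8000)),
            pct_div=round(float(rng.uniform(2.0, 30.0)), 1),
            pct_del=round(float(rng.uniform(0.0, 8.0)), 1),
            pct_ins=round(float(rng.uniform(0.0, 8.0)), 1),
            repeat_name=name,
            class_family=fam,
            te_id=te_id,
        ))
        truth_rows.append({
            "te_id": te_id, "chrom": chrom, "start": s, "end": e,
            "length": e - s, "te_class": cls, "compartment": comp,
            "ancient": ancient,
        })
    truth = pd.DataFrame(
        truth_rows,
        columns=["te_id", "chrom", "start", "end", "length", "te_class",
                 "compartment", "ancient"],
    )

    # genome sequence, then TATA planting in linc promoters
    genome = {}
    for chrom in sorted(chrom_lens):
        arr = _BASES[rng.integers(0, 4, size=chrom_lens[chrom])]
        genome[chrom] = arr.tobytes().decode()
    motif = cfg.tata_motif_seq
    comp_tr = str.maketrans("ACGT", "TGCA")
    for chrom, s, e, strand in prom4:
        if rng.random() >= cfg.tata_frac:
            continue
        plen = e - s
        i0 = plen + cfg.tata_offset  # sense-strand index of motif start
        if i0 < 0 or i0 + len(motif) > plen:
            continue
        seq = genome[chrom]
        if strand == "+":
            gs = s + i0
            genome[chrom] = seq[:gs] + motif + seq[gs + len(motif):]
        else:
            gs = s + plen - i0 - len(motif)
            rc = motif.translate(comp_tr)[::-1]
            genome[chrom] = seq[:gs] + rc + seq[gs + len(motif):]

    return SimulatedGenome(cfg, genome, linc, pc, tes, truth)


# ---------------------------------------------------------------------------
# ortholog alignment simulation
# ---------------------------------------------------------------------------


def _evolve_block(rng, cfg: SimConfig, ref_seq: str, ancient_mask: np.ndarray
                  ) -> tuple[str, str]:
    """Mutate one reference stretch into its query counterpart: per-site
    transitions/transversions everywhere; gap columns (query deletions and
    query insertions, half each) only where ``ancient_mask`` is set."""
    r = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    code = np.zeros(r.size, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[r == b] = i
    u = rng.random(r.size)
    q = code.copy()
    ts = u < cfg.ortho_P
    q[ts] = _TS_MAP[code[ts]]
    tv = (~ts) & (u < cfg.ortho_P + cfg.ortho_Q)
    pick = rng.integers(0, 2, size=int(tv.sum()))
    q[tv] = _TV_MAP[code[tv], pick]
    q_bytes = _BASES[q]

    g = rng.random(r.size)
    half = cfg.ancient_gap_frac / 2.0
    del_mask = ancient_mask & (g < half)
    ins_mask = ancient_mask & (g >= half) & (g < cfg.ancient_gap_frac)
    q_bytes = q_bytes.copy()
    q_bytes[del_mask] = ord("-")

    n_ins = int(ins_mask.sum())
    if n_ins == 0:
        return ref_seq, q_bytes.tobytes().decode()
    cum_excl = np.concatenate(([0], np.cumsum(ins_mask)[:-1]))
    pos = np.arange(r.size) + cum_excl
    out_len = r.size + n_ins
    ref_out = np.full(out_len, ord("-"), dtype=np.uint8)
    q_out = np.full(out_len, ord("-"), dtype=np.uint8)
    ref_out[pos] = r
    q_out[pos] = q_bytes
    q_out[pos[ins_mask] + 1] = _BASES[rng.integers(0, 4, size=n_ins)]
    return ref_out.tobytes().decode(), q_out.tobytes().decode()


def simulate_ortholog_alignments(cfg: SimConfig, sim: SimulatedGenome
                                 ) -> list[AlignmentBlock]:
    """Pairwise blocks covering lincRNA exons and ancient TEs; stretches
    occupied by lineage-specific TEs (and non-TE repeats) are unaligned."""
    rng = np.random.default_rng([cfg.seed, 17])
    t = sim.truth
    ancient_iv = ivl.merge_by_chrom(
        (r.chrom, r.start, r.end) for r in t[t.ancient].itertuples()
    )
    excluded_iv = ivl.merge_by_chrom(
        (r.chrom, r.start, r.end)
        for r in t[(~t.ancient)].itertuples()
    )
    exon_iv = ivl.merge_by_chrom(
        (g.chrom, e.start, e.end) for g in sim.linc_genes for e in g.exons
    )
    blocks = []
    q_cursor: dict[str, int] = {}
    for chrom in sorted(sim.genome):
        want = ivl.merge(exon_iv.get(chrom, []) + ancient_iv.get(chrom, []))
        want = ivl.subtract(want, excluded_iv.get(chrom, []))
        anc = ancient_iv.get(chrom, [])
        qch = "q" + chrom
        for s, e in want:
            mask = np.zeros(e - s, dtype=bool)
            for as_, ae in ivl.intersect([(s, e)], anc):
                mask[as_ - s:ae - s] = True
            ref_text, q_text = _evolve_block(
                rng, cfg, sim.genome[chrom][s:e], mask
            )
            q_len = sum(1 for ch in q_text if ch != "-")
            blocks.append(AlignmentBlock(
                ref_chrom=chrom, ref_start=s, ref_text=ref_text,
                query_chrom=qch, query_start=q_cursor.get(qch, 0),
                query_strand="+", query_text=q_text,
            ))
            q_cursor[qch] = q_cursor.get(qch, 0) + q_len
    return blocks


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimConfig, tes_fraction: Mapping[str, float],
                        gene_lengths: Mapping[str, int] | None = None,
                        library_size: int = 20_000_000
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Microarray-style intensities and RNA-seq counts whose latent (log2)
    level correlates with per-gene TES fraction at ``expr_rho``.

    Returns (array_df, counts_df): array columns are gene_id, tissue_1..;
    counts columns gene_id, count, length.
    """
    rng = np.random.default_rng([cfg.seed, 29])
    gene_ids = list(tes_fraction)
    t = np.array([tes_fraction[g] for g in gene_ids], dtype=float)
    n = t.size
    if n == 0:
        raise ValueError("no genes")
    rho = cfg.expr_rho
    sd = t.std()
    z = (t - t.mean()) / sd if sd > 0 else np.zeros(n)
    latent = rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)

    base = 8.0  # typical log2 microarray intensity scale
    tissue = latent[:, None] + base + cfg.noise_sd * rng.standard_normal(
        (n, cfg.n_tissues)
    )
    array_df = pd.DataFrame(
        np.power(2.0, tissue),
        columns=[f"tissue_{i + 1}" for i in range(cfg.n_tissues)],
    )
    array_df.insert(0, "gene_id", gene_ids)

    lengths = np.array(
        [gene_lengths[g] if gene_lengths else 1000 for g in gene_ids]
    )
    target_rpkm = np.power(2.0, latent + 2.0)
    mu = target_rpkm * lengths * library_size / 1e9
    counts = rng.poisson(mu)
    counts_df = pd.DataFrame(
        {"gene_id": gene_ids, "count": counts, "length": lengths}
    )
    return array_df, counts_df


def simulate_feature_table(n: int, rho: float, seed: int,
                           rate_mean: float = 0.17, rate_sd: float = 0.04
                           ) -> pd.DataFrame:
    """A gene feature table with a planted correlation between TES fraction
    and evolutionary rate (for exercising the association stage directly)."""
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng([seed, 41])
    t = rng.beta(2.0, 5.0, size=n)
    z = (t - t.mean()) / t.std()
    lat = rho * z + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
    rate = np.clip(rate_mean + rate_sd * lat, 1e-4, None)
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "tes_fraction": t,
        "evo_rate": rate,
    })
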