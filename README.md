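# lincte

Quantify transposable-element-derived sequence (TES) in the architecture of
long intergenic non-coding RNA (lincRNA) genes, classify the elements by
evolutionary age, and relate TES content to sequence evolution and
expression.

## Who this is for

Genome biologists studying how transposable elements (TEs) shape non-coding
gene evolution. The package takes standard annotation inputs — RepeatMasker
`.out` repeat calls, BED12 gene models, pairwise genome alignments in MAF,
genome FASTA, and expression tables — and produces nucleotide-resolution
answers to questions like: *what fraction of lincRNA promoters, exons and
introns is TE-derived? are those differences significant? which elements
predate a species split? does TES content track evolutionary rate or
expression level?* A synthetic-genome generator with fully known planted
truth makes the whole pipeline testable end to end without any downloads.

## The analysis

**Compartments.** Each retained lincRNA (intergenic: its genomic span
overlaps no protein-coding gene span; mature length ≥ 200 nt) contributes a
core promoter (the 100 bp upstream of the TSS, strand-aware), its exons, and
its introns. Overlapping bases across genes are assigned once with
precedence exon > intron > promoter.

**TES coverage.** Coverage is the interval *union* of repeat records with a
compartment, so `te_nt ≤ total_nt` always. Simple repeats, low-complexity
and similar non-TE records are excluded (switchable). Compartment
differences are tested with the two-sided Fisher exact test on the 2×2
table of TES vs TE-free nucleotide counts, computed by hypergeometric
enumeration:

    p = Σ { P(T) : tables T with the observed margins, P(T) ≤ P(observed) }

**Ancient elements.** A TE is *ancient* when its projection through the
cross-species alignment is longer than 100 columns with a gap-column
fraction < 5 % (stringent) or ≤ 25 % (relaxed); elements with no qualifying
alignment are *lineage-specific*. Per-compartment ancient fractions are
compared with the same Fisher machinery on element counts.

**Evolutionary rate.** Per gene, site patterns pooled over the concatenated
exon alignment give the Kimura two-parameter distance

    d = -1/2 · ln[(1 − 2P − Q) · sqrt(1 − 2Q)]

with P and Q the observed transition and transversion proportions.

**Associations.** Per-gene TES fraction is correlated (Pearson r, two-sided
t-test) with the K2P rate and with expression, summarized either as the
median log2 microarray intensity across tissues or as
RPKM = 10⁹·C/(N·L) from pooled RNA-seq counts.

**Promoters.** Core promoters are scanned for the TATA consensus
(IUPAC `TATAWAW` by default) and the per-offset match frequency profiled
over −100..−7; a promoter is TATA-containing when a match starts in
[−35, −25].

## Worked example

```sh
lincte run --config config.yaml --outdir report/
```

with `config.yaml`:

```yaml
mode: synthetic
seed: 5
sim:
  n_linc_genes: 80
  n_pc_genes: 15
```

This simulates a genome (planted TES densities: promoter 0.10, exon 0.20,
intron 0.35; planted ancient probabilities 0.5 / 0.35 / 0.15), runs every
stage, and writes eight report files. `report/fig1_fractions.tsv`:

```text
region_class  total_nt  te_nt   fraction  fisher_p_vs_intron  fisher_p_vs_intron_bonferroni
PROMOTER      8000      789     0.098625  4.94066e-324        9.88131e-324
EXON          158713    31305   0.197243  4.94066e-324        9.88131e-324
INTRON        267407    93274   0.348809  NA                  NA
```

The measured fractions recover the planted densities; at nucleotide scale
the Fisher p-values underflow double precision (reported at the float
floor, i.e. p < 1e-323). `report/fig5_ancient.tsv` shows the ancient-TE
recovery (0.485 / 0.354 / 0.122 here at small scale), and
`report/figS2_expression.tsv` the planted negative TES-expression
correlation (r = −0.165 at n = 80, r → −0.25 as n grows). The same stages
are available individually (`lincte simulate / quantify / ancient / dist /
tata`) and as library functions.

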