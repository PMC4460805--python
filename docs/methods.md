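# Methods

This note records the models, conventions, parameter choices and known
limitations behind `lincte`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand; every
converter lives at the I/O boundary. RepeatMasker `.out` records (1-based
inclusive, `C` for minus strand) and MAF query rows (strand-relative
starts, normalized as `srcSize − start − size` for minus-strand rows) are
translated on read and re-translated on write. Only the first two `s` rows
of a MAF block are used: the analysis is strictly pairwise.

Repeat records map to TE classes by the prefix of the class/family string:
`LINE`, `SINE`, `LTR`, `DNA` map to themselves; `Simple_repeat`,
`Low_complexity`, `Satellite`, the structural-RNA families and `Unknown`
are non-TE and excluded from all TES totals by default (the
`include_non_te` switch on `AnalysisParams` counts them instead — whether
simple repeats belong in a TES total is a genuine judgement call, so it is
exposed rather than fixed); anything else (e.g. `RC/Helitron`) is `OTHER`
and counted as TES.

## Gene partitioning

* Core promoter: 100 bp (`promoter_len`) immediately upstream of the
  annotated TSS, strand-aware, clipped at chromosome ends; a fully
  off-chromosome promoter is dropped with a log entry. Extended promoters
  are deliberately not modelled.
* lincRNA selection: mature (spliced) length ≥ 200 nt (`min_linc_len`,
  strict "shorter than" removal) and span-level intergenicity — any overlap
  between the candidate's genomic span and a protein-coding gene span
  excludes it, which also excludes candidates inside protein-coding
  introns. Candidates overlapping *each other* are kept (logged): collapsing
  isoforms is out of scope.
* Compartment precedence: where gene sets overlap, a base is counted once
  as exon > intron > promoter. The precedence prevents double counting in
  the Fisher denominators; the exon-first choice reflects that an exonic
  base is exonic no matter what another isoform does around it.

## TES quantification

Coverage is an interval union: overlapping repeat records never count a
base twice, guaranteeing `te_nt ≤ total_nt`. For per-class accounting,
bases covered by records of different classes go to the record with the
higher Smith–Waterman score (ties: earlier record), mirroring
RepeatMasker's own preference; a `per_class_union=False` switch instead
counts each class's independent union (sums may then exceed the overall
union where classes overlap).

The two-sided Fisher exact test uses the probability-mass definition,
implemented by direct hypergeometric enumeration in log space
(`scipy.stats.hypergeom.logpmf` + `logsumexp`) with a 1e−7 relative
tolerance for probability ties, so results are stable across float
regimes. Degenerate margins (an empty row or column) return p = 1 by
convention, logged. At nucleotide scale p easily underflows double
precision; `fisher_exact_two_sided` floors at the smallest positive float
to keep p ∈ (0, 1], and `fisher_exact_log10p` reports the unfloored
magnitude. Raw p-values are reported without multiplicity correction; the
report adds a clearly-marked Bonferroni column as an extension.

Per-gene TES fraction is exonic union coverage over mature length; the
distribution is histogrammed in bins of 0.2 with the last bin closed at 1.

## Ancient-TE classification

A TE's orthologous alignment is obtained by projection: all alignment
columns whose reference coordinate falls inside the TE, plus
query-insertion (reference-gap) columns strictly between the first and
last selected reference columns of a block. TEs spanning several blocks
concatenate their per-block projections; unaligned inter-block stretches
contribute no columns (logged at debug level). The number of reference
non-gap columns therefore always equals the TE–block overlap length, a
conservation property asserted in tests.

"Insertions/deletions" is read as the gap-column fraction of the
projection — the quantity a pairwise alignment exposes directly; an
indel-*event* based variant would need event parsing and is not
implemented. Thresholds: ancient requires strictly more than
`ancient_min_cols` = 100 columns, with gap fraction < 0.05 (stringent,
strict) or ≤ 0.25 (relaxed, inclusive). An absent projection is
lineage-specific. Stringent calls are a subset of relaxed calls by
construction and by test.

Element-level compartment attribution (for ancient/lineage counts) uses
maximal base overlap with ties broken promoter > exon > intron — counts
here are per element, not per nucleotide, and the promoter-first tie-break
keeps the scarcest compartment from being absorbed by its neighbours.
A possible stricter mode — requiring the orthologous sequence to be
annotated as the same repeat in the second species — is noted but not
implemented (it needs second-species repeat annotation).

## Kimura two-parameter distances

`d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)]`, with P and Q the transition and
transversion proportions over comparable sites. Columns containing a gap
or any non-ACGT character in either row are excluded from the comparable
count entirely (no partial weighting of ambiguity codes; on synthetic data
the effect vanishes). When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the estimator
is saturated: the result carries `defined=False` and no numeric distance,
never a silent infinity. Per-gene rates pool site patterns over all exon
projections before one distance is computed; genes with fewer than 50
comparable sites (`low_conf_sites`, configurable) are flagged
low-confidence, and genes with no aligned exon bases are missing.

## Expression and associations

Microarray mode summarizes each gene as the median of log2 intensities
("median of logs" rather than "log of median": identical ranking since
log2 is monotone, values differ only for even tissue counts). Non-positive
intensities are an input error — no silent pseudo-count. RNA-seq mode pools
counts across tissues first, then computes one RPKM = 10⁹·C/(N·L) per
gene. Correlations are Pearson r with the two-sided t-test on n−2 degrees
of freedom (via `scipy.stats.pearsonr`); rows with missing members are
dropped pairwise per pairing, not listwise, and pairings with fewer than 3
complete rows are skipped with a log entry.

## Promoter scanning

The TATA detector is the IUPAC consensus `TATAWAW` (W = A/T), exposed as a
parameter — the profiling machinery is motif-agnostic, and the consensus
choice is the package's own (log-odds PWM scoring is out of scope). `N`
never matches. A match is addressed by its 5′-most base, offsets relative
to the TSS (−1 = immediately upstream); "match in the −35..−25 window"
also refers to the match start (a center-based convention would shift the
window by half the motif length and is a one-line change). Minus-strand
promoters are reverse-complemented so all sequences read 5′→3′ on the
gene's sense strand.

## Synthetic data: what is emulated, what is not

The generator plants every truth the analysis later estimates:

* **Layout.** Genes (lincRNA and protein-coding shuffled together) are laid
  sequentially per chromosome with inter-gene gaps of at least
  `2·(promoter_len + max TE length) + 100` nt, so facing promoters and
  their reserved spillover zones never collide and all planted compartments
  are exactly the compartments the partitioner recovers.
* **TE planting.** Elements are non-overlapping, full-length
  (120–300 nt), planted per compartment by a budget scheme: each
  interval accrues `density × length` nt of per-class budget, spent on
  whole elements, with the unspent remainder carried to later intervals.
  Global coverage therefore tracks the target within one element length
  (well inside the 3-binomial-SE bands used in tests) without ever
  planting truncated, unclassifiable elements. Promoters are special: a
  100 bp promoter cannot contain a 120–300 nt element, so at most one
  element per promoter covers the budgeted bases inside the promoter and
  extends upstream into the reserved spillover zone; the spilled bases are
  charged against the intergenic density budget. Element lengths make
  every planted element long enough to clear the 100-column ancientness
  threshold; the rare element that cannot be (there are none under the
  defaults, but a config could create them) would be forced
  lineage-specific in truth.
* **Orthologs.** The second species is generated by per-site substitution
  (transition probability `ortho_P` = 0.1, transversion `ortho_Q` = 0.05 —
  also the conditions under which the K2P closed form equals 0.170182) over
  lincRNA exons and ancient TEs; lineage-specific elements are carved out
  of the alignment entirely. Gap columns are planted i.i.d. per site at
  rate `ancient_gap_frac` = 0.01 inside ancient TEs, half deletions and
  half insertions — low enough that binomial fluctuation almost never
  pushes an ancient element over the 5 % stringent bound at the minimum
  element length. Indel-event realism (length distributions, bursts) is
  deliberately absent: thresholds operate on gap-column fractions.
* **Expression.** Latent log2 expression is built as
  `ρ·z(tes) + √(1−ρ²)·ε` with `expr_rho` = −0.25, then observed through
  tissue-level Gaussian noise (SD 0.25 over 24 tissues, small enough that
  the median summary attenuates the correlation by well under the test
  band) and, for RNA-seq, Poisson counts whose RPKM follows the latent
  level. The evolutionary-rate correlation (+0.3) is planted at the
  feature-table level (`simulate_feature_table`), since the genome
  simulator applies one uniform substitution rate to all genes.
* **Defaults as study conditions.** 1100 lincRNA genes on 2 chromosomes
  give ≥ 1e5 nt per compartment (promoters are the binding constraint at
  100 bp each) with planted densities promoter 0.10 / exon 0.20 / intron
  0.35 and ancient probabilities 0.5 / 0.35 / 0.15 — the full ordering
  structure the analysis is meant to detect. The full default study runs
  in roughly a minute on one CPU; smaller configs are used in unit tests.

Not emulated: realistic repeat family sequence (TE bodies are random
sequence tagged by class), nested/fragmented RepeatMasker calls (the
quantifier handles overlap, exercised by hand-built fixtures, but planted
truth stays non-overlapping), isoform structure, GC/base-composition
structure, and demographic or phylogenetic realism. Passing tests
therefore demonstrate the correctness of the measurement machinery under
known truth, not the biology of any real genome.

## Pipeline and reproducibility

All randomness flows from `numpy.random.default_rng` seeded from the
config; generators are pure functions of (config, seed), and report files
use fixed 6-significant-digit formatting, so identical config + seed gives
byte-identical outputs. `manifest.json` records the config snapshot, seed,
input digests, output digests and per-stage row counts — and deliberately
nothing volatile: stage wall times go to the log, keeping the manifest
(and hence the whole report directory) reproducible. Any stage failure
aborts the run with the stage name.

## Numerical choices, degenerate inputs

* Empty compartment: coverage fraction is `None` (undefined), distinct
  from 0; empty classes are excluded from Fisher comparisons.
* Fisher ties: 1e−7 relative tolerance; underflow floored at the smallest
  positive double (see above).
* K2P saturation: explicit `defined=False` signal; zero comparable sites
  raises.
* Histogram: values outside [0, 1] raise; the last bin includes 1.0.
* Constant vectors and n < 3 raise in correlation; `r` is computed from
  data, never imputed.

## Known limitations

* Span-level intergenicity and exon-union compartments are coarser than a
  transcript-isoform-aware treatment.
* Ancientness relies on alignment presence/absence; alignment-pipeline
  artifacts in real MAFs (missing blocks over genuinely orthologous
  sequence) would inflate lineage-specific calls.
* Gap-column fraction is a proxy for indel content; event-level counting
  would differ on clustered gaps.
* Expression handling assumes one record per gene; probe-to-gene
  aggregation is out of scope.
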