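# Methods

## Codon-level ESE/ESS scoring

A codon starting at position *i* of an exon is contained in exactly four
hexamers, starting at *i*−3 … *i*. Each hexamer carries an ESEseq score,
an ESSseq score and a class (E = enhancer, S = silencer, N = neutral).
The codon score averages the ESE and ESS scores of its non-neutral
windows and reports ln(mean ESE / mean ESS). Two undefined outcomes are
kept explicit rather than coerced to 0: `undefined_all_neutral` (all
four windows are class N) and `undefined_no_context` (the codon sits
within 3 nt of a sequence end, so fewer than four windows exist). With
the default `require_full_context=True` boundary codons are dropped —
in the original study design these are a few percent of the sample — and
a caller can instead supply flanking intron sequence to restore full
context.

The ln of a score ratio requires positive means. Score tables whose raw
scores can be non-positive must declare an additive `score_offset`;
nothing is offset silently. This is a disclosed choice: the published
hexamer resources do not state how non-positive raw scores enter a log
ratio.

## Codon frequency profiles

Each hexamer contributes its four complete in-frame triplet tokens
(offsets 0–3), so a set of *n* hexamers yields exactly 4*n* tokens
(1182 → 4728, 1090 → 4360 for the reference high-confidence set sizes).
Per-codon frequencies are additively smoothed,
f(c) = (count + α) / (total + 64α), with α = 0.5 by default so that
ln(ESEf/ESSf) is always finite; α = 0 is allowed only when no codon
count is zero. Frequencies are normalised over codon tokens (not over
all hexamer occurrences), and the smoothing constant is carried in the
output. Both conventions are package choices, disclosed rather than
inferred from any external source.

## Exon profiles and group comparison

Exon cores are trimmed of their first and last 3 nt, which shape the
3′ss/5′ss consensus rather than the auxiliary code. The exon profile is
the unweighted mean of per-hexamer ln(ESE/ESS) over all overlapping
hexamers of the trimmed core, neutral hexamers skipped; cores shorter
than 6 nt give an undefined mean. Averaging per-hexamer log ratios
(rather than taking the log of ratio of averaged scores) is local and
robust; the alternative would weight strong hexamers more heavily.
Exons longer than 350 nt are excluded from group comparisons to avoid
terminal/large-exon bias, and exons are weighted equally when groups are
aggregated. Group inference uses classical one-way ANOVA with
Tukey–Kramer post-hoc comparisons (studentized-range based, valid for
unequal n) and Kruskal–Wallis as the non-parametric companion.

Dataset filters mirror the stringent/extended annotation variants:
`stringent` drops residues inferred only by homology in multiple
alignments, and the metal-site validation filter drops residues whose
structural assignment could not be validated (consumed as a status
column; the validation itself is out of scope).

## Acceptor architecture

Positions are counted with −1 = the last intron nucleotide; exon +1 is
the first exon nucleotide.

- **Splice-site strength.** The default model is a position weight
  matrix scored as Σ log₂(P(base)/0.25) over a 9-mer donor window
  (3 exonic + 6 intronic nt) or a 23-mer acceptor window (20 intronic +
  3 exonic). Externally computed maximum-entropy score tables can be
  plugged in as a window → score mapping; the shipped PWM default keeps
  the pipeline self-contained.
- **Branchpoints.** The built-in caller scans every adenine at
  −60…−13 nt and scores the 7-mer placing that adenine at the branch
  offset under a log-odds weight model built around a CU-rich yUnAy-type
  consensus (the yeast TACTAAC box is the canonical instance of this
  geometry). Ties break to the 3′-most adenine, matching dominant human
  branchpoint positioning. Adenines outside the window are never
  called — distant branchpoints are rare and deliberately out of scope.
  Predictions from dedicated branchpoint tools can be imported from TSV
  and filtered through the same window.
- **AGEZ.** The AG-exclusion-zone length counts nucleotides strictly
  between the nearest upstream AG dinucleotide and the 3′ss AG. When the
  provided sequence contains no upstream AG the value is censored at the
  available scan length and flagged. Anchor points and censoring are a
  disclosed operational definition.
- **PPT score.** Published PPT scores come from branchpoint-predictor
  internals with unpublished formulas; this package substitutes a
  transparent maximum-sum contiguous-segment score over the region
  strictly between the branch adenine and the 3′ss AG, with weights
  T = +1.0, C = +0.5, A = G = −2.0 (empty segment = 0, so the score is
  never negative and is monotone when purines are replaced by T).
  Comparisons built on it are therefore relative (group A vs group B),
  never absolute against external scores.
- **Uridine profile.** 15 indicators for positions −4…−18, the span
  covering both U2AF65 RRM contact peaks.
- **Motifs.** (U)₄ and (C)₄ counts use overlapping occurrences within
  the branchpoint–3′ss region; presence flags accompany the counts
  because published fractions are presence-based.
- **Intron type.** Terminus-based only: GT–AG, AT–AC (U12-type flag), or
  other. Donor/branchpoint U12 matrices are out of scope.
- **−3 association.** For each of exon positions +1…+6 and each base, a
  2×2 table of −3 class (T/C) × base presence yields an odds ratio
  (Haldane +0.5 correction only when a cell is zero) and a 1-df Pearson
  χ² without continuity correction. The per-position base most
  associated with −3T is the odds-ratio maximiser.

## Inclusion analysis

PSI is kept on the 0–100 scale (the convention of the public PSI
resources); EST-derived levels are treated identically after scaling.
Means are stratified by exon, exon × tissue or group; missing tissues
are simply absent (no imputation) and the stratified n accompanies every
mean. Records for exons shorter than 28 nt are excluded before group
comparisons — no published cutoff exists for "small exons and
microexons", so 28 nt (the common microexon boundary) is the default and
is configurable. Candidate exons for regulated splicing are those whose
mean PSI falls below 90% in at least one of the key tissues. Validation
bookkeeping counts exons skipping in ≥1 and in all of the declared
transcriptome contexts, with the percentage rounded to the nearest
integer.

## Statistics

`stattests` wraps scipy.stats behind one result type so the pipeline can
serialize method metadata: one-way ANOVA, Tukey–Kramer (scipy's
studentized-range implementation, which handles unequal n),
Kruskal–Wallis with tie correction, Mann–Whitney U (exact enumeration up
to n = 8 per group without ties, tie-corrected normal approximation
otherwise), Mood's median test as a 2×2 χ² about the pooled median,
Pearson χ² without continuity correction by default, and the exact
binomial test (two-sided p sums outcomes with pmf ≤ pmf(k); one-sided is
the default for directional claims). No multiple-testing correction is
applied anywhere by default; a Bonferroni helper exists for the −3
association tables. The test suite checks every wrapper against
closed-form or full-enumeration oracles and calibrates type-I error
under simulated nulls, never against the wrapped library itself.

## Synthetic data: what it emulates, and what it does not

The generators produce every input format the pipeline reads, with
planted structure at the documented study conditions:

- **Score table** (`gen_score_table`): 1182 E / 1090 S / 1824 N hexamers
  by default (a complete 4096-entry table); scores are log-normal and
  strictly positive with E-class ESE > ESS in expectation
  (exp N(±0.6, 0.25) for the dominant/recessive score, exp N(0, 0.25)
  for neutral hexamers).
- **Exon cohorts** (`gen_exon_cohort`): two groups of 200 exons
  (60–240 nt, whole codons), coordinating codons at fraction 0.2 drawn
  from the Cys/His pool (TGC/TGT/CAC/CAT, Zn) or Asp/Glu pool
  (GAC/GAT/GAA/GAG, Ca). Background codons are chosen greedily toward
  group targets placed δ = 0.3 apart around the table's mean hexamer
  ln-ratio, so the realized group difference in mean exon profiles is
  ≈ δ; an unachievable δ raises with a diagnostic. Annotation flags
  (homology-extension 13.5%, failed validation 11.5%) follow the
  proportions of the reference dataset variants.
- **Introns** (`gen_intron`): a TACTAAC branchpoint box is planted at a
  position drawn uniformly from −45…−18 (within the canonical window,
  away from its edges), with a purine guard and a pyrimidine-only scan
  window so the built-in caller recovers the planted adenine uniquely on
  noise-free draws; the branchpoint–3′ss region is kept AG-free; PPT
  bases are T with probability `ppt_u_content` (0.75 Zn-like, 0.55
  Ca-like by default), remainder mostly C; the terminal NAG follows
  group-specific −3 base probabilities (CAG excess in the Ca-like
  group); AT–AC termini occur at 0.2% (Zn) and 3.5% (Ca).
- **Association records** (`gen_minus3_cohort`): the haplotype
  +1G +2A +3A +4T +5T +6A is enriched (P = 0.55 per position) under −3T
  and uniform under −3C.
- **PSI tables** (`gen_psi_table`): PSI = 100·Beta(50, 1) per
  exon × tissue, i.e. near-constitutive inclusion with mean ≈ 98.
- **Disorder scales** (`gen_disorder_scale`): drawn jointly with the
  supplied amino-acid values at a target correlation (Gaussian
  construction), so the planted r is recovered in expectation.

All generators are bit-reproducible given (spec, seed); the root seed is
split hierarchically per component via stable CRC32 keys.

What passing tests on these cohorts do **not** show: real exons have
correlated hexamer composition, codon usage and GC structure that the
greedy construction does not model; real PPTs contain purine
interruptions and G residues; real branchpoints are degenerate and often
multiple, so 100% recovery holds only for the noise-free planted boxes;
and the absolute values of PPT scores, PWM site scores and synthetic
table ln-ratios are not comparable to scores from the external
published resources. Conclusions transfer as *relative* group contrasts
and as correctness guarantees for the scoring procedures, not as
reproductions of published absolute statistics, which require the
original curated datasets.

## Problem sizes and numerical choices

Default cohort sizes (200 exons/group, 500-intron recovery batches,
100-seed power sweeps, 2000-rep null calibrations) were chosen as the
smallest sizes at which the planted effects are comfortably detectable
and the calibration bands are tight; they run in well under a minute
each on a single core. Degenerate inputs are handled explicitly: empty
groups and all-tied samples give F = H = 0 with p = 1; a zero-variance
side makes a correlation an error, not a NaN; degenerate contingency
tables are rejected. Floating-point comparisons in tests use relative
tolerances except where exact identities (token counts, enumeration
tails) are asserted exactly.

## Known limitations

- The PPT score and branchpoint model are transparent stand-ins
  developed for this package; they are not calibrated against lariat
  sequencing data.
- Maximum-entropy splice-site models are supported only as precomputed
  score tables; the package does not fit them.
- Homology extension and structural metal-site validation are consumed
  as annotation columns; the package neither aligns nor validates
  structures.
- U12-type classification is terminus-based; AT–AC introns with
  non-canonical termini (e.g. AT–AA) fall into "other".
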