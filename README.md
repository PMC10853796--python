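# metalsplice

Splicing-code profiling of human exons that encode metal-coordinating
residues.

## The problem

Exons carry two overlapping codes: the protein code and the auxiliary
splicing code of exonic splicing enhancers and silencers (ESEs/ESSs),
short motifs that promote or repress exon inclusion by the spliceosome.
Residues that coordinate divalent metals sit at opposite ends of the
Irving–Williams stability series: weak binders (Ca²⁺) favour acidic
residues (Asp/Glu), tight binders (Zn²⁺) favour Cys/His. Because the
same nucleotides encode both codes, metal-coordination constraints leave
a footprint on splicing: codons for Zn²⁺-coordinating residues tend to
be splice-repressing, and exons carrying them must compensate through
traditional splicing signals — stronger splice sites, uridine-richer
polypyrimidine tracts (PPTs) and particular 3′-splice-site architecture.

`metalsplice` is a library for quantifying that interplay. It is aimed
at researchers in RNA splicing and regulatory genomics who want to
profile exon cohorts (real or simulated) for:

- **codon-level splicing scores**: for a codon at position *i*, the four
  overlapping hexamers *h* ∈ {*i*−3 … *i*} fully containing it are
  scored with a per-hexamer ESE/ESS table; neutral hexamers are ignored
  and the codon score is ln(mean ESE / mean ESS);
- **codon frequency profiles**: ln(ESEf/ESSf), where ESEf is the
  frequency of a codon among the 4 complete in-frame triplet tokens of
  each of the high-confidence ESE hexamers (1182 ESEs → 4728 tokens,
  1090 ESSs → 4360 tokens), with additive smoothing;
- **full-exon profiles**: mean per-hexamer ln(ESE/ESS) over exon cores
  trimmed of their first and last 3 nt, compared between groups by
  one-way ANOVA with Tukey–Kramer post-hoc tests and Kruskal–Wallis;
- **acceptor architecture**: splice-site strength (PWM log-odds or
  imported maximum-entropy tables), terminal NAG class and the −3
  pyrimidine, branchpoint calls restricted to −13…−60 nt from the 3′ss,
  AG-exclusion-zone length, PPT uridine profile (−4…−18) and a
  maximum-sum-subsegment PPT score (T = +1, C = +0.5, purines = −2),
  (U)₄/(C)₄ motif counts, and U12-type (AT–AC) intron flagging;
- **−3 allele association**: odds ratios and χ² linking TAG vs CAG
  acceptors to the first six exon positions;
- **inclusion levels**: PSI/EST aggregation, microexon exclusion,
  selection of candidates with PSI < 90% in key tissues, and validation
  bookkeeping;
- **disorder correlations**: amino-acid-level ln(ESEf/ESSf) under equal
  or context-specific codon usage, correlated with per-residue disorder
  propensity scales.

A first-class synthetic-data generator (`metalsplice.simulate`) emulates
every input with planted, recoverable structure, so the full pipeline is
testable without any external downloads.

## Worked example

```python
from metalsplice import compare_exon_groups, exon_profile
from metalsplice.simulate import CohortSpec, gen_exon_cohort, gen_score_table

spec = CohortSpec(seed=1, n_exons_per_group=200, delta=0.3)
table, _ = gen_score_table(seed=1)
exons, _ = gen_exon_cohort(spec, table)

profiles = {}
for e in exons:
    profiles.setdefault(e.group, []).append(exon_profile(table, e))
report = compare_exon_groups(profiles)
```

which prints (see `examples/02_exon_groups.py`):

```
ZF: n=200  mean ln(ESE/ESS) = -0.112 (SEM 0.002)
EF: n=200  mean ln(ESE/ESS) = +0.185 (SEM 0.002)
ANOVA: F = 11694.8, p = 3.65e-297
```

The zinc-finger-like (ZF) cohort sits ~0.3 ln units below the EF-hand
(Ca²⁺) cohort — the planted effect — and ANOVA separates the groups
decisively. The `examples/` directory holds one short script per
capability (codon scoring, exon groups, acceptor architecture, PSI
aggregation, −3 association, disorder correlation); each prints the
numbers it computes and a line on what they mean.

A thin CLI mirrors the library for shell use:

```bash
metalsplice make-fixtures --out fixtures --seed 1
metalsplice profile-exons --score-table fixtures/score_table.tsv --exons fixtures/exons.fasta
metalsplice stats binom --k 18 --n 22 --p0 0.5 --alt greater
```

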