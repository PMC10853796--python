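"""Score a metal-coordinating codon from its overlapping hexamers.

A codon's splicing propensity is the average ESEseq/ESSseq score of the
four hexamers that fully contain it, with splicing-neutral hexamers
ignored, reported as ln(mean ESE / mean ESS).
"""

from metalsplice import score_codon
from metalsplice.simulate import gen_score_table

table, _ = gen_score_table(seed=1)

# a TGC (Cys, a typical Zn2+-coordinating codon) in mid-exon context
seq = "GAAGAATGCGAAGAA"
cs = score_codon(table, seq, codon_start=6)
print(f"codon {cs.codon}: mean ESE {cs.mean_ese:.3f}, mean ESS {cs.mean_ess:.3f}")
print(f"ln(ESE/ESS) = {cs.ln_ratio:.3f} over {cs.n_windows_used} non-neutral windows")

# the same codon at the exon start has no upstream context and is dropped
boundary = score_codon(table, seq, codon_start=0)
print(f"codon at exon start: status = {boundary.status}")
# Positive ln(ESE/ESS) marks an exon-promoting context, negative a
# repressive one; boundary codons are excluded from the primary analysis.
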