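"""Allelic association between the -3 pyrimidine and exon starts.

TAG and CAG acceptors are not interchangeable: a -3T allele co-occurs
with a characteristic haplotype at the first six exon positions.  The
generator plants +1G +2A +3A +4T +5T +6A under -3T; the association scan
recovers it from odds ratios of 2x2 tables.
"""

from metalsplice import minus3_association
from metalsplice.simulate import gen_minus3_cohort

records = gen_minus3_cohort(n=5000, seed=4)
res = minus3_association(records)

print("pos  base  OR(-3T vs -3C)  chi2")
for row in res["table"]:
    if row["base"] == res["most_associated"][row["position"]]:
        print(f"+{row['position']}    {row['base']}     "
              f"{row['odds_ratio']:6.2f}      {row['chi2']:8.1f}")
pattern = "".join(res["most_associated"][p] for p in range(1, 7))
print(f"most -3T-associated haplotype: {pattern}")
# The recovered haplotype equals the planted GAATTA pattern; each odds
# ratio well above 1 marks enrichment under the -3T allele.
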