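"""Compare full-exon ESE/ESS profiles between Zn- and Ca-exon cohorts.

Generates a synthetic cohort with a planted 0.3 difference in mean exon
ln(ESEseq/ESSseq) between the Zn-like (ZF) and Ca-like (EF) groups, then
recovers it with exon profiling, one-way ANOVA and Kruskal-Wallis.
"""

from metalsplice import compare_exon_groups, exon_profile
from metalsplice.simulate import CohortSpec, gen_exon_cohort, gen_score_table

spec = CohortSpec(seed=1, n_exons_per_group=200, delta=0.3)
table, _ = gen_score_table(seed=1)
exons, _ = gen_exon_cohort(spec, table)

profiles = {}
for e in exons:
    profiles.setdefault(e.group, []).append(exon_profile(table, e))

report = compare_exon_groups(profiles)
for group, s in report["groups"].items():
    print(f"{group}: n={s['n']}  mean ln(ESE/ESS) = {s['mean']:+.3f} "
          f"(SEM {s['sem']:.3f})")
anova = report["anova"]
print(f"ANOVA: F = {anova.statistic:.1f}, p = {anova.p_value:.2e}")
# The EF - ZF mean difference recovers the planted delta of 0.3;
# a small p confirms the groups are separable at this sample size.
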