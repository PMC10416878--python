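"""Cohort statistics: group comparison and survival by layer number.

Simulates a 135-slide cohort (45 hyperkeratosis/hyperplasia, 82 mild/moderate
dysplasia, 8 severe dysplasia/carcinoma) where thicker epithelium carries a
higher progression hazard, then runs the reporting stages: one-way ANOVA of
the per-slide median layers across diagnosis groups, and a Kaplan-Meier /
Cox analysis after splitting the cohort at the median layer number.
"""

from epilayer import CohortSpec, compare_groups, generate_cohort, survival_split

cohort = generate_cohort(CohortSpec(seed=1))
print(f"cohort: {len(cohort)} slides, groups "
      f"{cohort.groupby('diagnosis_group').size().to_dict()}")

for stat in ("median_layers", "sd_layers"):
    cmp_res = compare_groups(cohort, stat)
    print(f"ANOVA on {stat:13s}: F = {cmp_res.f_statistic:7.2f}, p = {cmp_res.p_value:.3g}")

report = survival_split(cohort)
print(f"median split at {report.threshold:.1f} layers -> groups {report.group_sizes}")
print(f"Cox PH: HR = {report.hazard_ratio:.2f}, Wald p = {report.p_wald:.3g}, "
      f"likelihood-ratio p = {report.p_likelihood_ratio:.3g}")
# A hazard ratio above 1 means slides in the high-layer group progress
# sooner; the ANOVA p-values confirm the groups differ in thickness.
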