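"""A small synthetic severity cohort: index tables, rank-sum panels, group SDs.

Generates healthy-elder and two stroke severity groups (SIAS 4 and SIAS 1),
scores every trial, and runs the pairwise Wilcoxon rank-sum comparisons with
Holm correction on |ESB| and MCS.  Trials are shortened to 6 s at 250 Hz to
keep the example quick; the indexes only need a few usable seconds.
"""

import emgsym as es
from emgsym import CohortGroupSpec, Group, Motion, TrialSpec
from emgsym.synthetic import default_profiles, generate_cohort

profiles = default_profiles()
specs = {
    "healthy_elder": CohortGroupSpec(Group.HEALTHY_ELDER, 5, 3, profiles["healthy"]),
    "sias_4": CohortGroupSpec(Group.STROKE, 5, 3, profiles["sias_4"], sias_level=4),
    "sias_1": CohortGroupSpec(Group.STROKE, 5, 3, profiles["sias_1"], sias_level=1),
}
sessions = generate_cohort(
    specs,
    seed=42,
    trial_spec=TrialSpec(duration_s=6.0, sample_rate=250.0),
    rest_s=0.0,
    motions=(Motion.ELBOW_FLEXION,),
)
records = es.cohort_indexes(sessions)
panels = es.sias_summary(records)

for (index, motion), panel in panels.items():
    print(f"\n=== {index} / {motion.value} ===")
    print("group SD (dispersion grows with severity):")
    for group, sd in panel.group_sd.items():
        print(f"  {group:>14}: sd = {sd:.3f}  (n = {panel.group_n[group]})")
    print("pairwise rank-sum (Holm-corrected):")
    for pair, p, padj, sig in zip(
        panel.pairs, panel.p_values, panel.p_adjusted, panel.significant
    ):
        mark = "*" if sig else " "
        print(f"  {pair[0]:>14} vs {pair[1]:<14} p = {p:.4f}  holm = {padj:.4f} {mark}")

print("\nStarred pairs differ significantly after multiple-comparison control;")
print("severe impairment (SIAS 1) separates from healthy on both indexes.")
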