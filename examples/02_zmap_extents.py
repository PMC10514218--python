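"""Standardize one subject against a normative reference and score atrophy.

Builds an age-bracket reference (the 20 CN nearest in age within a 5-year
window), computes the subject's voxel-wise Z-map, and counts subthreshold
voxels per ROI — the per-subject atrophy score.
"""

import agenorm as ag

cohort = ag.generate_cohort(ag.CohortSpec(seed=1))
subject = next(r for r in cohort.records if r.group == "MCI")

ref = ag.build_bracket_reference(
    cohort.records, cohort.volumes, target_age=subject.age, half_width=5.0, k=20
)
print(f"subject {subject.id}, age {subject.age}")
print(f"reference: {ref.describe()}")
member_ages = [r.age for r in cohort.records if r.id in ref.member_ids]
print(f"member ages span {min(member_ages)}-{max(member_ages)} y")

zmap = ag.compute_zmap(cohort.volumes[subject.id], ref, subject_id=subject.id)
print(f"defined voxels: {zmap.n_defined}, flagged (SD floor): {zmap.flagged_voxels}")
print()
print("subthreshold voxel counts (Z < threshold):")
for roi in list(ag.ROI_NAMES) + ["total"]:
    counts = [ag.count_subthreshold(zmap, cohort.atlas, roi, t)
              for t in (-2.5, -3.5, -4.5)]
    print(f"  {roi:10s}  -2.5: {counts[0]:5d}  -3.5: {counts[1]:5d}  -4.5: {counts[2]:5d}")
print()
print("Counts are largest in MTL/temporal (where the MCI effect is focal)")
print("and shrink monotonically as the threshold deepens.")
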