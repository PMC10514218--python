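"""Fit the W-score regression model and score a subject with it.

W-scores adjust for age by regressing GM on age voxel-wise in CN and
standardizing the residual: W = (observed - predicted(age)) / residual SD.
Unlike bracket references, the model covers every age the regression can
extrapolate to.
"""

import numpy as np

import agenorm as ag

cohort = ag.generate_cohort(ag.CohortSpec(seed=1))
cn = [r for r in cohort.records if r.group == "CN"]

model = ag.fit_wscore_model(
    [cohort.volumes[r.id] for r in cn], [r.age for r in cn], [r.id for r in cn]
)
mtl = cohort.atlas.roi_mask("MTL")
print(f"fitted on {model.k} CN, mean age {model.mean_age:.1f} y")
print(f"median age slope in MTL: {np.median(model.slope_map.data[mtl]):.5f} /yr")
print(f"median residual SD in MTL: {np.median(model.resid_sd_map.data[mtl]):.4f}")

subject = next(r for r in cohort.records if r.group == "MCI")
wmap = ag.compute_wmap(
    cohort.volumes[subject.id], subject.age, model, subject_id=subject.id
)
counts = {t: ag.count_subthreshold(wmap, cohort.atlas, "MTL", t)
          for t in (-2.5, -3.5, -4.5)}
print(f"\nsubject {subject.id} (age {subject.age}), MTL subthreshold voxels: "
      + ", ".join(f"W<{t}: {n}" for t, n in counts.items()))
print()
print("The negative slope is the modeled age-related GM decline; the")
print("subthreshold W count flags the subject's excess (age-adjusted) atrophy.")
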