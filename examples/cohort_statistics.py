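"""Cohort simulation and normative statistics.

Draws a 60-subject synthetic cohort with a programmed age slope of
−0.3 µm/yr and a +8 µm male−female offset on total retinal thickness, then
recovers both effects with the regression-slope t-test and the unpaired
pooled t-test.
"""

import numpy as np

from retidiff import (
    CohortConfig,
    PhantomConfig,
    compute_thickness_maps,
    generate_cohort,
    slope_test,
    unpaired_t_test,
)

pc = PhantomConfig()
cc = CohortConfig(n_subjects=60, seed=7)
subjects, manifest = generate_cohort(cc, phantom_cfg=pc, render_volumes=False)
print(manifest.head())

ages, totals, male, female = [], [], [], []
for s in subjects:
    maps = compute_thickness_maps(s.truth, pc.spacing_um[1])
    peripheral = maps.total[0, 0]  # corner column: no foveal-pit attenuation
    ages.append(s.age)
    totals.append(peripheral)
    (male if s.sex == "M" else female).append(peripheral)

res_age = slope_test(np.array(ages), np.array(totals))
print(f"\nage slope: {res_age.effect:+.3f} µm/yr (programmed {cc.age_slope_um_per_year}),"
      f" t={res_age.statistic:.2f}, p={res_age.p_value:.2e}")

res_sex = unpaired_t_test(np.array(male), np.array(female))
print(f"sex offset: {res_sex.effect:+.1f} µm (programmed +{cc.sex_offset_um}),"
      f" t={res_sex.statistic:.2f}, p={res_sex.p_value:.4f}")
# Both programmed covariate effects are recovered in sign and magnitude
# within sampling error at this cohort size.
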