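"""Non-compartmental analysis of a synthetic 12-horse study.

Generates plasma concentration data with the default study design
(population model with multiplicative assay noise, LOQ censoring at
0.01 ng/mL, the study sampling schedule), runs per-horse NCA and prints
the cohort summary: the numbers to compare against a study's NCA table.
"""

import numpy as np

from isoflupk import ConcProfile, nca_cohort_summary, run_nca
from isoflupk.synthetic import StudyConfig, gen_plasma

plasma = gen_plasma(StudyConfig(seed=42))

results = []
for sid, grp in plasma.groupby("subject_id"):
    grp = grp.sort_values("time_h")
    blq = grp["blq"].to_numpy(bool)
    conc = np.where(blq, 0.0, grp["conc_ng_ml"].fillna(0.0).to_numpy(float))
    profile = ConcProfile(str(sid), grp["time_h"].to_numpy(float), conc, blq, loq=0.01)
    results.append(run_nca(profile))

summary = nca_cohort_summary(results)
print(summary.round(3).to_string(index=False))
# cmax ~1.5 ng/mL and auc_inf ~59 ng*h/mL reflect the generating
# population (typical CL/F 10.1 mL/min/kg gives AUCinf = dose/CL ~ 59);
# pct_extrap stays small because sampling runs to 312 h, ~10 half-lives
# past the peak.
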