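"""Two-stage population fit of the one-compartment model.

Simulates a 12-horse study from known population parameters, fits each
horse by log-scale least squares (the criterion matched to
multiplicative assay error), pools the fits into population estimates,
and compares them with the generating values.
"""

import numpy as np

from isoflupk import ConcProfile, DoseEvent, fit_individual, two_stage_population
from isoflupk.synthetic import StudyConfig, gen_plasma

dose = DoseEvent(dose_mg=20.0, bw_kg=556.5)
plasma = gen_plasma(StudyConfig(seed=7))

fits = []
for sid, grp in plasma.groupby("subject_id"):
    grp = grp.sort_values("time_h")
    blq = grp["blq"].to_numpy(bool)
    conc = np.where(blq, 0.0, grp["conc_ng_ml"].fillna(0.0).to_numpy(float))
    profile = ConcProfile(str(sid), grp["time_h"].to_numpy(float), conc, blq, loq=0.01)
    fits.append(fit_individual(profile, dose))

pop = two_stage_population(fits)
print(f"{'parameter':<22}{'fitted':>10}{'generating':>12}")
print(f"{'tvKa (1/h)':<22}{pop.tv.ka:>10.2f}{8.34:>12.2f}")
print(f"{'tvV/F (L/kg)':<22}{pop.tv.v_f:>10.1f}{27.9:>12.1f}")
print(f"{'tvCl/F (mL/min/kg)':<22}{pop.tv.cl_f:>10.2f}{10.1:>12.2f}")
print(f"{'stdev0':<22}{pop.stdev0:>10.3f}{0.187:>12.3f}")
print(f"{'omega2(Cl)':<22}{pop.omega2_cl:>10.4f}{0.0492:>12.4f}")
# Clearance and volume are well identified from the rich 27-point
# schedule; the absorption rate (and its between-subject variance) is
# the noisiest, since only a handful of samples fall before the ~45 min
# peak.
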