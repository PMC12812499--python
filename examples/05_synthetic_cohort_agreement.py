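"""Agreement between urine-free KrCrW and truth across a noisy cohort.

Draw a small synthetic cohort with the study population's statistics, add
lab noise to the serum samples, recover KrCrW from each patient's single
predialysis creatinine (using the true GCr/VdCr, i.e. the 'baseline
modeled values' use case), and summarize the error — the quantity a
Bland-Altman plot of the method would display.
"""

import numpy as np

from hdkinetics import MeasuredSamples, solve_krcrw
from hdkinetics.cohort import (CohortSpec, MeasurementNoise, generate_cohort,
                               generate_measurements)

spec = CohortSpec(n_patients=8, seed=42)
cohort = generate_cohort(spec)
rng = np.random.default_rng(42)

errors = []
for rec in cohort:
    samples, _ = generate_measurements(rec, MeasurementNoise(lab_cv=0.05,
                                                             collection_cv=0.0),
                                       rng)
    res = solve_krcrw(rec.gcr_mg_day, rec.vdcr_l,
                      MeasuredSamples(pre_scr=samples.pre_scr),
                      rec.schedule, rec.patient)
    errors.append(res.KrCrW - rec.krcrw_ml_min)
    print(f"patient {rec.patient_id}: {rec.schedule.n_sessions}/wk, "
          f"true {rec.krcrw_ml_min:5.2f}, estimated {res.KrCrW:5.2f} mL/min")

errors = np.array(errors)
print(f"\nmean error {errors.mean():+.2f} mL/min, SD {errors.std(ddof=1):.2f}")
print("With the true GCr/VdCr as inputs, 5% lab noise on one serum sample")
print("perturbs the estimate only mildly; in practice the dominant error is")
print("uncertainty in GCr and VdCr themselves (anthropometric estimates).")
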