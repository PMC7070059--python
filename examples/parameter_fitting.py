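"""Recover absorption parameters from a noisy synthetic cohort.

Generates a 10-animal colitis cohort with inter-animal variability and 10%
measurement noise, fits the disease-sensitive pair (ka, kce) per animal with
the central/peripheral constants fixed, and compares against the generator's
ground truth.  The relative errors show what single-animal sampling can and
cannot pin down.
"""

import numpy as np

from gutperm.pk import Dose, fit_oral
from gutperm.synthetic import DSS_PARAMS, MOUSE_FIXED, CohortSpec, generate_pk_cohort

dose = Dose.from_mg_per_kg(2.0)
spec = CohortSpec("DSS", n=10, params=DSS_PARAMS, dose=dose,
                  inter_animal_cv=0.3, noise_cv=0.1, lod=0.5, seed=42)
cohort = generate_pk_cohort(spec)

print(f"{'animal':>10} {'true ka':>10} {'fit ka':>10} {'rel err':>8}  flags")
errs = []
for tc, (_, truth) in zip(cohort.timecourses, cohort.truth.iterrows()):
    res = fit_oral(tc, fixed=MOUSE_FIXED, lod=spec.lod, dose=dose)
    err = abs(res.params.ka - truth["ka"]) / truth["ka"]
    errs.append(err)
    flags = "wide" if res.wide_uncertainty else ""
    print(f"{tc.animal_id:>10} {truth['ka']:10.2e} {res.params.ka:10.2e} "
          f"{err:7.1%}  {flags}")

print(f"\nmedian |relative error| on ka: {np.median(errs):.1%} "
      "(absorption is well identified from a 12-point curve at 10% noise)")
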