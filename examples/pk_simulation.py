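"""Simulate the oral-tracer blood curve for a diseased mouse.

Builds the default colitis parameter set (2 mg/kg oral dose in a 20 g mouse),
solves the three-compartment model, and reports the peak and the absorbed
fraction.  A variant with a delayed second absorption route shows the bimodal
profile seen in sick animals.
"""

import numpy as np

from gutperm.pk import Dose, PKParameters, bioavailable_fraction, cmax_tmax, simulate
from gutperm.synthetic import DSS_PARAMS, MOUSE_FIXED

dose = Dose.from_mg_per_kg(2.0)  # 40,000 ng
times = np.array([0.5, 1, 2, 4, 6, 8, 10, 12, 16, 24, 36, 48.0])

tc = simulate(DSS_PARAMS, dose, times, animal_id="dss-example", group="DSS")
for t, c in zip(tc.times, tc.concentrations):
    print(f"  t = {t:5.1f} h   C = {c:6.2f} ng/ml")

peak = cmax_tmax(DSS_PARAMS, dose)
frac = bioavailable_fraction(DSS_PARAMS)
print(f"\nCmax = {peak['Cmax']:.1f} ng/ml at Tmax = {peak['Tmax']:.1f} h")
print(f"absorbed fraction ka/(ka+kce) = {frac:.2%} "
      "(the rest of the dose is lost in feces)")

bimodal = PKParameters(ka=DSS_PARAMS.ka, kce=DSS_PARAMS.kce,
                       ka2=8e-4, lag2=10.0, **MOUSE_FIXED)
cb = simulate(bimodal, dose, np.linspace(0.5, 48, 96)).concentrations
d = np.diff(cb)
n_peaks = int(np.sum((d[:-1] > 0) & (d[1:] <= 0)))
print(f"with a second absorption route opening at 10 h: {n_peaks} blood peaks")
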