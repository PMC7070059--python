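# gutperm

Quantitative analysis toolkit for near-infrared (NIR) readouts of intestinal
barrier function in preclinical colitis models. An orally dosed ~1 kDa
polyanionic NIR dye crosses inflamed colonic epithelium through the
paracellular leak pathway and is measured in blood; an intravenously dosed
neutrophil-elastase-activated probe (NE680) reports mucosal inflammation by
endomicroscopy and ex vivo imaging. `gutperm` implements the full
quantitative chain behind such a study, for scientists running mouse DSS or
anti-CD40 colitis experiments (or scaling the readout to primates):

- **`gutperm.pk`** — a mechanistic three-compartment oral-absorption model
  (gut → central ⇄ peripheral, with renal elimination `k10` and fecal loss
  `kce` of unabsorbed tracer):

  ```
  dG/dt  = -(ka + kce) G
  dAc/dt =  ka G - (k10 + k12) Ac + k21 Ap
  dAp/dt =  k12 Ac - k21 Ap,      C(t) = Ac(t)/Vc
  ```

  solved exactly (matrix exponential), with constrained fitting of the
  disease-sensitive pair `(ka, kce)` while the IV-derived constants
  `(k10, k12, k21, Vc)` stay fixed, Cmax/Tmax extraction, an optional delayed
  second absorption route for bimodal disease profiles, and the absorbed
  fraction `ka/(ka+kce)`.
- **`gutperm.assay`** — plate-reader fluorescence → blood concentration via a
  linear standard curve with a blank+3·SD detection limit and 3× whole-blood
  dilution; one-way ANOVA with Tukey HSD, percent reduction and fold change.
- **`gutperm.cle`** — the ordinal 0–5 confocal-laser-endomicroscopy severity
  rubric on categorical frame annotations, with modal per-animal aggregation.
- **`gutperm.imaging`** — ROI mean fluorescence intensity, cohort-wide
  min-max normalisation, distal/proximal organ segmentation, IHC
  percent-positive-pixel areas, and histology interval arithmetic (total
  erosion length, inflammation extent from the rectal junction).
- **`gutperm.synthetic`** — generators for every input above (blood time
  courses, plates, frame annotations, ROI/IHC tables) with ground-truth
  sidecars, so the whole pipeline is testable without animal data.

A thin CLI (`gutperm make-synthetic|simulate-pk|fit-pk|assay|score-cle|quantify|report`)
wraps the library for shell use; `examples/` holds one narrative script per
capability.

## Worked example

Simulate the default diseased-mouse blood curve (2 mg/kg oral dose, 20 g
mouse) and recover its absorption parameters from noisy data:

```bash
python examples/pk_simulation.py
python examples/parameter_fitting.py
```

```
  t =   4.0 h   C =  11.55 ng/ml
  t =   8.0 h   C =  13.00 ng/ml
  t =  12.0 h   C =  12.34 ng/ml
...
Cmax = 13.0 ng/ml at Tmax = 8.0 h
absorbed fraction ka/(ka+kce) = 0.34% (the rest of the dose is lost in feces)
with a second absorption route opening at 10 h: 2 blood peaks
```

The disease curve peaks at 13 ng/ml around 8 h — the colonic transit
timescale — while only ~0.3% of the oral dose is ever absorbed; the rest
leaves in feces. Fitting 10 noisy animals (10% measurement CV, 30%
inter-animal CV on `ka`) recovers each animal's absorption rate with a median
relative error of ~4%:

```
    animal    true ka     fit ka  rel err
    DSS-01   2.45e-04   2.33e-04    4.7%
    DSS-02   3.12e-04   3.11e-04    0.3%
...
median |relative error| on ka: 4.4%
```

The assay example (`python examples/permeability_assay.py`) runs a full
plate: it fits a standard curve (slope 122.0, R² 0.9992, LOD 0.096 ng/ml),
converts the diluted blood samples, and finds the disease group at
6.39 ± 0.40 ng/ml vs 1.37 ± 0.07 under epithelial-repair treatment and
0.60 ± 0.05 in naive animals (ANOVA F = 115.3, p = 2.4e-11; Tukey separates
disease from both other groups) — a 78.7% permeability reduction with
treatment and a 10.7-fold disease-over-naive ratio.

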