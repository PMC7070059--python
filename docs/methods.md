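# Methods

## Compartment model

The oral tracer is described by a linear three-compartment system: a gut
depot `G` feeding a central compartment `Ac` (blood) that exchanges with a
peripheral compartment `Ap`, with first-order renal elimination from central
(`k10`) and first-order loss of unabsorbed tracer from gut to feces (`kce`):

```
dG/dt  = -(ka + kce) G        G(0) = D (oral)   or 0 (IV)
dAc/dt =  ka G - (k10 + k12) Ac + k21 Ap        Ac(0) = 0 (oral) or D (IV)
dAp/dt =  k12 Ac - k21 Ap                       Ap(0) = 0
C(t)   =  Ac(t) / Vc
```

Assumptions: all transfers first order (no saturable uptake), instantaneous
gut deposition at the dose time, a single well-mixed central volume, and no
enterohepatic recirculation. `ka` is a *net* absorption rate lumping small
intestine and colon; disease raises `ka` (leakier epithelium) while
`(k10, k12, k21, Vc)` are tracer properties determined from IV dosing and
held fixed during oral fits. The absorbed fraction is `ka/(ka+kce)`.

**Solver.** The system is linear, so the solution is exact:
`x(t) = exp(A t) x(0)`. The state is augmented with two elimination
accumulators (`∫k10·Ac`, `∫kce·G`), making mass balance
(`G + Ac + Ap + eliminated = D`) an algebraic identity of the solution that
the tests check to 1e-6·D over random parameter sets. The matrix exponential
is evaluated through eigendecomposition (vectorised over time points) with a
`scipy.linalg.expm` fallback when the eigenvector matrix is ill-conditioned
(near-defective cases, e.g. coinciding rates). An adaptive ODE integrator
(`solve_ivp`, rtol 1e-12) serves as an independent cross-check in tests only,
never as the production path.

**Bimodal absorption.** Diseased mice can show two blood peaks. This is
modelled as a second absorption route with rate `ka2` that opens on the same
gut amount at `t ≥ lag2` (piecewise-constant system matrix). Routing the
extra rate through the existing depot, rather than splitting the dose into a
second depot, keeps the model free of a dose-partition parameter and makes
`ka2 = 0` reduce to the unimodal model *exactly*, which the tests assert.
The route is off by default.

**Fitting.** `fit_iv` estimates `(k10, k12, k21, Vc)` by least squares on
log concentration (Levenberg–Marquardt on log-parameters for positivity,
5 multiplicative multi-starts, seeded). `fit_oral` estimates `(ka, kce)`
— optionally `(ka2, lag2)` — with the IV constants fixed, minimising squared
residuals of `log(C + LOD/2)`; the log scale weights the 2–13 ng/ml dynamic
range evenly and the LOD/2 floor keeps censored-adjacent values finite. Five
deterministic multi-starts around a scale-informed initial guess (peak height
and time of the data) guard against local minima. A fit whose predicted curve
never clears the detection limit is flagged `at_bound`/`wide_uncertainty`:
absorption is then indistinguishable from background and `kce` is
unidentifiable. Failures return an explicit non-converged status, never
silent defaults.

**Units.** Time h, rates 1/h, amounts ng, volumes ml, concentrations ng/ml.
Doses given in mg/kg are converted with the supplied body mass (default 20 g
mouse, 3 kg macaque in the primate scenario).

## Permeability assay

Fluorescence→concentration uses an ordinary least-squares line through ≥4
standard levels. The detection limit is the standard analytical convention
blank mean + 3·SD, expressed in concentration units through the fitted line
and floored at zero. Whole blood collected as 10 µL into 20 µL EDTA is a 3×
dilution (overridable); back-calculated concentrations are scaled by it and
floored at zero, with readings below the LOD flagged censored. Censored
values enter group summaries as LOD/2 with an audit flag.

Group inference is one-way ANOVA (scipy) with Tukey HSD pairwise contrasts
(statsmodels, Tukey–Kramer for unequal n). Percent reduction is
`(1 − treated/control)·100`, clipped at 0 and flagged when treatment exceeds
control; fold change is a plain ratio with LOD/2 substitution for censored
denominators. No 4PL/5PL calibration and no repeated-measures modelling — the
underlying designs used independent ANOVAs per day.

## Endomicroscopy severity rubric

Frame annotations are categorical: crypt-architecture change, collapsed
crypts (none/present/significant), luminal NE680 (absent/present/high),
NE680-positive area (low/high), fraction of crypts lacking acriflavine
staining, NE680-positive cells within erosions (none/present/exclusive), and
crypt loss. Grades 0–5 form an ordered ladder evaluated from most to least
severe, so overlapping descriptions resolve to the worst matching grade — the
convention of clinical severity indices:

5. only NE680-positive cells within erosions + significant crypt loss
4. >50% acriflavine-unstained crypts + high luminal NE680 + erosion cells present
3. significant collapsed crypts + high NE680 area
2. high luminal NE680 + collapsed crypts present
1. unchanged architecture + luminal NE680 present
0. unchanged architecture + no NE680 signal

Two deliberate design choices where the informal rubric under-determines the
rule. First, the grade-2 description pairs its features with ">50% healthy
crypt structure"; treating that clause as a *requirement* would let a frame's
grade drop from 2 to 1 when the healthy fraction worsens past 50%, violating
ordinal monotonicity. It is therefore treated as descriptive context: grade 2
fires on the severity-monotone pair {high luminal NE680, collapsed crypts
present}. With this reading the rubric is provably monotone — worsening any
single feature never lowers the grade — and the tests verify this
exhaustively over a discretised annotation lattice. Second, frames whose
architecture has changed but that match no ladder rule fall back to grade 1
if they show any NE680 signal, else 0; ">50%" thresholds are strict
inequalities.

Per-animal aggregation is unspecified by the source rubric; the default is
the modal frame score with ties broken toward the higher grade (a severity
index should not understate disease on a tie), with `max` and `median`
selectable. Fewer than three frames is allowed but flagged as low coverage.

## Imaging and histology quantification

MFI is the masked intensity mean; min-max normalisation is applied across a
cohort (all-equal input is an error, not a silent constant). Distal/proximal
segmentation splits the organ mask's bounding box along its longer axis at a
configurable fraction (default 0.5 — the anatomical boundary is not pinned by
the source material); the two submasks partition the organ exactly, so
count-weighted MFIs recombine to the whole-organ MFI to 1e-9. IHC
percent-positive pixels are `100·marker/mucosa`, clamped to [0, 100] against
float round-off; pixel *classification* is upstream and out of scope. Erosion
intervals are merged (sweep over sorted half-open intervals) before summing;
inflammation extent is the contiguous run of >50% crypt loss starting at the
rectal squamous junction (position 0) on a piecewise-constant profile —
disease not contiguous with the junction does not count.

## Synthetic cohorts

The generators emit every pipeline input plus a ground-truth sidecar, with
all randomness flowing from one seed per spec (bit-reproducible).
Multiplicative lognormal noise (unit median, CV-parameterised) models
fluorescence and concentration variability — positive and CV-scaling — and
per-animal `ka` is lognormal across animals; beta distributions model area
fractions. Only group means ± errors are published for the real cohorts, so
these distributional shapes are modelling choices, recorded here.

Default mouse scenario (illustrative, since the IV-derived constants and
fitted values were never printed): `k10=0.25`, `k12=0.2`, `k21=0.25` 1/h,
`Vc=1.4` ml (≈ plasma volume of a 20 g mouse, fast renal clearance of a small
polyanionic dye). The disease absorption pair (`ka=2.34e-4`, `kce=0.0685`
1/h) was calibrated once so the mean 2 mg/kg curve peaks at 13 ng/ml at 8 h,
the published disease profile. Naive animals are modelled as negligible
absorption (`ka=1e-8`) plus a constant 2 ng/ml blood background, matching the
flat naive time course; treated cohorts scale the disease `ka` down. The
severity generator emits each grade's defining annotation per frame, with a
noise rate that slips individual frames one grade up or down. What passing
tests show is therefore internal consistency — the fitters recover what the
generators planted under the stated noise — not agreement with any animal's
physiology; real data add features the generators omit (non-lognormal
outliers, time-varying absorption during disease progression, frame
annotations from imperfect human readers).

## Problem sizes and numerics

Mass-conservation and solver-agreement checks run over 1,000 and 50 random
parameter sets respectively; noisy parameter recovery uses 200 single-animal
replicates at 10% CV and 12 time points; the ANOVA null calibration uses
10,000 simulated three-group experiments (n=10 each). Cmax/Tmax from
parameters uses a 2001-point grid plus bounded scalar polishing (xatol
1e-10). Optimiser tolerances are scipy `least_squares` defaults with
`max_nfev=2000`.

## Known limitations

Linear kinetics only (no saturable absorption), no population/mixed-effects
PK, no allometric scaling beyond user-supplied fixed constants; assay
calibration is strictly linear; the rubric consumes human-annotated features,
not video; imaging starts from masks and areas, not raw classification. The
published "85% reduction" for the dye under treatment is not reproducible
from the printed group means by either plain (80.6%) or baseline-subtracted
(87.1%) arithmetic, so no code path targets that figure; `percent_reduction`
implements the plain definition.
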