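# Methods

## The model

`glucodyn` implements a three-state ODE model of breast-cancer cells
(MDA-MB-231-like) growing in a culture well under glucose limitation and a
glucose-uptake inhibitor (Cytochalasin B, a competitive GLUT1 blocker).
The states are live cells N(t), dead cells D(t) and extracellular glucose
G_total(t); time is in days with t = 0 at the medium change:

    dN/dt = k_p N (1 - N/θ) S_p  -  k_d N S_d  -  k_bys N D/(D+N)
    dD/dt = k_d N S_d  +  k_bys N D/(D+N)
    dG_total/dt = -v N G_acs / (G_acs + G*)

with the complementary state functions

    S_d = (1 - G_acs/(G_acs + G_min)) tanh(t),      S_p = 1 - S_d

and the accessible glucose

    G_acs = G_total / (1 + G_in N).

The three growth/death channels are logistic proliferation, starvation
death, and "bystander" death of live cells driven by factors released by
accumulated dead cells (proportional to the dead-cell fraction, defined as
0 when no cells are present).  Treatment enters only through the
dose-dependent inhibition constant G_in (1/cell): untreated wells have
G_in = 0 and the model reduces exactly to the baseline, treatment-free
model.  Measured confluence (percent well area) converts to cell number
through the carrying capacity θ.

The bystander rate is not a cell-line constant; it follows an exponential
decay in the initial (accessible) glucose level:

    k_bys(G0) = k_bys,0 exp(-α G0) + β.

### Parameters

| parameter | meaning | unit | default | origin |
|---|---|---|---|---|
| k_p | proliferation rate | 1/day | 0.14 | literature value for the cell line |
| k_d | starvation death rate | 1/day | 0.041 | literature value |
| v | glucose consumption | mM/(cell day) | 4.48e-5 | literature value |
| θ | carrying capacity | cells | 8e4 | literature value |
| G* | Michaelis-Menten constant | mM | 0.5 | literature value |
| G_min | minimum glucose for uptake | mM | 0.01 | literature value |
| G_in(2 µM) | inhibition constant | 1/cell | 3.02e-4 | literature point estimate; synthetic truth |
| G_in(10 µM) | inhibition constant | 1/cell | 4.55e-4 | literature point estimate; synthetic truth |
| k_bys,0, α, β | bystander decay law | 1/day, 1/mM, 1/day | 0.8, 0.4, 0.03 | package choice, see below |

`tanh(t)` takes t in days.  The unit is a modelling choice (the source
material does not state one); days make the death ramp span roughly the
first two days of the experiment, which matches when death visibly sets in,
and the choice is recorded here rather than hidden in code.

### A model property worth knowing

"More inhibitor ⇒ pointwise fewer live cells" is *not* a theorem of these
equations.  Inhibition also slows consumption (Eq. for dG_total), so a
treated well conserves its glucose; once an untreated comparison well has
depleted its supply and begun dying, the treated well can overtake it.
The ordering does hold in the non-depleting regime (large reservoir, low
seeding), and the property test asserts it there.

## Synthetic data generator

No raw measurements are publicly deposited, so every downstream stage runs
on synthetic data produced by the forward model plus a noise model.  Two
plate designs are emulated:

* **Dataset A** (no inhibitor): 3 seeding levels × 10 glucose levels
  {0, 0.1, 0.2, 0.5, 0.8, 1, 2, 5, 8, 10 mM} × 4 replicates = 120 wells.
* **Dataset B**: 3 seeding levels × 5 glucose levels {0.5, 1, 2, 5, 10 mM}
  × 3 doses {0, 2, 10 µM} × 4 replicates = 180 wells (60 per dose).

Both are sampled every 3 h for 4 days (33 time points).  Seeding fractions
default to 0.40/0.65/0.80 with a ±3-point uniform replicate jitter
(recorded on the well, so the design stays self-describing); the initial
dead confluence defaults to 2%.  Each well's true bystander rate comes
from the decay law evaluated at its *accessible* initial glucose
G0/(1 + G_in N0).  Measurement noise is additive Gaussian on the
confluence scale (default σ = 0.5 points, i.i.d. across time points and
channels, clipped to [0, 100]); an optional multiplicative component and
an optional lognormal per-well jitter of k_bys (both off by default) are
available.

**Choice of the decay-law defaults.** No literature values exist for the
fitted (k_bys,0, α, β).  We fixed the generator defaults by matching the
forward model to the literature summary of average live-cell percent changes
from day 0 to day 4 (45 design cells spanning all seedings, glucose
levels and doses): a coarse grid over the three coefficients and the
initial dead confluence gives k_bys,0 = 0.8/day, α = 0.4/mM, β = 0.03/day,
D(0) = 2% with an RMSE of ~10 percentage points.  With these values the
synthetic data reproduce the qualitative structure of the measurements:
untreated wells grow at high glucose and shrink at ≤1 mM, every treated
well shrinks, and higher doses kill more.  These are package choices, not
literature values.

**What the generator does not emulate.** Real confluence curves carry
segmentation artefacts, spatial heterogeneity, well-edge effects and
temporally correlated noise; the generator's noise is i.i.d. and the
generating model is exactly the fitted model.  Consequently the
mechanism-based model scores near-perfectly on synthetic validation data
(R² ≈ 1.0), far above what any model achieves on real microscopy data;
passing tests demonstrate the *internal consistency* of the pipeline
(generator ↔ calibrator ↔ predictor) and the correctness of the
statistics, not real-data performance.

## Calibration workflow

Seven stages, run per train/validation round:

1. **Global rates** (k_p, k_d, v shared; one k_bys per well) fitted to the
   untreated dataset by bound-constrained least squares on the pooled live
   + dead confluence residuals (unweighted; the two channels are on the
   same scale and no weighting is claimed anywhere).
2. **Decay law** fitted to the per-well k_bys against initial glucose
   (0 mM wells included; G0 = 0 is a valid abscissa).
3. k_bys expressed as a function of G_in per treated well through the
   accessible initial glucose.
4. **One G_in per nonzero dose** fitted to that dose's wells with k_bys
   pinned by stage 3; untreated wells pinned at G_in = 0.  95% confidence
   intervals from the linearized covariance.
5. **Joint refit**: G_in constrained inside its stage-4 interval, k_bys
   free per well.
6. **Consistency check**: the free rates must decay with accessible
   initial glucose (Spearman trend test at α = 0.05); if confirmed, the
   decay law is refit on the accessible scale, otherwise the stage-2 law
   is kept and flagged.
7. **Prediction** of unseen wells from initial conditions only.

### Numerical strategy

The stage-1/5 problems couple a handful of global parameters to one local
rate per well (123 parameters for the full Dataset A).  They are solved in
two phases:

* **Nested (concentrated) phase** — for any trial global vector, each
  well's scalar k_bys is optimized independently by bracketing grid
  refinement (12 candidates per pass, 7 passes, final precision ~3e-5 on
  the [0, 5]/day bounds).  All wells × candidates are stacked into one
  batched ODE system and integrated in a single adaptive solver call,
  which is what makes the loops affordable.  At the inner optimum the
  concentrated objective's gradient equals the partial gradient with the
  local rates held fixed (envelope argument), so the outer trust-region
  solver sees consistent derivatives.
* **Joint polish** — the nested phase tracks the strongly correlated
  k_d ↔ k_bys valley only approximately, so a joint Gauss–Newton pass over
  (globals, every k_bys) finishes the fit.  Its full Jacobian costs only
  ~5 batched solves because each well's residuals depend on no other
  well's rate (block structure) and all local columns are filled by one
  simultaneous perturbation.

On noiseless data this recovers the generating rates to ~1e-7 relative
error; the 1-D G_in stages use a log-spaced scan plus bounded Brent search
(derivative-free — finite differences at the 1e-4/cell parameter scale
would drown in ODE tolerance noise).

Defaults and bounds: k_p, k_d, k_bys ∈ [0, 5]/day; v ∈ [0, 1e-3]
mM/(cell day); G_in ∈ [0, 1e-2]/cell.  The default initial guess for the
global rates is the literature parameter set; multi-start (log-uniform
over the bounds, seeded) is available via `n_starts` for data where the
literature values are a poor anchor — the concentrated 3-parameter outer
problem proved unimodal from arbitrary starts in our checks, so the
default is a single start.  Integration uses `solve_ivp`: LSODA
(stiff-capable) at rtol 1e-8 for single-well simulation, RK45 at rtol 1e-6
for the batched calibration solves (the stacked system is non-stiff at
realistic rates and LSODA's dense-Jacobian handling scales poorly with
thousands of states).  States are clipped to 0 after integration only
within a small tolerance (1 cell / 1e-5 mM); larger negative excursions
raise an integration error.  G_total may reach 0 and stays there
naturally.

Confidence intervals default to the linearized (Jacobian-based) 95% form,
s²(JᵀJ)⁻¹ with t critical values; a non-parametric bootstrap over wells
(200 draws) is available and is the automatic fallback when the Jacobian
is singular.  Zero residuals give zero-width intervals, which makes the
stage-5 bounds collapse to a point on noiseless data — the constrained fit
then degenerates to per-well local fitting, by design.

## Machine-learning comparison

Exactly five features per (well, time point) row — initial live and dead
confluence, initial glucose, dose, measurement time — and two targets
(live and dead confluence scaled to [0, 1] by θ); no feature selection or
tuning.  Four regressors at scikit-learn defaults: multivariate linear
regression, k-nearest-neighbor with inverse-distance weighting, a decision
tree, and a random forest, each fitted per target (scores are reported per
channel, so per-target fitting keeps the mapping transparent; recorded
here as the package's choice).  Splits are leakage-safe at the well level
and drawn separately within Datasets A and B (75/25 by default: 90 + 135
training wells, 30 + 45 validation wells).  The repeated protocol re-splits
per round (50 rounds by default) and reports mean ± 95% CI; the
mechanism-based predictor plugs into the same harness and is scored with
the identical R² implementation on the identical splits.  Learning curves
subsample *training wells* (5%…100% in 5% steps) to stay consistent with
the leakage rule.

## Evaluation metrics

Per-well error metrics are signed, per time point, on the confluence
scale: error = predicted − measured; percent error = 100 error/measured
(time points with measured value exactly 0 are excluded and counted);
"mean" averages over the course, "at end" takes day 4.  Percent errors on
the dead channel are intrinsically large because the denominator is small
— a 1-point error at 5% measured confluence is a 20% percent error.
Curve agreement uses Lin's CCC with population (1/n) moments.  Partial
correlation is the Pearson correlation of residuals after linear
regression on the control variable (we use initial confluence as the
control when correlating bystander rates with glucose levels).  The
statistics suite wraps one-way/two-way ANOVA, Student's t, Bonferroni
correction (per-comparison α = α/m) and a one-sample KS test against a
fitted normal.

## Problem sizes used in the shipped checks

Noiseless recovery runs on the complete designs (120 + 180 wells).
Stochastic checks are scaled to keep the suite fast: the Monte-Carlo
recovery study uses 20 repeats of single-replicate layouts (18 untreated,
27 treated wells), the ML ordering check uses 5 rounds on the full noisy
designs, and the orchestration smoke test uses 2 rounds of a reduced
layout.  The acceptance script mirrors these sizes.

## Known limitations

* Intracellular metabolism (glycolysis/OXPHOS) and the inhibitor's
  actin-polymerization effect are outside the model by construction.
* Only two nonzero doses are modelled; G_in(dose) is a lookup, not a
  dose-response curve, so prediction at unseen doses is refused rather
  than extrapolated.
* The literature constants θ, G*, G_min are fixed inputs and never
  re-estimated.
* Linearized confidence intervals ignore the curvature of the
  ODE-embedded objective; the bootstrap alternative is exact in
  distribution but expensive for the stage-1 problem.
* On synthetic data generated by the model itself, every validation score
  is optimistic relative to real microscopy data (see the generator
  section).
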