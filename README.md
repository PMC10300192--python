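# glucodyn

Mechanistic and machine-learning modelling of how **glucose accessibility**
limits tumour cell growth.

Triple-negative breast cancer cells (MDA-MB-231) consume glucose, grow
logistically, starve when glucose runs out, and die from a *bystander
effect* driven by factors that accumulated dead cells release.  When the
glucose-uptake inhibitor Cytochalasin B (a competitive GLUT1 blocker) is
applied, the cells can no longer reach all of the glucose in the medium.
`glucodyn` models this with three coupled ODEs for live cells N(t), dead
cells D(t) and extracellular glucose G_total(t):

    dN/dt = k_p N (1 − N/θ) S_p − k_d N S_d − k_bys N · D/(D+N)
    dD/dt = k_d N S_d + k_bys N · D/(D+N)
    dG_total/dt = −v N · G_acs/(G_acs + G*)

    S_d = (1 − G_acs/(G_acs + G_min)) · tanh(t),    S_p = 1 − S_d
    G_acs = G_total / (1 + G_in · N)
    k_bys(G₀) = k_bys,0 · exp(−α G₀) + β

The single new treatment parameter is the dose-dependent **inhibition
constant** G_in (1/cell), which converts the total glucose into the
*accessible* glucose G_acs; untreated wells (G_in = 0) reduce exactly to
the baseline model.  The package provides:

* `glucodyn.model` — the ODE system, forward simulation (single-well and
  batched), unit conversions;
* `glucodyn.datasets` — a synthetic-data generator emulating the two
  plate-scale experimental designs (120 untreated + 180 treated confluence time courses,
  sampled every 3 h for 4 days) with a configurable noise model;
* `glucodyn.calibrate` — the seven-stage calibration / validation /
  prediction workflow (global rates → bystander decay law → per-dose G_in
  in two passes → accessible-glucose consistency check → prediction from
  initial conditions only), with linearized or bootstrap confidence
  intervals;
* `glucodyn.ml` — four scikit-learn baselines (linear, inverse-distance
  KNN, decision tree, random forest) on the five measurable features, with
  leakage-safe well-level splits, repeated evaluation and learning curves;
* `glucodyn.metrics` — signed error metrics, R², Lin's concordance
  correlation coefficient (CCC), accessible-level matching, partial
  correlation and the ANOVA / t-test / Bonferroni / KS statistics suite;
* `glucodyn.workflow` / `glucodyn.cli` — end-to-end orchestration and a
  `glucodyn` command with `synth`, `calibrate-a`, `fit-relation`,
  `calibrate-b`, `predict`, `ml-bench`, `evaluate` and `run-study`
  subcommands.

It is aimed at quantitative cancer biologists who want a calibratable,
interpretable alternative to black-box regressors for in-vitro treatment
data — and a harness for comparing the two fairly.

## Worked example

Synthesize a small untreated dataset, calibrate the cell-line rates, fit
the bystander decay law, estimate the inhibition constants from a treated
dataset, and predict a new well from its initial conditions alone:

```python
import numpy as np
from glucodyn import (
    DesignSpec, GlobalParams, NoiseSpec, TruthParams, Well,
    fit_dataset_a, fit_kbys_relation, fit_gin_constrained, generate_dataset, predict,
)
from glucodyn.model import InhibitionParams

truth = TruthParams(noise=NoiseSpec(additive_sd=0.5))
spec_a = DesignSpec.dataset_a(replicates=1, glucose_levels=(0.0, 0.5, 1.0, 2.0, 5.0, 10.0))
data_a = generate_dataset(spec_a, truth, seed=1)

step1 = fit_dataset_a(data_a)                      # shared k_p, k_d, v + one k_bys per well
for name, est in step1.globals_.items():
    lo, hi = step1.global_ci[name]
    print(f"{name} = {est:.3g}  (95% CI {lo:.3g} .. {hi:.3g})")

ids = list(step1.local_kbys)
relation = fit_kbys_relation([data_a.well(i).G0 for i in ids],
                             [step1.local_kbys[i] for i in ids]).relation
print(relation)

spec_b = DesignSpec.dataset_b(replicates=1, glucose_levels=(0.5, 2.0, 10.0))
data_b = generate_dataset(spec_b, truth, seed=2)
g = step1.globals_
fitted = GlobalParams(k_p=g["k_p"], k_d=g["k_d"], v=g["v"])
for dose, fit in fit_gin_constrained(data_b, fitted, relation).items():
    print(f"G_in({dose:g} uM) = {fit.value:.3g} 1/cell, 95% CI ({fit.ci[0]:.3g}, {fit.ci[1]:.3g})")

well = Well("new", initial_confluence=0.5, G0=10.0, dose=10.0, initial_dead_confluence=0.02)
inhibition = InhibitionParams({0.0: 0.0, 2.0: 3.02e-4, 10.0: 4.55e-4})
sim = predict(well, fitted, relation, inhibition)
print(f"day-4 live {sim.course.live[-1]:.1f}%  dead {sim.course.dead[-1]:.1f}%  "
      f"accessible glucose {sim.g_acs[-1]:.2f} mM of {sim.g_total[-1]:.2f} mM")
```

Output:

```
k_p = 0.139  (95% CI 0.138 .. 0.141)
k_d = 0.0403  (95% CI 0.0379 .. 0.0426)
v = 4.52e-05  (95% CI 4.43e-05 .. 4.6e-05)
BystanderRelation(k_bys_0=0.8194567519956033, alpha=0.3832173808468619, beta=0.01004486775290261)
G_in(2 uM) = 0.000299 1/cell, 95% CI (0.000294, 0.000304)
G_in(10 uM) = 0.000453 1/cell, 95% CI (0.000445, 0.000461)
day-4 live 44.5%  dead 21.2%  accessible glucose 0.39 mM of 6.66 mM
```

Reading it: from 18 noisy wells the calibration recovers the generating
proliferation rate (0.14/day), starvation death rate (0.041/day) and
consumption rate (4.48e-5 mM/cell/day) within their intervals; the
per-dose inhibition constants come back near their generating values
(3.02e-4 and 4.55e-4 1/cell), correctly ordered by dose; and the predicted
10 µM well, although supplied with 10 mM glucose, effectively lives at
~0.4 mM accessible glucose — which is why a third of it is dead by day 4.

The same pipeline is available from the shell, e.g.

```sh
glucodyn synth --dataset A --seed 1 --out a.csv
glucodyn calibrate-a --data a.csv --out cal.json
glucodyn run-study --rounds 5 --seed 1 --out study/
```

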