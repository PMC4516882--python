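# snpkpd

Population K-PD modelling of the mean-arterial-pressure (MAP) response
to sodium nitroprusside (SNP) infusion in children.

SNP is the classic agent for deliberate (controlled) hypotension during
paediatric surgery, yet it is cleared so fast that plasma concentrations
cannot be measured — so ordinary PK/PD analysis is impossible and dosing
has been folklore. The K-PD approach replaces the unmeasurable plasma
profile with a hypothetical effect compartment driven directly by the
infusion-rate history: a one-compartment system with nominal volume
1 L/70 kg whose clearance and volume scale allometrically with weight
(CL ∝ WT^0.75, V ∝ WT). Its concentration Ce drives MAP through an
inhibitory sigmoid Emax model on top of an age-dependent baseline and a
linear drift:

    MAP(t) = S0·(Age/11.33)^0.0338 − Emax·Ce(t)^γ/(EC50^γ + Ce(t)^γ) + α·t

Two latent subpopulations differ in EC50 (drug-sensitive "low" ≈ 138
µg/L vs resistant "high" ≈ 460 µg/L, mixing fraction ≈ 0.70 high) —
clinically important because the sensitive group needs roughly a quarter
of the dose. All subject-level parameters carry between-subject random
effects; residual error on MAP is proportional (≈33 %CV).

The package provides, for this model:

* the deterministic structural core (`snpkpd.kpd_core`) with closed-form
  effect-compartment kinetics for piecewise-constant infusions;
* between-subject variability, the EC50 mixture, residual error
  (`snpkpd.population`);
* a synthetic-trial generator emulating the blinded dose-ranging phase
  the model was estimated from — four arms at 0.3/1/2/3 µg/kg/min for
  30 min, MAP q2 min, five paediatric age strata, safety down-titration
  (`snpkpd.trial`), plus NONMEM-convention CSV I/O;
* nonlinear mixed-effects estimation by basin-summed Laplace marginal
  likelihood with the subject-level mixture, empirical Bayes estimates,
  non-parametric bootstrap and likelihood-ratio tests
  (`snpkpd.estimation`);
* visual predictive checks and goodness-of-fit tables
  (`snpkpd.evaluation`);
* the dose-finding simulations used for labelling guidance: single
  infusions achieving a target MAP reduction, and two-stage load/maintain
  regimens (`snpkpd.dosing`);
* a `snpkpd` command line (`simulate`, `fit`, `vpc`, `bootstrap`,
  `dose-find`, `gof`) with run manifests, and packaged parameter files
  for the published estimates (`snpkpd.io`).

It is aimed at pharmacometricians and anaesthesia researchers who want
to reuse, stress-test, or extend the published model — or to prototype
titration strategies against a simulated paediatric population.

## Worked example

```python
>>> from snpkpd import steady_state_er50, effect_half_life
>>> er = steady_state_er50(460.0, 3.12)      # high-EC50 x published CL
>>> print(f"{er.mg_per_h_70kg:.3f} mg/h/70kg = {er.ug_per_kg_min:.2f} ug/kg/min")
1.435 mg/h/70kg = 0.34 ug/kg/min
>>> print(f"{effect_half_life(3.12, 1.0):.1f} min")
13.3 min
```

ER50 — the steady-state infusion rate producing half the maximal MAP
drop — is 0.34 µg/kg/min for the resistant subpopulation and 0.103 for
the sensitive one; the 13.3-min effect half-life says the response
equilibrates within about three quarters of an hour and washes out as
fast.

Dose finding from the shell (defaults to the bootstrap-average
estimates, which reproduce the published dosing tables):

```
$ snpkpd dose-find --age 10.93 --weight 34.2 --subpop low --reduce 10 --horizon 5
0.347 ug/kg/min for 10 mm Hg reduction at 5 min (low EC50)

$ snpkpd dose-find --age 0.58 --weight 8 --subpop low --target-map 60
load 0.562 then maintain 0.159 ug/kg/min (target 60 mm Hg by 3 min, hold 30 min, low EC50)
```

The first says a typical 11-year-old in the sensitive subpopulation
needs ~0.35 µg/kg/min to shed 10 mm Hg within 5 min; the second gives a
7-month-old's load-then-maintain pair for holding 60 mm Hg. Simulate a
trial and refit the model:

```bash
snpkpd simulate --n 100 --seed 1 --out trial.csv
snpkpd fit --data trial.csv --out fit.json
snpkpd vpc --data trial.csv --fit fit.json --reps 100 --seed 2 --out vpc.csv
```

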