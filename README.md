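# enhv — normative modelling of brainstem and cerebral volumes

`enhv` is a Python toolkit for estimating the **expected normal healthy
volume (ENHV)** of five brain regions — the whole brainstem, its subfields
(medulla oblongata, pons, midbrain) and the cerebrum — from a person's
intracranial volume (ICV), age and sex, and for expressing measured
volumes as percentages of that expectation. It is aimed at researchers
quantifying regional brain atrophy (for example in chronic diffuse axonal
injury, DAI) from FreeSurfer morphometry, who need a head-size correction
stricter than the conventional *proportions method* (volume / ICV):
regional volumes are *not* proportional to ICV — regressions of volume on
ICV have clearly positive intercepts — so dividing by ICV over-corrects
small regions.

## The model

Each region receives one of three ordinary-least-squares equation forms,
chosen by a fixed decision procedure on a healthy cohort (sex coded
male = 1, female = 0):

```
form 1:  ENHV = a·ICV + b
form 2:  ENHV = (1 − sex)·(a_f·ICV + b_f) + sex·(a_m·ICV + b_m)
form 3:  ENHV = (1 − sex)·(a_f·ICV + b_f·age + c_f) + sex·(a_m·ICV + b_m·age + c_m)
```

1. **Screening** — Pearson correlation of each regional volume with age
   and with ICV; a covariate enters only if p < 0.05 (strict, two-sided).
   ICV is always retained.
2. **Interaction** — F-test of the sex×ICV term in
   `volume ~ sex + ICV + sex:ICV` on (1, n−4) df; significance triggers
   sex-stratified regression, fused into one equation via the sex dummy.
3. **Validation** — on an independent healthy cohort, the intraclass
   correlation ICC(A,1) (two-way model, single measures, *absolute
   agreement*) between measured volumes and model ENHVs; a region's
   equation is considered valid when ICC > 0.4.

A subject's atrophy is then quantified as the **ENHV-adjusted volume**
`100 · measured / ENHV` (% of ENHV; 100 = exactly as expected,
`percent loss = 100 − adjusted`). The package ships the published
coefficient set for East Asian adults (`published_model()`) and can fit
the same model family to any healthy cohort.

## Worked example

No subject-level data are distributed; the seeded generator in
`enhv.simulate` emulates cohorts with the published summary statistics
(demographics, ICV–volume correlations, patient atrophy levels and their
link to posttraumatic-amnesia duration).

```python
from enhv import (GeneratorConfig, NormativeVolumeModel, adjusted_volume_table,
                  generate_dai_cohort, generate_healthy_cohort, pta_correlation,
                  subjects_to_frame, summarize_loss, validate_model)

cfg = GeneratorConfig()
cohort = subjects_to_frame(generate_healthy_cohort(cfg, n=182, seed=11))
results = NormativeVolumeModel(cohort).fit()
print(results.summary())
```

```
Normative ENHV model
  fitted on n=182 healthy subjects (103 male / 79 female)

  region          form  coefficients
  ------------------------------------------------------------------
  whole_brainstem 2     a_f=0.00223222, b_f=21002.8, a_m=0.0105672, b_m=8979.06
  medulla         1     a=0.00142648, b=2549.51
  pons            2     a_f=0.00239285, b_f=10097.2, a_m=0.00624921, b_m=5153.75
  midbrain        2     a_f=0.000936035, b_f=3944.66, a_m=0.00210174, b_m=2378.41
  cerebrum        3     a_f=0.274378, b_f=-1537.22, c_f=622266, a_m=0.447682, ...

  region          sex x ICV F   df        p         stratified
  whole_brainstem 23.4          (1, 178)  2.83e-06  True
  medulla         1.43          (1, 178)  0.234     False
  ...
```

The builder reproduces the published decision path on this draw: only the
medulla pools the sexes (form 1), only the cerebrum uses age (form 3),
and the interaction test has its (1, 178) degrees of freedom at n = 182.
Validation on a disjoint cohort and application to a synthetic patient
group:

```python
holdout = subjects_to_frame(generate_healthy_cohort(cfg, n=47, seed=12))
for r in validate_model(results, holdout):
    print(f"{r.roi}: ICC={r.icc:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}] {r.band}")

dai = subjects_to_frame(generate_dai_cohort(cfg, n=22, seed=13))
adjusted = adjusted_volume_table(results, dai)
print(summarize_loss(adjusted)[["mean_adjusted", "mean_percent_loss"]].round(1))
```

```
whole_brainstem: ICC=0.463 [0.203, 0.661] fair
medulla: ICC=0.335 [0.063, 0.563] poor
pons: ICC=0.438 [0.181, 0.640] fair
midbrain: ICC=0.563 [0.329, 0.731] fair
cerebrum: ICC=0.841 [0.731, 0.908] excellent

                 mean_adjusted  mean_percent_loss
whole_brainstem           85.9               14.1
medulla                   92.9                7.1
pons                      84.0               16.0
midbrain                  93.6                6.4
cerebrum                  89.8               10.2
```

The patient group has lost ~14% of its expected brainstem volume, with
the pons most affected, and the loss correlates with injury severity
(`pta_correlation(adjusted)` gives the partial correlations of adjusted
volume with posttraumatic-amnesia duration, controlling time since
injury).

## Command line

```sh
enhv simulate healthy --out hc.csv --seed 1          # synthetic cohort CSV
enhv ingest SUBJECTS_DIR demographics.csv cohort.csv # collect FreeSurfer stats
enhv fit cohort.csv model.json                       # fit + summary
enhv predict medulla 1.5e6                           # -> 4675.0 (published model)
enhv validate holdout.csv --model model.json         # per-region ICC report
enhv adjust dai.csv adjusted.csv                     # ENHV-adjusted volumes
enhv compare --dai dai.csv --hc hc.csv --out report.json
enhv correlate dai.csv corr.json                     # PTA partial correlations
```

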