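# Methods

## The normative model

The toolkit models the volume of five regions — whole brainstem, medulla
oblongata, pons, midbrain, cerebrum — in healthy adults as linear
functions of intracranial volume (ICV, mm³), and, where warranted, age
(years) and sex (dummy-coded male = 1, female = 0). The modelling
assumptions are deliberately minimal:

* regional volume is linear in ICV with a non-zero intercept (the data
  that motivated the approach show positive intercepts everywhere, which
  is exactly why the volume/ICV "proportions" correction is biased);
* sex may modify the ICV slope, in which case the sexes are fitted
  separately and the two regressions are fused with a sex dummy;
* age enters only where its marginal (Pearson) correlation with volume is
  significant — in practice only the cerebrum, whose volume declines
  roughly linearly over the adult range, while brainstem volumes are
  age-stable;
* residuals are treated as homoskedastic within a region (ordinary least
  squares; no weighting).

The fitting procedure is a fixed decision path, so that a model fitted on
any healthy cohort is fully reproducible from the cohort alone:
Pearson screening (strict two-sided p < 0.05; ICV always retained, with a
warning if its correlation is for some reason not significant), then the
sex×ICV interaction F-test in `volume ~ sex + ICV + sex:ICV` with
(1, n−4) degrees of freedom — the "two-way ANOVA" is this continuous-ICV
linear model, not a binned factorial, which is what the quoted degrees of
freedom imply — then per-sex or pooled OLS. The strictness of the
threshold matters in one documented corner: a correlation with p exactly
0.050 does *not* qualify.

The decision grid maps (stratify, use-age) to equation forms 1/2/3. The
combination "pooled but age-using" has no published precedent and no form
number; it is represented as a degenerate form 3 with identical female and
male blocks and `sex_stratified=False`. A single-sex cohort makes the
interaction test impossible; `fit()` then falls back to pooled ICV-only
(form 1) equations for every region and warns, rather than guessing at
sex effects it cannot estimate.

The published coefficient set is stored verbatim at its printed precision
(3 significant figures) and serialized as decimal text; predictions from
`published_model()` therefore carry that rounding (up to ~0.5% per term).

## Validation

A model is validated on an independent healthy cohort by ICC(A,1) — the
two-way, single-measure, *absolute agreement* intraclass correlation —
between measured volumes and model predictions, with the McGraw–Wong
F-based 95% interval (Satterthwaite denominator df) and the MSR/MSE
F-test against ICC = 0. Absolute agreement is the point: a constantly
biased predictor correlates perfectly but agrees poorly, and the
normative use case cannot tolerate constant bias. Negative estimates are
reported as computed and classified "poor". Reliability bands are
left-closed intervals — poor < 0.4 ≤ fair < 0.6 ≤ good < 0.75 ≤
excellent ≤ 1 — closing the small gaps (0.59–0.6, 0.74–0.75) left by the
conventional verbal definition; validity is ICC > 0.4.

A structural property worth knowing: when the predictor is an OLS fit and
the true ICV–volume correlation is r, the large-sample ICC(A,1) between
measurement and prediction is 2r²/(1+r²) (prediction variance is r² of
measurement variance; no bias term). For the medulla, whose ICV
correlation is only ≈0.50, this puts the expected ICC at ≈0.395 — right
at the 0.4 validity threshold — so medulla validity on any given
validation cohort of ~47 subjects is close to a coin flip, and published
medulla ICCs above 0.5 imply validation samples whose ICV correlation
drew above ≈0.6. The other regions sit comfortably above the threshold.

## Adjusted-volume analysis battery

Atrophy is quantified per subject and region as
`adjusted = 100·measured/ENHV` (% of ENHV), with
`percent loss = 100 − adjusted` its exact complement, and the
conventional proportion `measured/ICV` computed alongside as comparator.
The patient-vs-control battery uses two-tailed nonparametric tests
throughout: Mann–Whitney U per quantity with Bonferroni correction
(default family size 6 = ICV + five regions; configurable since the
choice of family is a convention), Wilcoxon signed-rank for whole
brainstem vs cerebrum within patients, Friedman plus three
Bonferroni-corrected pairwise Wilcoxon tests across the brainstem
subfields, and Pearson or first-order partial correlation (closed form,
p on n−3 df) of posttraumatic-amnesia (PTA) duration — an integer number
of weeks, its clinical reporting convention — with adjusted volumes,
controlling for time since injury (months). Correlation p-values are
reported uncorrected.

Numerical conventions: exact-distribution p-values are used for
Mann–Whitney and Wilcoxon whenever the data are tie-free and each sample
has ≤ 25 observations (scipy's exact enumeration), otherwise the normal
approximation with tie correction; a constant covariate makes the partial
correlation collapse to the plain Pearson correlation (residualisation is
a no-op); zero paired differences short-circuit the Wilcoxon test to
p = 1.

## Synthetic cohorts

The generator exists because no subject-level data are distributable. It
emulates the *joint statistical structure* the model assumes, with every
default pinned to a published summary statistic:

* healthy cohort: n = 182, 99/182 male, age uniform on 18–68 y, pooled
  ICV 1.544e6 ± 1.92e5 mm³ with a male–female mean offset of 10% of the
  mean ICV (the offset is not published; 10% matches the pooled SD and is
  in the range reported for adult sexual dimorphism in head size) —
  within-sex spread is derived by removing the offset variance, and
  within-sex deviations are truncated at ±3σ to keep volumes below ICV;
* regional volumes: true equation value (published coefficients) plus
  independent Gaussian noise whose SD per region is solved *in closed
  form* from the target population ICV–volume correlations
  (0.496/0.567/0.677/0.614/0.828 for medulla/pons/midbrain/whole
  brainstem/cerebrum) using exact mixture moments — not tuned by
  simulation. The cerebrum's age correlation is then emergent (≈ −0.29
  for a target of ≈ −0.33; within sampling error at n = 182);
* DAI cohort: n = 22, 17/22 male, age uniform 21–61 y; PTA weeks from a
  rounded log-normal (median 7.5, σ_log 0.75) clipped to 1–26; time since
  injury from a log-normal (median 53 months, σ_log 0.9) clipped to
  5–355; per-region adjusted volumes from a linear latent-severity model
  `adjusted = mean + r·sd·z_PTA + sd·√(1−r²)·ε` with the published group
  means/SDs and PTA correlations, and measured volume reconstructed as
  `adjusted/100 × ENHV`.

What the generator does **not** emulate — and what passing tests on it
therefore cannot certify about real data: inter-regional residual
covariance (volumes are conditionally independent given ICV/age/sex, so
the generated whole brainstem is not the exact sum of its subfields);
non-Gaussian residuals and segmentation failure modes; scanner or site
effects; any nonlinear age trajectory; lesion anatomy. The cerebral
tissue-class split (≈50/44/6% of cerebrum) and the superior cerebellar
peduncle (≈0.9% of whole brainstem, always < 3%) are generated only so
FreeSurfer-format fixture files are syntactically faithful.

Cohort engineering mirrors the study design: an age-controlled 4:1
permuted-block split (sort by age, blocks of five, random within-block
assignment; a final short block of r subjects sends round(r/5) members to
the small group, half-way ties favouring the large group — so 229
subjects split 183/46) and matched-control selection by per-subject
uniform random numbers, keeping the top n per sex. Everything is
deterministic under a seed, down to byte-identical CSV and fixture files.

## Replication experiments and their honest limits

`enhv.experiments.replicate_study` re-runs the whole design — fit
(n = 182), validate (n = 47), held-out control adjustment (n = 60),
patient battery (n = 22) — across independent replicate seed sets; the
acceptance script reports median held-out quantities over 50 replicates.
These sample sizes and replicate counts keep the full suite within a few
minutes on one CPU while leaving Monte-Carlo error well below the effects
of interest.

The replication rates have intrinsic ceilings that are properties of the
study's effect sizes, not of the implementation:

* the *decision path* (forms 1/2/2/2/3) reproduces in only ~half of
  replicates: each no-age region carries a ~5% age-screening false
  positive, and interaction powers at the published effect sizes are
  ~0.7–0.95 per region, so the five-way conjunction is capped well below
  0.9;
* the held-out per-region mean adjusted volumes have SEM 0.9–1.4% at
  n = 60 (their per-subject SDs, implied by the correlation calibration,
  reproduce the published 7–11%), so all five means land inside a
  ±1.5-point band around 100 in fewer than half of replicates;
* minimum regional ICC > 0.4 hinges on the medulla ceiling derived above;
* the PTA partial correlations (true values −0.53 to −0.57 at n = 22)
  are each significant with probability ≈0.7, jointly ≈0.4 — the
  published single-cohort result sits at the same knife edge (its
  uncorrected p-values were 0.005–0.012).

The pons-greatest-loss ordering, by contrast, is robust (~0.9 of
replicates), as are all deterministic properties (coefficient recovery,
oracle equivalences, arithmetic identities).

## Known limitations

The published coefficients apply to Japanese and other East Asian adults;
other populations need a refit. The model is linear and cross-sectional:
no splines, centiles or longitudinal trajectories. PTA enters as integer
weeks; day-level resolution is not reconstructed. The toolkit consumes
FreeSurfer's text outputs only — it never runs segmentation, and it
trusts the upstream quality control.
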