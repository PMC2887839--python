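# agscore

Pharmacogenetic scoring and analysis toolkit for acenocoumarol dosing.

Patients on coumarin anticoagulants (acenocoumarol, warfarin) differ widely
in the weekly dose that keeps them stably anticoagulated, and much of that
variability is genetic: reduced-function *CYP2C9* alleles (\*2, \*3) slow the
drug's clearance, and *VKORC1* promoter/intronic variants (c.-1639G>A,
497T>G, 1173C>T) alter the drug target's expression. `agscore` implements an
additive **acenocoumarol-dose genotype score (AGS)** over these five
polymorphisms, plus the downstream statistics used to evaluate such a score
against stable-dose phenotype groups. It is aimed at pharmacogenetics
researchers who want a tested, reusable implementation of the score and its
evaluation pipeline, with a seeded synthetic-cohort generator so every stage
is exercisable without patient-level data.

## The score

Each marker's genotype gets a genotype score GS ∈ {0, 1, 2} counting the
alleles associated with **higher** dose requirement (0 = "very slow
metaboliser" genotype, 1 = "slow", 2 = "normal"). For the five-marker panel

AGS = (100 / 10) × (GS<sub>CYP2C9\*2</sub> + GS<sub>CYP2C9\*3</sub> +
GS<sub>VKORC1 −1639</sub> + GS<sub>VKORC1 497</sub> + GS<sub>VKORC1 1173</sub>)

so AGS ∈ {0, 10, …, 100}; 100 is the profile most tolerant of high doses.
With missing calls the score rescales to the markers actually scored
(`strict=True` refuses incomplete profiles). Genotype→score assignments are
configuration (JSON), not code; the packaged default covers the panel above.

Downstream, the package classifies subjects into stable-dose groups
(low < 7, medium 7–28, high > 28 mg/week) and provides: metaboliser-count
tables with Pearson and ordinal-trend χ² tests, ANCOVA-adjusted group means
with Bonferroni contrasts, ROC analysis with Mann–Whitney AUC,
Hanley–McNeil/DeLong intervals and Youden cut-offs, odds ratios for the
dichotomised score (2×2 Woolf and IRLS logistic regression), and a
normal-approximation two-mean sample-size calculation.

## Worked example

```python
import agscore as ag

cfg = ag.default_simulation_config()          # group sizes 34/141/18
cohort = ag.simulate_cohort(cfg, seed=7)      # seeded synthetic cohort
results = ag.AgsStudy(cohort=cohort, seed=7).fit()
print(results.summary())
```

prints (abridged):

```
Per-group AGS
              n  mean_ags  sem_ags  mean_dose  mean_age  pct_male
dose_group
low          34     65.59     2.57       3.41     62.43     55.88
medium      141     71.77     1.20      18.08     63.88     51.77
high         18     78.33     2.18      44.22     63.76     55.56

Adjusted means (covariates: sex, age)
        adjusted_mean    se
low             65.63  2.43
medium          71.76  1.19
high            78.35  3.33
  low vs high: diff=+12.71  p(Bonferroni)=0.0070

ROC (high-dose coding): AUC=0.660 [0.517, 0.803] p=0.0281; cut-off score > 60 (sens=0.944, spec=0.354)
ROC (low-dose coding): AUC=0.626 [0.517, 0.734] p=0.0232; cut-off score <= 50 (sens=0.265, spec=0.912)

Association (high-dose): AGS > 70: OR=2.930 95%CI [1.051, 8.168] p=0.0399
```

Reading it: the synthetic high-dose group carries systematically higher
scores than the low-dose group (adjusted means 78 vs 66, Bonferroni
p = 0.007), the score discriminates the high-dose group with AUC ≈ 0.66,
and subjects scoring above 70 have about 2.9-fold odds of being high-dose —
the qualitative behaviour the score is designed to show when the generating
genotype frequencies actually differ between dose groups.

The same pipeline runs from the shell:

```bash
agscore simulate --seed 7 --out sim/
agscore analyze --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv --out report/
```

Real data enter as a genotype table (or VCF matched by rsID) plus a
phenotype table; see the docstrings in `agscore.io`.

## Documentation

`docs/methods.md` describes the model, its assumptions, the synthetic-data
generator and its limits, and the numerical conventions (tie handling,
thresholds midway between discrete scores, separation handling in the
logistic fit).
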