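# Methods

## The additive genotype score

The AGS treats each of five biallelic CYP2C9/VKORC1 polymorphisms as an
independent additive contribution to acenocoumarol dose requirement. Per
marker, the genotype associated with the highest stable dose scores 2, the
heterozygote 1, the lowest 0; the sum over m scored markers is normalised to

    AGS = 100 * raw_sum / (2 * m)

which for the full panel is `10 * raw_sum`, a 0–100 score in steps of 10.
The additive model deliberately ignores dominance and epistasis; it is the
simplest score a clinician can compute from a genotype report.

Two algebraic identities follow on complete five-marker profiles and are
enforced as internal-consistency checks: with n0/n1/n2 markers scored
0/1/2, `AGS = 10*(2*n2 + n1) = 10*(5 + n2 − n0)`. The same linearity lets a
group's mean AGS be recovered from the marginal distributions of n2 and n1
alone (`10*(2*E[n2] + E[n1])`), whatever their joint distribution — this is
how the packaged count tables yield derived group means of 64.1 (low-dose)
and 81.7 (high-dose).

**Missing calls.** The default rescales to the scored markers, preserving
the 0–100 reading; `strict=True` refuses incomplete profiles. No imputation
is attempted.

**Configuration, not constants.** The genotype→score map is a JSON document
so other panels can be scored; the packaged default is the five-marker
CYP2C9\*2 / \*3, VKORC1 −1639/497/1173 panel. One packaged frequency value
(rs9923231, high-dose GG) is restored from an evident transcription error
(35.0 → 50.0, the row's complement to 100%), and each per-group triplet is
renormalised to sum to one; the config's `notes` field records this.

## Dose groups

Stable weekly dose partitions subjects into low (< 7 mg/week), medium and
high (> 28 mg/week). Only the strict outer inequalities are defined by the
phenotype; boundary doses (exactly 7 or 28) fall in the closed middle
interval. The partition is exhaustive and exclusive on [0, ∞).

## Input handling

Genotypes arrive as delimited text (columns matched by marker key or rsID)
or as VCF matched **by rsID only** — coordinates are never interpreted, and
an allele pair differing from the panel's is a hard error rather than a
strand flip, because A/T and C/G markers make silent complementation
unsafe. All genotypes are canonicalised to alphabetical allele order;
phase separators in VCF GT fields are ignored.

## Group inference

*Adjusted means.* AGS is regressed on dose-group indicators plus covariates
(sex and age by default, optionally 0/1 co-medication flags) by ordinary
least squares; adjusted means are model predictions with every covariate at
its sample mean, and the three pairwise contrasts are Wald tests with
Bonferroni multiplication. A rank-deficient design (e.g. a covariate
constant within groups) raises rather than silently dropping columns.

*Count-table tests.* The metaboliser-count layout (subjects per group with
exactly k = 0..5 genotypes of one category) is tested two ways. The default
is Pearson's χ² on the groups×k table after dropping all-zero rows, with no
pooling and no continuity correction; expected cells below 5 are counted
and flagged because they make small-sample p-values fragile. The `trend`
option is the 1-df linear-by-linear association statistic `(N−1)·r²`,
treating both k and the dose group as ordinal. On the packaged tables the
two conventions disagree sharply: Pearson gives p = 0.235 / 0.868 / 0.373
(very-slow / slow / normal) while the trend test gives 0.0072 / 0.452 /
0.011. Published analyses of this table shape report 0.005 / 0.242 / 0.006
— a pattern the ordinal test reproduces and the unpooled Pearson test does
not, which is why both are always reported and small expected cells are
flagged. No tested convention reproduces those three decimals exactly; the
exact cell handling behind them is not recoverable from the printed counts.

*Sample size.* Per-group n for a two-mean comparison uses the normal
approximation `n = 2·(z_{1−α/side} + z_power)² / d²` with d standardised by
either the root-mean-square ("pooled", default) or the plain average of the
two SDs. For the reference scenario (means 84.1 vs 62.2, SDs rebuilt from
SEMs 3.4·√18 and 4.8·√34, power 95%) the default two-sided pooled form
gives 27 per group; the one-sided averaged-SD variant gives 21. Published
figures of 21/group for this scenario correspond to the latter convention;
the default stays two-sided/pooled and the variants are flags.

## Diagnostics

*ROC.* The AUC is the Mann–Whitney probability that a random case outscores
a random control, ties counting one half — identical to the trapezoid area
under the empirical curve (asserted against a brute-force pairwise oracle).
Because the AGS is discrete (multiples of 10), thresholds are evaluated
midway between adjacent observed scores and reported as the inclusive bound
on the observed scale (">70", "≤60"). The low-dose analysis uses a
direction flag (score ≤ t is test-positive) instead of score negation so
reported cut-offs read naturally. The AUC standard error is Hanley–McNeil
by default with DeLong's placement-based estimator as an option; the test
against AUC = 0.5 is a Wald z on that SE. The Youden cut-off maximises
sensitivity + specificity − 1, breaking ties toward higher sensitivity and
then the lower threshold.

*Associations.* The dichotomised score (≤60 vs the low-dose outcome,
>70 vs the high-dose outcome by default — options, since cut-offs are
data-derived) is analysed both as a 2×2 cross-product OR with a Woolf
log-scale interval (Haldane +0.5 when a cell is empty) and by
maximum-likelihood logistic regression via iteratively reweighted least
squares (convergence when max |score| < 1e-8, at most 50 iterations, one
polish step after convergence; coefficients beyond ±30 on the logit scale
are treated as separation and raise, pointing to the corrected 2×2 path).
On the saturated single-predictor model the two routes agree to numerical
precision, which the tests assert.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes:
fixed dose-group sizes (default 34/141/18), per-group genotype frequency
triplets for each marker (the packaged defaults are the observed per-group
genotype frequencies), doses uniform within each group's interval (the
open-ended high group capped at 56 mg/week, twice the threshold), sex
Bernoulli (male fraction 0.518), age normal (mean 64, SD 13.9 — the SEM of
1 at n = 193 scaled up; draws clipped to [18, 100]), and optional Bernoulli
co-medication flags (none by default, as no prevalences are published).
Genotype frequencies are used directly rather than via allele frequencies,
so no Hardy–Weinberg assumption is made.

What it does **not** emulate: linkage disequilibrium between the VKORC1
SNPs (markers are sampled independently within a subject; real VKORC1
variants are strongly correlated, so simulated AGS distributions are
narrower-tailed than real ones), dose–genotype feedback from titration, or
co-medication effects on dose. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated generating model,
not clinical performance on real cohorts. A joint-frequency mode can be
emulated by supplying degenerate or user-specified triplets per group.

`simulate_null_cohort` forces the size-weighted pooled frequencies on every
group, making AGS independent of dose group — the reference condition for
the type-I-error and AUC ≈ 0.5 calibration checks (500 replicates at
200/group, sizes chosen so expected cells are large enough for the χ²
approximation).

## Numerical conventions and edge cases

- Genotype canonicalisation: alphabetical allele order everywhere.
- Dose boundaries: closed middle interval, checked property-based.
- χ²: all-zero rows dropped, nothing else pooled; expected < 5 flagged.
- ROC with one class present, profiles with every call missing, zero
  effect sizes in the power formula, and two-zero-cell tables without
  correction are hard errors, not warnings.
- Reports round only at the presentation layer; JSON carries full
  precision, and re-fitting identical inputs is byte-identical.

## Known limitations

- The evaluation statistics published for the original patient cohort
  (AUC 0.630/0.676, OR 2.356/3.347, adjusted means 62.2/84.1) require
  subject-level data that were never deposited; the package reproduces the
  quantities that are derivable from printed tables and verifies its
  estimators against independent oracles instead.
- The additive equal-weight score ignores effect-size differences between
  markers; it classifies dose groups and does not predict continuous dose.
- ANCOVA assumes homogeneous covariate slopes across groups; no interaction
  terms are fitted.
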