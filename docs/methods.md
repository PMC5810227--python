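# Methods

This note records the statistical models, algorithms, parameter
conventions and numerical choices behind `gbrecall`. The package
implements a genotype-based recall (GBR) workflow: a large genotyped
cohort is screened for a variant with enough minor-allele homozygotes,
carriers are recalled in matched triads for deep phenotyping (an oral
glucose tolerance test, OGTT), and phenotypes are analyzed under an
additive genetic model.

## 1. Synthetic cohort generator (`gbrecall.simulate`)

### Genotypes

Markers are biallelic and stored minor-allele oriented (0/1/2 copies of
the minor allele; missing = −1). For a marker with minor-allele
frequency *p* and `n_subpops` subpopulations with divergence parameter
*F* (`fst_like_divergence`), subpopulation frequencies follow the
Balding–Nichols model:

    p_s ~ Beta(p (1−F)/F, (1−p)(1−F)/F)

so E[p_s] = p and Var[p_s] = F·p(1−p). Within a subpopulation,
genotypes are Binomial(2, p_s) draws, i.e. Hardy–Weinberg conditional
on the local frequency. With `n_subpops = 1` or `F = 0` this collapses
to plain HWE at frequency *p*.

Close relatives are simulated by gene dropping. The last
`2 × related_pairs` rows form pairs; for a `full_sib` pair two parental
genotypes are drawn per marker and each sibling inherits one allele
from each parent, for `parent_offspring` the child inherits one allele
from the stored parent and one from a random founder. Missingness is
per-marker Bernoulli(`missing_rate`), independent of genotype.

What the generator emulates: allele-frequency drift between mild
population strata, HWE within strata, first-degree relatedness, and
missing-at-random genotyping dropout. What it does not emulate:
linkage disequilibrium between markers (markers are independent),
genotyping batch effects, informative missingness, or assay-specific
cluster artifacts (those enter only through the optional
`marker_scores` channel of the QC cascade).

### Covariates and phenotypes

`simulate_covariates` draws age ~ Uniform(`age_range`, default 45–75 y),
sex ~ Bernoulli(`sex_ratio`, 1 = female), self-reported fasting time
~ Normal(11, 2.5) h clipped to [4, 24], and independent flags for
diabetes (8%), anticoagulant use (5%) and lipid-lowering medication
(15%). These rates are the package's own defaults for a late-middle-aged
population cohort and can be overridden upstream.

`simulate_phenotypes` builds a quantitative trait
y = β·dosage + β_age·age + β_sex·sex + ε, ε ~ N(0, `noise_sd`²), with
missing dosage mean-imputed. β (`beta_per_allele`) is in phenotype-SD
per minor allele when `noise_sd = 1` and the phenotype is later
z-scored.

### OGTT curves

One test produces glucose, insulin, NEFA and glycerol at
t = 0, 15, 30, 60, 90, 120, 180 min. The post-load excursion is a
gamma-shaped pulse

    f(t) = (t/t_p)^k · exp(k (1 − t/t_p)),   k = t_p / t_d

which is 0 at t = 0, peaks at exactly 1 when t = t_p (`peak_time`,
default 40 min) and decays with time scale `decay_time` (60 min).
Glucose is `basal_glucose + glucose_excursion_peak · f(t)` (defaults
5.5 + 4.0 mmol/L). Insulin is
`basal_insulin · (1 + response_scale · f(t) / m)` where *m* is the
per-person insulin-sensitivity multiplier — smaller *m* means a larger
insulin response to the same glucose load. NEFA and glycerol decline
linearly from their basal values (400 and 80 µmol/L) to
`(1 − supp)`-times basal by 120 min and stay suppressed; the
suppression fraction is capped at 0.99 so values remain strictly
positive. Multiplicative log-normal noise with coefficient of variation
`noise_cv` (default 5%) is applied with the mean-preserving offset
−σ²/2 on the log scale.

The multiplier deliberately affects only the post-load response; fasting
hyperinsulinemia must be expressed through `basal_insulin`. This keeps
the fasting-state indices (HOMA-IR, revised QUICKI) and the whole-body
index (Matsuda) controllable separately.

### Participation

`simulate_response` draws Bernoulli invitation outcomes at per-genotype-
group probabilities; the default `EffectSpec.participation_probs`
(0.31, 0.44, 0.40) reflects typical recall-study response rates ordered
(major-allele homozygotes, heterozygotes, minor-allele homozygotes).

## 2. Genotype QC (`gbrecall.qc`)

### Exact Hardy–Weinberg test

`hwe_exact_pvalue` is the exact test conditional on observed allele
counts. For n samples with r copies of the rarer allele, the
probability of h heterozygotes (h ≡ r mod 2) is

    P(h) ∝ 2^h · n! / [ ((r−h)/2)! · h! · (n − (r+h)/2)! ]

The p-value sums P(h′) over all configurations no more probable than
the observed one. Probabilities are computed by the standard two-sided
recurrence from the modal heterozygote count —
P(h−2) = P(h)·h(h−1) / ((r−h+2)(2n−r−h+2)) going down and the mirrored
form going up — then normalized. The recurrence avoids factorial
overflow and is O(r); the test suite and the reproduction script verify
it against an independent direct log-Γ enumeration to ≈1e−12.
Monomorphic markers return p = 1. The conditional-exact test is
conservative: under the null the rejection rate at α is ≤ α, which the
calibration tests assert one-sidedly.

### Cascade

`apply_qc_cascade` applies, in order:

1. **Sample filters** — reported-vs-genetic sex discordance (a
   precomputed boolean, since the simulated panel carries no sex
   chromosomes); ancestry outliers beyond 3 SD on either of the first
   two MDS components; heterozygosity outliers beyond 5 SD within each
   of two MAF strata (< 1% and ≥ 1%); sample call rate < 98%.
2. **Marker stage A** — call rate < 97%, exact HWE p < 1e−4, and, when
   a `marker_scores` frame is supplied, cluster separation < 0.4 or
   GenTrain score < 0.6.
3. **Marker stage B** — call rate < 99% and HWE recomputed on the
   surviving samples.
4. **Relatedness** — greedy pruning at pairwise relatedness > 0.1875
   (halfway between full siblings at 0.5 and second-degree relatives at
   0.25 on the pi-hat scale); the pair member with the lower call rate
   is removed, ties broken lexicographically.

Every removal is logged with a reason code in a `QcReport`. The
thresholds are the `QcThresholds` defaults and mirror standard
exome-array practice.

Ancestry components are classical multidimensional scaling (MDS) of the
pairwise 1 − IBS-proportion distance matrix, computed over mutually
non-missing markers via one-hot genotype-indicator matrix products (the
whole distance computation is three float32 GEMMs, which keeps a
2,500-sample cohort tractable on one core). Relatedness is the
method-of-moments estimator: allele-frequency-standardized dosages
(mean-imputed where missing) averaged over markers, scaled so
duplicates ≈ 1 and full siblings ≈ 0.5.

Caveat: the cascade is idempotent in its absolute filters (call rates,
HWE, scores) but not in its *relative* ones — re-running on filtered
data recomputes means and SDs, so the 3-SD/5-SD rules can flag a small
number of new tail samples. Similarly, a near-duplicate pair distorts
the MDS embedding and may be removed at the ancestry step before the
relatedness pruner sees it; the end state (no close pair survives) is
the invariant, not the step at which it is reached.

## 3. Variant screen (`gbrecall.screen`)

Eligibility keeps directly genotyped protein-altering variants
(missense or LOF) with at least `min_minor_hom` (default 10)
minor-allele homozygotes — the quantity that limits a recall study's
rarest group. Phenotypes are prepared per `PhenotypeSpec`: optional
natural-log transform, exclusion of diabetics and of samples fasting
fewer than the required hours, then z-scoring. The association scan is
per-variant ordinary least squares of the prepared phenotype on
minor-allele dosage plus covariates, complete-case per variant, with
two-sided t p-values on the dosage coefficient. The OLS core
(`gbrecall._stats.ols_fit`) is a thin `numpy.linalg.lstsq` wrapper that
raises on rank deficiency; `check_collinearity` names the offending
column by testing which single-column removals restore full rank.
P-values are floored at `numpy.finfo(float).tiny` rather than reported
as exact zeros. `rank_candidates` flags a variant as feasible when
`n_minor_hom × assumed_response_rate ≥ target_group_size`.

## 4. Recall design (`gbrecall.recall`)

Exclusions remove anyone on anticoagulants or lipid-lowering drugs or
with diagnosed diabetes (deep metabolic phenotyping is confounded or
contraindicated in those groups); each exclusion is logged. Matching is
homozygote-anchored: every minor-allele homozygote in the pool is an
anchor, and for each anchor one heterozygote and one major-allele
homozygote of the same sex within ±`age_window_years`/2 (total window 2
years by default) are drawn uniformly without replacement from the
eligible candidates. Candidates are sorted before the seeded draw so
the plan is invariant to input row order. Anchors that cannot be fully
matched are still invited and reported in `plan.unmatched`.
`assign_batches` randomizes whole triads into invitation waves so a
matched triple is never split across clinic periods. `clinic_export` is
structurally blinded — the genotype group and anchor columns are simply
absent from the frame handed to clinic staff.

`tally_participation` reports per-group invited/included counts and
`rate_percent = round(100 × included / invited)` to the nearest integer
(NaN for a group with no invitees). `genotype_concordance` compares
recall-phase confirmatory genotypes to the cohort calls and returns the
concordant fraction plus the discordant sample ids.

## 5. OGTT metrics (`gbrecall.ogtt`)

All formulas follow the units convention: glucose mmol/L, insulin mU/L,
NEFA and glycerol µmol/L. The mmol/L→mg/dL conversion uses
18.016 mg/mmol (glucose molar mass).

- **HOMA-IR** = G₀[mmol/L] × I₀[mU/L] / 22.5. The calibration point
  G₀ = 4.5, I₀ = 5 gives exactly 1.0.
- **Matsuda index** = 10000 / √(G₀·I₀·Ḡ·Ī) with both glucose terms in
  mg/dL. The means Ḡ, Ī are trapezoidal time-averages over **0–120 min
  only** (the index's defined window); the 180-min sample never enters.
  A flat curve at G = 100 mg/dL, I = 10 mU/L gives exactly 10, and a
  flat curve generally reduces to 10000/(G_mgdl × I) — useful closed
  forms for testing. Because I₀ appears in both the fasting product and
  the mean, scaling all insulin values by c divides the index by c (not
  by √c).
- **Revised QUICKI** = 1 / (log₁₀ G₀[mg/dL] + log₁₀ I₀[mU/L] +
  log₁₀ NEFA₀[µmol/L]). NEFA below 10 raises an error: values that
  small almost certainly indicate mmol/L was supplied where µmol/L is
  required, and a silent unit error would shift the index materially.
- **AUCs** are plain trapezoids (`numpy.trapezoid`) over 0–180 min for
  glucose/insulin and 0–120 min for NEFA/glycerol; a series ending
  before the window raises, and interior missing timepoints integrate
  over the observed grid with a logged notice.

`index_panel` assembles these per sample from a long-format frame and
optionally adds BMI and waist-hip ratio from anthropometry (height
outside 100–250 cm raises, catching cm/m confusion).

## 6. Recall analysis (`gbrecall.analysis`)

`recall_regression` fits, per phenotype, OLS of the (optionally
natural-log-transformed) trait on minor-allele dosage plus covariates
(default age, sex and three ancestry components), complete-case, and
requires n ≥ number of parameters + 2. The default log-transform list
covers the right-skewed metabolic traits (insulin, HOMA-IR, AUCs, NEFA,
glycerol, triglycerides, fasting glucose). `baseline_tests` checks
group comparability with one-way ANOVA on age and a Freeman–Halton
exact test (Fisher's exact generalized to r×c, implemented by
enumerating the free (r−1)×(c−1) block with fixed margins in
log-factorial space) on the sex-by-genotype table. `group_summary`
prints publication-style "mean (sd)" strings on the original scale
alongside the transformed-scale p-value, because readers interpret raw
units but inference should respect the skew.

## 7. Operating characteristics (`gbrecall.calibration`)

`beta_recovery` and `type_one_error` run the generator and the scan end
to end over many fresh cohorts. At n = 922, MAF 0.14, β = 0.19 SD per
allele, 200 replicates recover the mean estimate within ±0.02; at the
null, 2,000 replicates hold the rejection rate at 0.05 within
Monte-Carlo error both at cohort scale (n = 922) and at recall scale
(n = 40). These sizes are the package's own calibration anchors chosen
to bracket the two regimes the workflow operates in.

## 8. Reproducibility and numerics

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; sub-seeds are spawned (never reused
  across purposes) and reduced mod 2³¹−1 where an `int` seed is
  required.
- Genotypes are int8; the IBS/MDS path uses float32 GEMMs, everything
  statistical is float64.
- PLINK bed/bim/fam I/O is a self-contained 2-bit codec
  (variant-major, magic `6c 1b 01`); on load, markers stored
  major-allele-oriented are flipped to the package's minor-allele
  convention with a logged notice. The VCF writer emits minimal
  VCFv4.2 with REF = major, ALT = minor.
- p-values are never reported as 0; the floor is
  `numpy.finfo(float).tiny`.
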