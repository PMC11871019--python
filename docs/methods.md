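# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Survival model and Martingale-residual phenotype

Age is the analysis timescale. A subject enrolled at age `e_i` and observed
to age `t_i` (dead: δ_i = 1; administratively censored: δ_i = 0) is at risk
exactly on the left-open interval `(e_i, t_i]` — delayed entry, also called
left truncation. The genotype-free null model is Cox proportional hazards,
`H(t|Z) = H0(t)·exp(Zβ)`, with sex and principal-component covariates.

Fitting maximizes the Breslow-tie partial likelihood by Newton–Raphson with
step halving (max 100 iterations). Convergence requires the score max-norm
below 1e-8; a monotone likelihood (a covariate separating all events)
leaves the fit flagged non-converged rather than silently wrong. Risk-set
sums are accumulated as a single signed suffix sum over the merged
exit (+w) / entry (−w) key sequence; computing them as a difference of two
independent suffix sums loses enough precision through cancellation that
Newton–Raphson stalls above tolerance on cohorts of a few thousand. Step
acceptance tolerates log-likelihood decreases within 1e-11·(1+|ll|), the
float-noise scale of the objective; without this margin, step halving can
freeze at machine-noise plateaus.

The Breslow baseline cumulative hazard is
`Ĥ0(t) = Σ_{t_d ≤ t} d_d / Σ_{at risk} exp(Zβ̂)`, a nondecreasing step
function jumping only at event ages. Martingale residuals accrue expected
events over each subject's own window:

```
M_i = δ_i − [Ĥ0(t_i) − Ĥ0(e_i)] · exp(Z_i β̂)
```

At the MLE they sum to zero exactly (a property of the Breslow estimator —
the identity holds at any β, which the tests exploit). Residuals are ≤ 1,
unbounded below, and strongly right-skewed when the death fraction is
small; this skewness matters for the rare-variant tests (below).

Kaplan–Meier curves use the product-limit estimator with delayed entry
(at-risk count = #{entry < t} − #{exit < t}). Carrier hazard ratios come
from a Cox fit with the carrier indicator as the first design column;
p-values are two-sided Wald. With tens of carrier events, Wald intervals
sit slightly below nominal coverage (simulated coverage ≈ 94% for 95%
intervals at ~60–90 carrier events); this is the standard small-sample
behavior of the Wald construction, not a defect of the optimizer, and it is
why the recovery acceptance bar is 93%.

## Mixed-model stand-in

At biobank scale the residual phenotype is scanned with linear mixed models
to absorb relatedness and population structure. Synthetic cohorts are
unrelated by construction, so this package replaces the mixed model with a
fixed-effect least-squares projection: residuals are orthogonalized against
[1, covariates] and then each variant is tested by simple linear regression
(two-sided t). This is the package's single largest deliberate
substitution. Consequences: no genomic-relatedness shrinkage, and the scan
is exact OLS — under the simulated null its genomic-control λ is ~1.00 and
p-values are uniform, which the tests verify. Reported betas are on the
adjusted-residual scale.

## Rare-variant tests

Within a (gene, class) set with genotype submatrix `g_ij` (missing treated
as non-carrier — conservative for a collapse) and Beta(1, 25)-density MAF
weights `w_j` (the customary choice; nothing in the analysis pins another):

* **Burden** — score test of the binary collapse `G_i` against the adjusted
  residuals: `z = G̃'y / (σ̂ √(G̃'G̃))` with `G̃` the covariate-projected
  indicator and `σ̂²` the residual variance. Mean-based: powerful when
  effects share a direction.
* **SKAT** — `Q = Σ_j (w_j g̃_j' y)² / σ̂²`, a variance-component kernel
  statistic; its null is the eigenvalue mixture of the weighted, projected
  kernel `Z'Z`, robust to opposing effect directions.
* **SKAT-O** — `Q_ρ = (1−ρ)·Q_SKAT + ρ·Q_burden` over the grid
  ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; the minimum per-ρ p-value
  is calibrated by decomposing along the shared burden direction and
  numerically integrating the 1-df conditioning variable out (256-node
  Gauss–Legendre on the chi-square probability transform). The final p is
  clamped to [min-p, grid-size × min-p]. When every per-ρ p saturates at
  the float floor, the selected ρ is tie-broken by the standardized
  exceedance of Q_ρ.

The burden test uses the collapsed indicator while SKAT/SKAT-O use the
per-variant submatrix; with one variant and no homozygotes all three
p-values coincide, which is asserted to 1e-6.

**Kurtosis adjustment.** The chi-square-mixture null assumes normal scores.
Martingale residuals at a ~9% death fraction have excess kurtosis ≈ 5–6,
and rare-variant scores sum only a handful of them, so the normal-theory
mixture understates the null variance — simulated SKAT type-I error at
α = 0.05 was ≈ 0.087 uncorrected. Each score component `T_r = u_r'y`
(eigenvectors of the projected kernel) therefore gets
`Var(T_r²) = 2 + γ̂₂·Σ_i u_ri⁴`, with γ̂₂ the empirical excess kurtosis of
the adjusted residuals and the quartic eigenvector sum measuring how
concentrated the component is on few subjects; `T_r²` is gamma-matched so
third and fourth cumulants stay consistent, and the mixture tail is then
evaluated by the usual noncentral chi-square moment match. Setting γ̂₂ = 0
recovers the normal theory exactly. After adjustment all three tests hold
type-I error within (0.04, 0.06) at α = 0.05 on 2,000 null genes, and
analytic p-values track 50,000-permutation oracles within |Δlog10| ≈ 0.07
(tolerance 0.3).

**Quadratic-form tails.** The standalone `quadform_pvalue` evaluates
`P(Σ λ_j χ²₁ > q)` by Ruben's series — a probability-weighted expansion in
central chi-squares with scale β = min λ, whose truncation error is bounded
by the unassigned weight, so it is accurate in both bulk and far tail
(verified against 1e6-draw Monte Carlo). Eigenvalues below 1e-7 of the
trace are dropped first; if the series has not absorbed all but 1e-6 of the
mass in 20,000 terms (extreme eigenvalue spread), the noncentral chi-square
moment match is used instead. A single eigenvalue is handled exactly.

**Thresholds.** Family-wise thresholds are α/n with a display value that
truncates (never rounds) to two significant digits, matching the printed
conventions (0.05/599 → 8.3e-5; 0.05/42 → 1.1e-3; 0.05/1670 → 2.9e-5). The
gene-wide default is the constant 7.4e-7: it nominally accounts for genes ×
classes × methods, but no single printed divisor reproduces it, so it is
carried as a configurable constant rather than derived. The per-variant Cox
screen keeps variants with MAC ≥ 3 and corrects over the number actually
tested.

**Five-fold CV** partitions subjects (seeded), refits the null model and
residuals on each 80% split, reruns burden and SKAT-O, and counts
significant folds per gene; genes falling below 10 carriers in a fold are
skipped there and recorded.

## Hardy–Weinberg exact test

The conditional exact test: given allele counts, every heterozygote count
of matching parity is enumerated, probabilities computed in log-gamma space
and normalized, and the p-value sums configurations no more probable than
the observed one (tie comparison tolerates 1e-9 relative float error).
A test over every genotype triple with total ≤ 200 against an
exact-integer enumeration oracle agrees to 1e-12. Hard calls are used
(dosages rounded when calls are absent): the exact test is defined on
counts. Retention boundaries follow the printed exclusion rules read as
complements: info ≥ 0.3, missingness ≤ 0.05, MAF ≥ 0.001, HWE p ≥ 1e-6,
all inclusive on the keep side; the rare-variant MAF bound is strictly
< 1%.

## VAF and CHIP calls

VAF = alt reads / depth, computed per heterozygous carrier only;
homozygous calls and zero-depth carriers are excluded (the latter logged).
Carrier-level VAFs are pooled across a gene's variants and the 95% CI of
the mean comes from a seeded percentile bootstrap (10,000 replicates)
resampling carriers — the carrier, not the variant, is the exchangeable
unit here, since each carrier contributes one sequencing observation. A
gene is called left-shifted iff the CI upper bound is strictly below 0.5.
Percentile (not BCa) intervals: with ≥ 100 carriers and depth ~30 the mean
is effectively Gaussian and the refinement would change nothing material.
By construction the germline false-call rate is the one-sided CI error
(≈ 2.5%), and a somatic mean VAF of 0.30 at ≥ 100 carriers is separated
from 0.5 by > 10 standard errors, so discrimination is essentially
deterministic — the simulations confirm ≥ 95% / ≤ 5% with wide margin.

## PheWAS-lite

Binary phenotypes: logistic regression of phenotype on carrier + age + sex
(effect reported as OR); continuous: OLS (effect = slope). Phenotypes with
fewer than 100 cases/observations are dropped and logged; tested + dropped
reconciles to the input count. Separation leaves a flagged, non-converged
row rather than a silent drop. The phenome-wide threshold is
α / (number tested). Ordinal/multinomial models are out of scope.

## Synthetic cohort model

The generator's defaults encode the study conditions the analysis assumes:

| parameter | default | rationale |
| --- | --- | --- |
| enrollment age | Uniform(40, 69) | recruitment window of the emulated cohort |
| follow-up | Uniform(12.8, 16.8) yr | 2006–2010 recruitment to a late-2022 censor date |
| death fraction | 0.09 | ~35.5k deaths in ~394k subjects |
| baseline hazard | Weibull, shape 8 | adult-mortality-like acceleration; closed-form inverse-transform sampling |
| sex log-HR | 0.45 | realistic male excess mortality |
| PCs | 10 iid N(0,1) | the real covariate distributions are not public; generic stand-ins by declaration |
| rare gene | k variants, carrier freq < 5%, one het variant per carrier | rare-variant reality: compound carriers are negligible |
| read depth | Poisson(30), zero-resampled | WES-like coverage |
| somatic VAF | Beta centered on the gene's mean, concentration 50 | simplest left-shifted clonal-fraction model |

Survival sampling is inverse-transform from the conditional Weibull:
`T = t0 + b·(H0(e) + E/θ)^{1/a}`, `E ~ Exp(1)`, `θ = exp(η − η̄)`, censored
at entry + follow-up (optionally capped by an administrative age). The
optional hazard onset age `t0` (default 0) zeroes the hazard below `t0`,
both adding realism (negligible pre-adult mortality) and providing an exact
no-events-possible regime for degenerate-case tests. When a death-fraction
target is set, the Weibull scale is calibrated by root-finding on the
covariate-free expected event fraction given the realized entries and
censor ages. Deliberately, the calibration ignores the linear predictors:
conditioning the baseline on the realized genetic draws couples the two and
measurably distorts carrier-effect confidence coverage (simulated coverage
dropped from ~95% to ~93% when theta entered the calibration).

One global seed fans out through `numpy.random.SeedSequence` children per
stage, so any stage is reproducible in isolation and whole-bundle
regeneration is byte-identical.

**What the generator does not emulate** — linkage disequilibrium, related
individuals, population stratification beyond iid PC stand-ins,
X-chromosome dosage, imputation error structure (a scalar INFO score only),
sequencing error in read counts, and compound heterozygotes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to confounding that the mixed-model machinery
of the full-scale analysis exists to absorb.

## Problem sizes in the test and acceptance suites

Calibration uses 2,000 null genes at n = 2,000 (10 variants, carrier
frequency 1.5% — within the emulated cohort's carrier-rate range and large
enough that score asymptotics are meaningful at desk scale); permutation
oracles use 20 fixtures at n = 500 with 50,000 permutations; recovery uses
200 cohorts of n = 10,000 with 3% carriers at true HR 2.0; CHIP
discrimination uses 200 gene replicates of 150 carriers at depth 30. These
sizes were chosen so the full suite completes in a few minutes on one CPU
while keeping every binomial acceptance band several standard errors wide.

## Known limitations

* The kurtosis adjustment corrects second moments per score component and
  gamma-matches higher cumulants; at astronomically small p (< 1e-12) the
  relative error of any moment-matched tail grows, and SKAT-O's selected ρ
  between near-tied saturated p-values is decided by a standardized
  statistic rather than the (unresolvable) p ordering.
* Wald carrier CIs undercover by ~1% at tens of carrier events (above).
* The VCF reader splits multiallelic records on hard calls; per-alt dosages
  for multiallelic sites are reconstructed from genotypes, not read from DS.
* `interface.run_pipeline` scans every variant passing common-variant QC,
  including annotated rare variants present in the same VCF; at biobank
  scale arrays and WES are distinct files and the overlap is empty.
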