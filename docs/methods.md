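# Methods

This note documents the models, numerical choices and known limitations of
`stabprs`.  It is written for users who want to understand what the
pipeline computes and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Synthetic cohort generator

The generator exists because individual-level genotype/phenotype cohorts
of the kind this pipeline targets cannot be shared.  It emulates the
features the pipeline's stages actually exercise; it is first-class,
tested code, not a fixture.

**Genotypes.**  Each sample is two independent haplotypes.  Ancestral
allele frequencies are uniform on a configurable MAF range (default
0.05–0.5).  With `n_subpops > 1`, subpopulation frequencies follow the
Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F), so `fst` controls
differentiation; samples are assigned to subpopulations by the mixing
weights.  LD is induced through a latent-Gaussian copula: within a block
the latent process is AR(1) with parameter `within_block_rho` (default
0.9), so correlation decays geometrically with distance — adjacent
variants are strongly correlated, variants ~10 steps apart are nearly
independent — and blocks are mutually independent.  We chose a decaying
process deliberately: an exchangeable (single-factor) block leaves *every*
retained pair of an LD-pruned panel sitting just under the pruning
threshold, a pathological spectrum that no real, distance-decaying LD
produces and that destabilizes eigenvalue-based structure tests.  Blocks
are laid out across 22 chromosomes with 1 kb spacing within a block and
2 Mb between blocks on the same chromosome, so physical windows behave
sensibly.  Dosages are 0/1/2 counts of the effect allele; missing entries
are NaN, never 0.

**Phenotypes.**  The primary trait (height, cm) is

```
height = 161.5 + sex_effect·male + age_slope·(age − mean age) + g + e
```

with `g` a weighted sum of standardized causal dosages (weights i.i.d.
Gaussian, then jointly rescaled) and `e` Gaussian noise.  `heritability`
is defined as the fraction of **total** phenotypic variance carried by
`g`: the generator fixes a height-like total-variance target of 100 cm²
(pooled-sex SD 10 cm), sets var(g) = h²·100 exactly in-sample, and scales
the noise to absorb the remainder after the realized sex/age contribution.
With the default sex gap of +12.7 cm (variance ≈ 40 cm²) the feasible h²
is therefore ≈ ≤ 0.55; beyond that the noise floor is clipped with a
logged warning.  Defaults: ages uniform on 30–80 years, `age_slope`
−0.05 cm/yr, sexes ~1:1.

**Secondary phenotype.**  Diastolic blood pressure shares a fraction
`secondary_rho` (default 0.3) of the *standardized* genetic value, plus
sex, BMI and antihypertensive-medication effects (medication Bernoulli
with rate 0.35 in males, 0.12 in females) and noise with SD 10.5 mmHg.
Systolic pressure carries no genetic share, mirroring the asymmetry the
pipeline's secondary-association stage is meant to detect.  Weight/BMI
are height-linked with an independent adiposity component.

**Degradation.**  `degrade` injects entry-wise missingness at a given
rate, draws per-variant imputation INFO scores uniform on a range
(cohort default 0.85–1.0, i.e. roughly a third of variants fail the 0.9
INFO filter — imputed panels concentrate near 1), and can force a chosen
fraction of samples below 90% call rate (15% of their genotypes masked)
to give sample QC something real to remove.  Phenotypes are always
simulated from the clean genotypes; degradation affects only what the
pipeline observes.

**What passing tests do not show.**  The generator has no recombination
maps, no allele-frequency/effect-size coupling, no non-additive effects,
no imputation dosage uncertainty beyond the scalar INFO, and its LD is
block-diagonal.  Results on it demonstrate that the pipeline's machinery
is correct and calibrated under its stated model, not that any particular
R² will be achieved on a real cohort.

## Quality control

Variants are removed if INFO, call rate or MAF is *strictly below*
threshold (defaults 0.9 / 0.95 / 0.05), applied in the order INFO → call
rate → MAF with sequential removal counts; samples with call rate
strictly below 0.90 are removed afterwards, so sample call rates are
computed over surviving variants.  MAF uses non-missing dosages only and
is folded to ≤ 0.5; monomorphic variants fall to the MAF rule.  Variants
lacking an INFO value are treated as directly genotyped (INFO = 1) with a
logged warning.  LD pruning is a greedy per-chromosome left-to-right
scan: a variant is dropped if its r² with any already-kept variant within
the physical window (default 250 kb) exceeds the threshold (default 0.2);
the retained panel provably contains no within-window pair above the
threshold.  Pruning parameters are conventional pre-PCA settings and
configurable.

## PCA and Tracy–Widom selection

Missing dosages are mean-imputed (PCA cannot consume missingness and the
imputation is deterministic), each variant is centred at 2p̂ and scaled by
√(2p̂(1−p̂)), and the sample covariance of the scaled matrix is
eigen-decomposed via the smaller-side Gram matrix.  The number of
components reflecting real structure is chosen by sequentially testing
leading eigenvalues against the Tracy–Widom β=1 law: the remaining
spectrum is renormalized to mean 1, an effective marker count is
estimated from its first two moments, the top eigenvalue is centred and
scaled with the standard Wishart-edge formulas, and testing stops at the
first non-significant eigenvalue (cap 20, α = 0.05 by default).

Two numerical choices matter:

* **TW1 quantiles** are computed at runtime as a Fredholm determinant of
  the kernel Ai((x+y)/2)/2 on (s, ∞) with 80-point Gauss–Legendre
  quadrature, and inverted with Brent's method (cached per level).  This
  matches published critical values (0.9793 / 2.0234 / 3.2724 at
  95/99/99.9%) to four decimals and avoids bundling a quantile table.
* **Effective marker count.**  The classical moment estimator
  n′ = (m′+1)S₁²/((m′−1)S₂ − S₁²) is biased by a factor ≈ (1 − n′/m′²)⁻¹,
  which in moderate dimensions (say 100 samples × 1,000 markers) shifts
  the TW statistic by more than two of its SDs and inflates the
  false-selection rate several-fold.  We use the exact-Wishart-moment
  version n′ = m′(m′²−3)/(D+m′) with D = (m′−1)S₂ − S₁² on mean-1
  eigenvalues, which restores the nominal level (empirically 0.01–0.05 at
  α = 0.05 across the sizes the tests run).

## Association scan

One OLS engine serves every scan: trait ~ dosage + sex + age + selected
PCs, fitted per variant on the samples with a non-missing dosage
(per-variant sample dropping, not imputation, so standard errors are
honest), p-values from the t distribution with residual degrees of
freedom.  Complete variants go through a vectorized residualization;
variants with missing entries are fitted exactly via cross-product
downdates of the full-data normal equations (verified against per-variant
`statsmodels` fits to ~1e-12).  Monomorphic variants are excluded and
counted.  A `backend` label exists for bookkeeping because cohort studies
often run several association tools; all additive linear-model backends
fit the same model, so one engine represents them.

Whether per-iteration scans recompute PCs on each source split or reuse
whole-cohort PCs is configurable; recomputation is the default.  The LD
*prune list* for PCA, by contrast, is computed once on the whole cohort
and reused across iterations: it is a deterministic LD thinning whose
subset-level changes are negligible, and recomputing it dominated
runtime (a `reprune_each_iteration` switch restores the literal
behaviour).

## C+T engine

Clumping is greedy: repeatedly take the smallest-p unclaimed variant as
index (ties by position, then id, for determinism) and claim unclaimed
variants within the window (default 250 kb) with r² above the threshold
(default 0.1) in the target genotypes.  Variants absent from the LD
reference form their own clump, logged.  Thresholding scans a fixed
p-value grid (5e-8 … 1.0); because thresholds are nested, scores are
built incrementally by cumulative sums.  The incremental R² of adding a
score to the covariates is computed in closed form from residualized
cross-products, which also makes the permutation null cheap: phenotype
permutations are re-residualized in blocks and the best-over-grid gain is
compared with the observed one.  Scores are reported raw and min–max
scaled to [0,1] (a constant score maps to 0.5).  Strand-ambiguous (A/T,
C/G) variants are kept by default — the simulator is strand-consistent —
and can be dropped for real data.  Ties in the threshold scan go to the
smaller threshold.

The average-per-observed-allele normalization with mean-dosage imputation
of missing genotypes is the default because it is the cited scoring
tool's default behaviour; a printed per-cohort sample-size factor in the
source formula has no place in a per-individual score and is treated as
normalization bookkeeping.

## Stability ensemble

Each iteration draws a fresh 80/20 partition *without replacement*
(`floor(0.8·N)` source samples) — the scheme is iterated subsampling, not
a with-replacement bootstrap, though the resulting empirical p-value is
conventionally called a bootstrap p.  Per-iteration seeds derive from the
master seed via `numpy` `SeedSequence.spawn`, so runs are reproducible
end to end.  Iteration failures are recorded and skipped; the run aborts
if more than 10% fail.

Aggregation counts each variant once per iteration in which it entered
the best model.  Every distinct appearance cut-off at or above the floor
(default 10, the published absolute rule) defines a candidate; because
cut-offs are scanned in increasing order the candidate SNP sets are
nested.  A candidate's incremental-R² distribution re-scores its fixed
SNP set on each iteration's target samples with that iteration's source
effects (variants missing from an iteration's scan are dropped for that
iteration) — the only reading that yields a per-candidate distribution
comparable with the per-iteration baseline.  Narrowing keeps candidates
at strict local maxima of the mean-R² sequence (endpoints compare with
their single neighbour).  The bootstrap p-value of a candidate is the
fraction of iterations whose baseline R² exceeds the candidate's mean.
The final candidate is the narrowed candidate with the highest mean
incremental R², and its weights are re-assigned from a whole-cohort
association scan with the same covariate structure.

**Known limitation: in-cohort optimism.**  The candidate evaluation is
not leakage-free: every other iteration's 80% source set overlaps a given
iteration's 20% target, so variants selected *recurrently* carry
chance-correlation information about every target subset.  Under a
null (h² = 0) cohort, candidates assembled at low appearance cut-offs can
therefore beat the per-iteration baseline, and a bootstrap p of 0 should
not be read as a calibrated significance statement.  The absolute
appearance floor of 10 is the effective guard: under the null, few
variants recur that often, and the pipeline then (correctly) reports that
no candidate reaches the floor rather than emitting an overfit score —
the null-calibration test counts that refusal as the controlled outcome.
A fully calibrated assessment requires samples held out of the *entire*
ensemble, which is exactly what the hold-out validation stage provides;
trust it, not the in-ensemble bootstrap p, for generalization claims.

## Validation and secondary association

Hold-out validation repeats: draw a random fraction (default 5%, 100
repeats), score it with the fixed model, compute PCs *on the held-out
samples*, and fit trait ~ covariates and trait ~ PRS + covariates;
reported are the full-model R², the incremental R² and the Pearson r,
each as mean ± SD over repeats.  Descriptive statistics stratify by sex:
continuous variables get mean ± SD and a pooled-variance t-test (Welch
optional; the pooled form is the common default for reported tables),
binary variables get proportions and a chi-square test.  The secondary
association fits OLS of the outcome on the [0,1]-scaled PRS with two
covariate sets (age+sex+BMI; plus medication flag) and reports the
unadjusted Pearson correlation alongside.  Permutation-derived "p = 0"
values are reported as bounds (< 1/n_permutations), never literal zero.
SNP-set overlap with external scores is an exact id intersection (with
deduplication warnings); a chrom:pos fallback is available through the
composite-id convention in the IO layer.

## Problem sizes used by the test suite

The suite exercises the full pipeline at sizes chosen to make the
statistical assertions sharp while remaining desk-scale: null
calibration on 20 cohorts of 500 samples × 2,000 variants with 10
iterations; parameter recovery on 10 cohorts of 2,000 × 5,000 with 200
causal variants and 25 iterations; Tracy–Widom calibration on 200
unstructured cohorts of 300 × 1,000.  With fewer iterations than the
published 100, the appearance floor is either kept at the absolute 10
(acceptance runs) or scaled proportionally in small demos; permutation
counts are set to 0 where the empirical p is not under test.  The
acceptance script runs one seed of the 2,000 × 5,000 condition.

## Defaults at a glance

| parameter | default | unit / meaning |
|---|---|---|
| INFO / variant call rate / MAF / sample call rate | 0.9 / 0.95 / 0.05 / 0.90 | strict-below removal |
| prune window / step / r² | 250 kb / 25 / 0.2 | pre-PCA thinning |
| TW α / max PCs | 0.05 / 20 | component selection |
| clump window / r² | 250 kb / 0.1 | C+T |
| p-grid | 5e-8 … 1.0 (12 values) | C+T thresholds |
| permutations | 10,000 | empirical p |
| iterations / split / floor | 100 / 80:20 / 10 | ensemble |
| holdout fraction / repeats | 0.05 / 100 | validation |
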