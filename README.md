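# stabprs

Stability-selection polygenic risk scores for quantitative traits.

`stabprs` builds a cohort-specific polygenic risk score (PRS) for a
quantitative trait — the motivating application is adult height — by
repeating a clumping+thresholding (C+T) derivation over many random 80/20
source/target splits of one cohort and keeping only variants that are
selected *stably* across iterations.  It is aimed at groups working with
small or mid-sized cohorts (a few thousand samples) where a single C+T fit
is notoriously sensitive to which samples happen to land in the training
split.

## The method

For individual *j* a PRS is the weighted allele count

```
PRS_j = Σ_i  β_i · G_ij / (2 · m_j)
```

where `G_ij ∈ {0,1,2}` counts effect alleles, `β_i` is the per-allele GWAS
effect and `m_j` is the number of scored variants observed for *j*
(average-per-allele normalization; a plain weighted sum is available).

One pipeline iteration is the classic C+T recipe:

1. **QC** — drop variants with imputation INFO < 0.9, call rate < 95% or
   MAF < 5%, and samples with call rate < 90%;
2. **structure** — LD-prune, run PCA on the pruned panel and keep the
   leading components whose eigenvalues are significant under the
   Tracy–Widom (β=1) law with an effective-marker correction;
3. **association** — per-variant OLS of trait on dosage with sex, age and
   the selected PCs as covariates, on the 80% source split;
4. **C+T** — greedy LD clumping by p-value, then a scan over p-value
   inclusion thresholds; the threshold whose score maximizes the
   *incremental R²* (R² with the PRS minus R² without it) on the 20%
   target split wins, with an optional permutation p-value against
   threshold-scan overfitting.

The ensemble repeats this (default 100×), records each iteration's best
incremental R² (the *baseline* distribution), and counts how often each
variant appears in a best model.  Every distinct appearance cut-off ≥ 10
defines a candidate PRS; candidates are re-scored on each iteration's
target with that iteration's source effects, local maxima of the mean-R²
sequence are retained, and each gets an empirical **bootstrap p-value**:
the fraction of iterations whose baseline R² beats the candidate's mean.
Final weights come from a whole-cohort association scan, and the final
score is validated by repeated random hold-outs and associated with a
secondary phenotype (blood pressure) if present.

Because individual-level cohort data of this kind cannot be redistributed,
the package ships a generator for synthetic cohorts with known causal
architecture — Balding–Nichols population structure, AR(1) latent-copula
LD blocks, additive effects with sex/age covariates, missingness and
per-variant INFO scores — so every stage is testable end to end.

## Worked example

```python
import stabprs as sp
from stabprs.qc import apply_qc

cohort = sp.simulate_cohort(
    n_samples=600,
    ld=sp.LDBlockSpec(n_blocks=30, block_size=20),
    arch=sp.TraitArchitecture(n_causal=60, heritability=0.5),
    missing_rate=0.01,
    seed=7,
)
g, vrep, srep = apply_qc(cohort.genotypes)
config = sp.EnsembleConfig(n_iterations=20, min_freq_floor=4,
                           ct=sp.CTParams(n_permutations=0))
result = sp.stability_pipeline(g, cohort.phenotypes, config, seed=7)
val = sp.holdout_validate(result.final_model, g, cohort.phenotypes,
                          fraction=0.2, repeats=10, seed=8)
```

prints (via the obvious `print` calls):

```
post-QC: 600 samples x 388 variants (removed {'info': 210, 'call_rate': 0, 'maf': 2})
baseline incremental R2: 0.2086 +- 0.0423
  candidate f>= 4:  43 SNPs, mean R2 0.2684 +- 0.0514, bootstrap p 0.05
  candidate f>= 5:  29 SNPs, mean R2 0.2552 +- 0.0525, bootstrap p 0.10
  candidate f>= 6:  22 SNPs, mean R2 0.2758 +- 0.0518, bootstrap p 0.05
final PRS: 22 SNPs (appearing >= 6/20 iterations), bootstrap p = 0.05
holdout (20%, 10 repeats): full-model R2 0.727 +- 0.030, incremental R2 0.290, PRS-trait r 0.541
causal SNPs in final model: 13/22 (base rate 0.111)
```

Reading this: the 22-SNP candidate at appearance cut-off 6 is a local
maximum of mean incremental R² (0.276) and beats the per-iteration
baseline in 19 of 20 iterations (bootstrap p = 0.05).  On 20% hold-outs
the finalized score adds 0.29 to the covariate-only R² — close to the
simulated heritability of 0.5 times the share it can capture from 22 of
60 causal variants plus their LD partners — and 59% of its SNPs are truly
causal versus an 11% base rate.

A `stabprs` command-line tool wraps the same stages
(`simulate`, `qc`, `pca`, `gwas`, `clump`, `prs-score`, `descriptives`,
`overlap`, `full-run`); `stabprs full-run --config cfg.yaml --outdir run/`
executes the whole pipeline from a YAML config and writes every artifact
with a SHA-256 manifest.

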