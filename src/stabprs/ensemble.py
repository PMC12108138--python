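"""Iterative bootstrap ensemble for PRS stability selection.

The cohort is repeatedly (default 100 times) partitioned into a source
(80%) and a target (20%) set; per iteration the source yields summary
statistics (with per-iteration variant QC and freshly computed principal
components as covariates) and the target yields that iteration's best
clumping+thresholding PRS and its incremental R-squared.  The 100
per-iteration incremental R2 values form the baseline distribution.

Variants are then aggregated by how often they appear in the
per-iteration best models; every distinct frequency cut-off at or above a
floor (default 10 of 100) defines a candidate PRS whose incremental R2 is
re-evaluated on each iteration's target set using that iteration's source
effects, giving each candidate a mean and SD.  Candidates at local maxima
of the mean-R2 sequence are kept, and each receives an empirical
bootstrap p-value: the fraction of iterations whose baseline R2 exceeds
the candidate's mean.  Final weights come from whole-cohort summary
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import SummaryStats, covariate_matrix, gwas_scan
from .containers import GenotypeMatrix, ParameterError, PhenotypeTable
from .pca import genotype_pca
from .prs import CTParams, PRSModel, _incremental_r2_columns, derive_best_prs
from .qc import PruneParams, QCThresholds, filter_variants, ld_prune

log = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    n_iterations: int = 100
    train_fraction: float = 0.8
    min_freq_floor: int = 10
    qc: QCThresholds = field(default_factory=QCThresholds)
    prune: PruneParams = field(default_factory=PruneParams)
    ct: CTParams = field(default_factory=CTParams)
    alpha: float = 0.05
    max_pcs: int = 20
    per_iteration_qc: bool = True
    reprune_each_iteration: bool = False
    trait: str = "height_cm"
    max_failure_fraction: float = 0.1

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.min_freq_floor < 1:
            raise ParameterError("min_freq_floor must be >= 1")
        self.qc.validate()
        self.prune.validate()
        self.ct.validate()


@dataclass
class IterationRecord:
    """Everything one iteration contributes to the aggregation stage."""

    index: int
    source_ids: np.ndarray = field(repr=False)
    target_ids: np.ndarray = field(repr=False)
    model: PRSModel = field(repr=False, default=None)
    incremental_r2: float = np.nan
    prs_p: float = np.nan
    empirical_p: float = np.nan
    betas: pd.Series = field(repr=False, default=None)  # variant id -> source-set beta
    target_covars: np.ndarray = field(repr=False, default=None)
    failed: bool = False
    error: str = ""


@dataclass
class CandidatePRS:
    """Frequency-thresholded SNP set with its per-iteration R2 distribution."""

    min_freq: int
    snp_ids: np.ndarray = field(repr=False)
    r2_values: np.ndarray = field(repr=False)
    bootstrap_p: float = np.nan

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_values)) if len(self.r2_values) else np.nan

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2_values, ddof=1)) if len(self.r2_values) > 1 else np.nan


def _iteration_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_ensemble(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    config: EnsembleConfig | None = None,
    seed: int = 0,
    pruned: list[str] | None = None,
) -> tuple[list[IterationRecord], np.ndarray]:
    """Run the source/target iteration scheme on a QC-passed cohort.

    Returns the iteration records (failed ones flagged) and the baseline
    distribution of per-iteration incremental R2 values.  The run aborts
    if more than ``max_failure_fraction`` of iterations fail.
    """
    config = config or EnsembleConfig()
    config.validate()
    n = g.n_samples
    n_src = int(np.floor(config.train_fraction * n))
    if n_src < 3 or n - n_src < 3:
        raise ParameterError("cohort too small for the requested split")

    # LD thinning for PCA is computed once on the whole cohort: the pruned
    # panel is a deterministic LD skeleton and subset LD barely moves it.
    whole_prune = pruned
    if whole_prune is None and not config.reprune_each_iteration:
        whole_prune = ld_prune(g, config.prune)

    seeds = _iteration_seeds(seed, config.n_iterations)
    records: list[IterationRecord] = []
    for i in range(config.n_iterations):
        rng = np.random.default_rng(seeds[i])
        derive_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        perm = rng.permutation(n)
        src_idx, tgt_idx = perm[:n_src], perm[n_src:]
        rec = IterationRecord(index=i, source_ids=g.samples[src_idx], target_ids=g.samples[tgt_idx])
        try:
            _run_iteration(rec, g, ph, src_idx, tgt_idx, config, whole_prune, derive_seed)
        except Exception as exc:  # noqa: BLE001 - iteration failures are data
            rec.failed = True
            rec.error = str(exc)
            log.warning("iteration %d failed: %s", i, exc)
        records.append(rec)

    n_failed = sum(r.failed for r in records)
    if n_failed > config.max_failure_fraction * config.n_iterations:
        raise RuntimeError(f"{n_failed}/{config.n_iterations} iterations failed; aborting")
    baseline = np.array([r.incremental_r2 for r in records if not r.failed])
    return records, baseline


def _run_iteration(rec, g, ph, src_idx, tgt_idx, config, whole_prune, derive_seed) -> None:
    src_g = g.subset(samples=src_idx)
    if config.per_iteration_qc:
        src_g, _ = filter_variants(src_g, config.qc)
    kept_ids = src_g.variant_ids

    if config.reprune_each_iteration:
        pruned = ld_prune(src_g, config.prune)
    else:
        kept = set(kept_ids)
        pruned = [v for v in whole_prune if v in kept]
    if not pruned:
        raise ParameterError("no pruned variants available for PCA")

    src_basis = genotype_pca(src_g, pruned, alpha=config.alpha, max_pcs=config.max_pcs)
    ss = gwas_scan(src_g, ph, pcs=src_basis, trait=config.trait)

    tgt_g = g.subset(samples=tgt_idx).subset_by_variant_id(kept_ids)
    tgt_basis = genotype_pca(tgt_g, pruned, alpha=config.alpha, max_pcs=config.max_pcs)
    covars, _ = covariate_matrix(ph, tgt_basis, sample_ids=tgt_g.samples)

    model, fit = derive_best_prs(
        ss, tgt_g, ph, covars, params=config.ct, seed=derive_seed, trait=config.trait
    )
    rec.model = model
    rec.incremental_r2 = fit.attrs["best_incremental_r2"]
    rec.prs_p = fit.attrs["prs_p"]
    rec.empirical_p = fit.attrs["empirical_p"]
    rec.betas = ss.table["beta"]
    rec.target_covars = covars


def aggregate(records: list[IterationRecord]) -> pd.Series:
    """Appearance count of each variant across per-iteration best models."""
    ok = [r for r in records if not r.failed]
    if not ok:
        raise ParameterError("no successful iterations to aggregate")
    counts: dict[str, int] = {}
    for r in ok:
        for v in set(r.model.variant_ids):
            counts[v] = counts.get(v, 0) + 1
    s = pd.Series(counts, dtype=int)
    s = s.iloc[np.lexsort((s.index.to_numpy(), -s.to_numpy()))]  # count desc, id asc
    s.index.name = "variant_id"
    s.name = "count"
    return s


def build_candidates(
    freq: pd.Series,
    records: list[IterationRecord],
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    min_freq_floor: int = 10,
    trait: str = "height_cm",
) -> list[CandidatePRS]:
    """One candidate per distinct frequency cut-off >= the floor.

    Each candidate's SNP set (all variants appearing at least ``cut-off``
    times) is re-scored on every iteration's target samples using that
    iteration's source-set effects, yielding a per-iteration incremental
    R2 distribution.  Cut-offs are ascending, so candidate SNP sets are
    nested (higher cut-off implies a subset).
    """
    if min_freq_floor < 1:
        raise ParameterError("min_freq_floor must be >= 1")
    ok = [r for r in records if not r.failed]
    if not ok:
        raise ParameterError("no successful iterations")
    eligible = freq[freq >= min_freq_floor]
    if eligible.empty:
        return []
    cutoffs = sorted(eligible.unique())

    # order union by count descending (ties by id) so every cut-off is a prefix
    union = eligible.sort_values(ascending=False, kind="mergesort")
    union = union.iloc[np.lexsort((union.index.to_numpy(), -union.to_numpy()))]
    union_ids = union.index.to_numpy()
    union_counts = union.to_numpy()
    # number of SNPs at each cut-off
    k_at = {f: int(np.searchsorted(-union_counts, -f, side="right")) for f in cutoffs}

    col_of = {v: j for j, v in enumerate(g.variant_ids)}
    cols = np.array([col_of[v] for v in union_ids], dtype=int)

    r2_rows = []
    for r in ok:
        tgt = g.subset_by_sample_id(r.target_ids).subset(variants=cols)
        w = r.betas.reindex(union_ids)
        have = ~w.isna().to_numpy()
        wv = np.where(have, w.to_numpy(float), 0.0)
        d = tgt.mean_imputed()
        obs = (~np.isnan(tgt.dosage)) & have[None, :]
        wsum = np.cumsum(d * wv, axis=1)
        osum = np.cumsum(obs, axis=1)
        y = ph.aligned_to(r.target_ids)[trait].to_numpy(float)
        scores = np.empty((len(y), len(cutoffs)))
        for c, f in enumerate(cutoffs):
            k = k_at[f]
            num = wsum[:, k - 1]
            ob = osum[:, k - 1]
            denom = 2.0 * np.where(ob > 0, ob, max(k, 1))
            scores[:, c] = num / denom
        r2_rows.append(_incremental_r2_columns(scores, y, r.target_covars))
    r2_mat = np.array(r2_rows)  # iterations x cutoffs

    out = []
    for c, f in enumerate(cutoffs):
        k = k_at[f]
        if k == 0:
            continue
        out.append(CandidatePRS(min_freq=int(f), snp_ids=union_ids[:k].copy(), r2_values=r2_mat[:, c]))
    return out


def narrow_down(candidates: list[CandidatePRS]) -> list[CandidatePRS]:
    """Keep candidates at strict local maxima of mean R2 over the
    frequency-ordered sequence (endpoints compare with their one neighbour)."""
    if not candidates:
        raise ParameterError("narrow_down requires at least one candidate")
    if len(candidates) == 1:
        return list(candidates)
    means = np.array([c.mean_r2 for c in candidates])
    keep = []
    for i, c in enumerate(candidates):
        left = means[i] > means[i - 1] if i > 0 else True
        right = means[i] > means[i + 1] if i < len(means) - 1 else True
        if left and right:
            keep.append(c)
    return keep


def bootstrap_p(candidate: CandidatePRS, baseline: np.ndarray) -> float:
    """Fraction of iterations whose baseline R2 exceeds the candidate mean."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise ParameterError("baseline distribution is empty")
    if len(candidate.r2_values) == 0:
        raise ParameterError("candidate has no per-iteration R2 values")
    return float(np.mean(baseline > candidate.mean_r2))


def finalize(candidate: CandidatePRS, whole_cohort_ss: SummaryStats) -> PRSModel:
    """Assign whole-cohort effects to the candidate's SNP set."""
    tab = whole_cohort_ss.table
    present = [v for v in candidate.snp_ids if v in tab.index]
    n_missing = len(candidate.snp_ids) - len(present)
    if not present:
        raise ParameterError("no candidate SNP is present in the whole-cohort summary statistics")
    if n_missing:
        log.warning("%d candidate SNPs missing from whole-cohort summary statistics; dropped", n_missing)
    sel = tab.loc[present]
    return PRSModel(
        entries=pd.DataFrame(
            {
                "chrom": sel["chromosome"],
                "pos": sel["base_pair_location"],
                "effect_allele": sel["effect_allele"],
                "weight": sel["beta"],
                "p_source": sel["p_value"],
            },
            index=sel.index,
        ),
        p_threshold=1.0,
        source=f"freq>={candidate.min_freq}",
    )


@dataclass
class PipelineResult:
    records: list[IterationRecord] = field(repr=False)
    baseline: np.ndarray = field(repr=False)
    frequency: pd.Series = field(repr=False)
    candidates: list[CandidatePRS] = field(repr=False)
    narrowed: list[CandidatePRS] = field(repr=False)
    final_candidate: CandidatePRS = None
    final_model: PRSModel = None
    whole_cohort_ss: SummaryStats = field(repr=False, default=None)


def stability_pipeline(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Ensemble, aggregation, narrowing and finalization in one call.

    ``g`` should already have passed cohort-level QC.  The final candidate
    is the narrowed candidate with the highest mean incremental R2.
    """
    config = config or EnsembleConfig()
    pruned = None if config.reprune_each_iteration else ld_prune(g, config.prune)
    records, baseline = run_ensemble(g, ph, config, seed=seed, pruned=pruned)
    freq = aggregate(records)
    candidates = build_candidates(
        freq, records, g, ph, min_freq_floor=config.min_freq_floor, trait=config.trait
    )
    if not candidates:
        raise ParameterError("no candidate reaches the minimum appearance frequency")
    narrowed = narrow_down(candidates)
    for c in candidates:
        c.bootstrap_p = bootstrap_p(c, baseline)

    if pruned is None:
        pruned = ld_prune(g, config.prune)
    basis = genotype_pca(g, pruned, alpha=config.alpha, max_pcs=config.max_pcs)
    whole_ss = gwas_scan(g, ph, pcs=basis, trait=config.trait)
    final_candidate = max(narrowed, key=lambda c: c.mean_r2)
    final_model = finalize(final_candidate, whole_ss)
    return PipelineResult(
        records=records,
        baseline=baseline,
        frequency=freq,
        candidates=candidates,
        narrowed=narrowed,
        final_candidate=final_candidate,
        final_model=final_model,
        whole_cohort_ss=whole_ss,
    )
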