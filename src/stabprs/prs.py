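"""Clumping + thresholding PRS derivation, scoring and permutation p-values.

A score is a weighted sum of effect-allele dosages, PRS = sum_i beta_i G_i,
reported per individual as the average per observed allele: the weighted
sum divided by twice the number of model variants with an observed
genotype for that individual.  Missing dosages contribute the variant's
expected dosage 2*p_hat (frequency taken from the scored cohort).  A plain
weighted-sum normalization is available via ``normalization="sum"``.

Derivation is the classic two-step: greedy LD clumping keeps the most
significant variant of each correlated group, then a grid of p-value
inclusion thresholds is scanned and the threshold whose score adds the
most incremental R-squared over the covariates on the target samples wins.
Overfitting of the threshold scan is measured with an empirical p-value:
the fraction of phenotype permutations whose best-over-grid incremental
R-squared reaches the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ParameterError, PhenotypeTable

log = logging.getLogger(__name__)

DEFAULT_P_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class CTParams:
    clump_window_kb: float = 250.0
    clump_r2: float = 0.1
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    n_permutations: int = 10_000

    def validate(self) -> None:
        if self.clump_window_kb <= 0:
            raise ParameterError("clump_window_kb must be > 0")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ParameterError("clump_r2 must be in [0, 1]")
        grid = tuple(self.p_grid)
        if not grid or any(not (0.0 < t <= 1.0) for t in grid):
            raise ParameterError("p_grid thresholds must be in (0, 1]")
        if list(grid) != sorted(grid):
            raise ParameterError("p_grid must be sorted ascending")
        if self.n_permutations < 0:
            raise ParameterError("n_permutations must be >= 0")


@dataclass
class PRSModel:
    """A weighted variant list defining a score.

    ``entries`` is indexed by variant id with columns chrom, pos,
    effect_allele, weight, p_source.
    """

    entries: pd.DataFrame = field(repr=False)
    p_threshold: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.entries.index.has_duplicates:
            raise ParameterError("PRS model variant ids must be unique")

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.entries.index.to_numpy()

    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(float)


@dataclass
class PRSProfile:
    """Per-sample scores: raw, min-max scaled to [0, 1], alleles observed."""

    table: pd.DataFrame = field(repr=False)  # index sample_id: raw_score, scaled_score, n_alleles_observed

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw_score"].to_numpy(float)

    @property
    def scaled(self) -> np.ndarray:
        return self.table["scaled_score"].to_numpy(float)


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        return (raw - lo) / (hi - lo)
    return np.full_like(raw, 0.5)


def clump(ss, ld_ref: GenotypeMatrix, params: CTParams | None = None) -> list[str]:
    """Greedy p-value-ordered clumping against an LD reference panel.

    Repeatedly takes the smallest-p unclaimed variant as an index and
    claims every unclaimed variant within ``clump_window_kb`` whose squared
    correlation with it exceeds ``clump_r2``; returns the index variants.
    Ties in p break by position then id.  Variants absent from the
    reference are kept as their own clump (logged).
    """
    params = params or CTParams()
    params.validate()
    table = ss.table

    ref_ids = {v: i for i, v in enumerate(ld_ref.variant_ids)}
    present = table.index.isin(ref_ids.keys())
    absent_ids = list(table.index[~present])
    if absent_ids:
        log.warning("%d variants absent from the LD reference form their own clumps", len(absent_ids))

    tab = table[present]
    order = np.lexsort(
        (tab.index.to_numpy(), tab["base_pair_location"].to_numpy(), tab["p_value"].to_numpy())
    )
    ids = tab.index.to_numpy()[order]
    chrom = tab["chromosome"].to_numpy()[order]
    pos = tab["base_pair_location"].to_numpy(float)[order]
    col = np.array([ref_ids[v] for v in ids], dtype=int)

    x = ld_ref.mean_imputed()[:, col]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    n = x.shape[0]
    window = params.clump_window_kb * 1000.0

    claimed = np.zeros(len(ids), dtype=bool)
    index_variants: list[str] = []
    for i in range(len(ids)):
        if claimed[i]:
            continue
        claimed[i] = True
        index_variants.append(ids[i])
        near = ~claimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        cand = np.flatnonzero(near)
        if cand.size:
            r = x[:, cand].T @ x[:, i] / n
            claimed[cand[r * r > params.clump_r2]] = True
    return index_variants + absent_ids


def _match_dosage(
    model: PRSModel, g: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray, int]:
    """Dosage matrix aligned to the model's effect alleles.

    Returns (n x m_matched dosage with NaN for missing, matched positions
    into the model, count of unmatchable entries).  Swapped-allele variants
    are flipped to the model's effect allele.
    """
    ref = {v: i for i, v in enumerate(g.variant_ids)}
    cols, rows, flip = [], [], []
    n_unmatched = 0
    gv = g.variants
    for k, vid in enumerate(model.variant_ids):
        j = ref.get(vid)
        if j is None:
            n_unmatched += 1
            continue
        ea, oa = gv.at[j, "effect_allele"], gv.at[j, "other_allele"]
        mea = model.entries.iloc[k]["effect_allele"]
        if mea == ea:
            flip.append(False)
        elif mea == oa:
            flip.append(True)
        else:
            n_unmatched += 1
            continue
        cols.append(j)
        rows.append(k)
    if n_unmatched:
        log.warning("%d model variants unmatchable in the scored cohort", n_unmatched)
    if model.n_snps and n_unmatched > 0.5 * model.n_snps:
        raise ParameterError(">50% of model variants unmatchable in the scored cohort")
    d = g.dosage[:, cols].copy()
    flip_arr = np.array(flip, dtype=bool)
    d[:, flip_arr] = 2.0 - d[:, flip_arr]
    return d, np.array(rows, dtype=int), n_unmatched


def score(
    model: PRSModel,
    g: GenotypeMatrix,
    normalization: str = "avg",
) -> PRSProfile:
    """Score every sample in ``g`` with ``model``.

    ``normalization="avg"`` divides each sample's weighted sum by twice its
    count of observed model variants (average per observed allele);
    ``"sum"`` is the plain weighted sum.
    """
    if normalization not in ("avg", "sum"):
        raise ParameterError("normalization must be 'avg' or 'sum'")
    d, rows, _ = _match_dosage(model, g)
    w = model.weights()[rows]
    obs = (~np.isnan(d)).sum(axis=1)
    if d.shape[1]:
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan = np.isnan(d)
        d[nan] = np.broadcast_to(col_mean, d.shape)[nan]
        raw = d @ w
    else:
        raw = np.zeros(g.n_samples)
    if normalization == "avg":
        denom = 2.0 * np.where(obs > 0, obs, max(d.shape[1], 1))
        raw = raw / denom
    return PRSProfile(
        pd.DataFrame(
            {
                "raw_score": raw,
                "scaled_score": _minmax(raw),
                "n_alleles_observed": 2 * obs,
            },
            index=pd.Index(g.samples, name="sample_id"),
        )
    )


def _incremental_r2_columns(scores: np.ndarray, y: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Incremental R2 of adding each score column to the covariate model."""
    q, _ = np.linalg.qr(covars)
    y_r = y - q @ (q.T @ y)
    tss = y - y.mean()
    tss = tss @ tss
    s_r = scores - q @ (q.T @ scores)
    sxx = np.einsum("ij,ij->j", s_r, s_r)
    sxy = s_r.T @ y_r
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(sxx > 0, sxy**2 / sxx, 0.0)
    return gain / tss


def derive_best_prs(
    ss,
    target_g: GenotypeMatrix,
    target_ph: PhenotypeTable,
    covars: np.ndarray,
    params: CTParams | None = None,
    seed: int = 0,
    trait: str = "height_cm",
) -> tuple[PRSModel, pd.DataFrame]:
    """Derive the best clumping+thresholding PRS on a target set.

    After clumping, each p-value threshold of the grid defines a candidate
    score built from the clumped variants with p <= threshold; the
    candidate maximizing incremental R-squared over the covariates wins
    (ties to the smaller threshold).  The returned fit record (one row per
    threshold) carries n_snps and incremental R2, with the best row's
    empirical permutation p-value and the t-test p of the PRS term attached
    as DataFrame attrs ``empirical_p`` / ``prs_p`` / ``best_threshold``.
    """
    params = params or CTParams()
    params.validate()
    clumped = clump(ss, target_g, params)
    tab = ss.table.loc[[v for v in clumped if v in ss.table.index]]
    tab = tab.sort_values("p_value", kind="mergesort")

    loosest = params.p_grid[-1]
    if not (tab["p_value"] <= loosest).any():
        raise ParameterError("no variant passes the loosest p-value threshold")

    y = target_ph.aligned_to(target_g.samples)[trait].to_numpy(float)

    # matched dosages for all clumped variants at once, mean-imputed
    full_model = PRSModel(
        entries=pd.DataFrame(
            {
                "chrom": tab["chromosome"],
                "pos": tab["base_pair_location"],
                "effect_allele": tab["effect_allele"],
                "weight": tab["beta"],
                "p_source": tab["p_value"],
            },
            index=tab.index,
        ),
        p_threshold=loosest,
    )
    d, rows, _ = _match_dosage(full_model, target_g)
    w = full_model.weights()[rows]
    pv = tab["p_value"].to_numpy()[rows]
    obs_mask = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan = np.isnan(d)
    d[nan] = np.broadcast_to(col_mean, d.shape)[nan]

    # nested thresholds: variants sorted by p, so each threshold is a prefix
    counts = np.searchsorted(pv, np.array(params.p_grid), side="right")
    usable = counts > 0
    if not usable.any():
        raise ParameterError("no variant passes the loosest p-value threshold")

    n = d.shape[0]
    scores = np.zeros((n, int(usable.sum())))
    thresholds = [t for t, u in zip(params.p_grid, usable) if u]
    kcounts = counts[usable]
    wsum = np.cumsum(d * w, axis=1)
    osum = np.cumsum(obs_mask, axis=1)
    for col, k in enumerate(kcounts):
        num = wsum[:, k - 1]
        ob = osum[:, k - 1]
        denom = 2.0 * np.where(ob > 0, ob, k)
        scores[:, col] = num / denom

    r2 = _incremental_r2_columns(scores, y, covars)
    best_col = int(np.argmax(r2))  # argmax takes the first (smallest threshold) on ties
    best_t = thresholds[best_col]
    best_k = int(kcounts[best_col])

    # empirical p: permute the trait, keep covariates and scores fixed
    if params.n_permutations > 0:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(covars)
        s_r = scores - q @ (q.T @ scores)
        sxx = np.einsum("ij,ij->j", s_r, s_r)
        sxx[sxx == 0] = np.inf
        perm_best = np.empty(params.n_permutations)
        y_c = y - y.mean()
        tss = y_c @ y_c
        block = 256
        perms = np.empty((n, block))
        done = 0
        while done < params.n_permutations:
            b = min(block, params.n_permutations - done)
            for j in range(b):
                perms[:, j] = y[rng.permutation(n)]
            yp = perms[:, :b]
            yp_r = yp - q @ (q.T @ yp)
            sxy = s_r.T @ yp_r  # thresholds x perms
            gain = (sxy**2 / sxx[:, None]) / tss
            perm_best[done : done + b] = gain.max(axis=0)
            done += b
        empirical_p = float(np.mean(perm_best >= r2[best_col]))
    else:
        empirical_p = np.nan

    # significance of the PRS term at the best threshold
    prs_p = _prs_term_p(scores[:, best_col], y, covars)

    sel_ids = tab.index.to_numpy()[rows[:best_k]]
    sel = tab.loc[sel_ids]
    model = PRSModel(
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
        p_threshold=best_t,
        source=ss.backend,
    )
    record = pd.DataFrame(
        {"p_threshold": thresholds, "n_snps": kcounts, "incremental_r2": r2}
    )
    record.attrs["best_threshold"] = best_t
    record.attrs["best_incremental_r2"] = float(r2[best_col])
    record.attrs["empirical_p"] = empirical_p
    record.attrs["prs_p"] = prs_p
    return model, record


def _prs_term_p(s: np.ndarray, y: np.ndarray, covars: np.ndarray) -> float:
    from scipy import stats as sps

    design = np.column_stack([s, covars])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = len(y) - rank
    if df <= 0:
        return np.nan
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.pinv(design.T @ design)[0, 0])
    if se == 0:
        return 0.0
    return float(2.0 * sps.t.sf(abs(coef[0] / se), df))
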