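"""Hold-out validation, descriptive statistics, secondary-trait association
and SNP-set overlap for a finalized PRS."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import covariate_matrix
from .containers import GenotypeMatrix, ParameterError, PhenotypeTable
from .pca import genotype_pca
from .prs import PRSModel, PRSProfile, score
from .qc import PruneParams, ld_prune

log = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Aggregated hold-out regression metrics over repeats.

    ``full_r2`` is the R2 of trait ~ PRS + sex + age + PCs on the held-out
    samples; ``incremental_r2`` subtracts the covariate-only R2; ``r`` is
    the Pearson correlation between the raw score and the trait.
    """

    holdout_fraction: float
    repeats: int
    full_r2_mean: float
    full_r2_sd: float
    incremental_r2_mean: float
    incremental_r2_sd: float
    r_mean: float
    r_sd: float
    per_repeat: pd.DataFrame = field(repr=False, default=None)


def _fit_r2(y: np.ndarray, design: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = y - y.mean()
    tss = tss @ tss
    return float(1.0 - resid @ resid / tss) if tss > 0 else 0.0


def holdout_validate(
    model: PRSModel,
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    fraction: float = 0.05,
    repeats: int = 100,
    seed: int = 0,
    trait: str = "height_cm",
    prune: PruneParams | None = None,
    alpha: float = 0.05,
    max_pcs: int = 20,
) -> ValidationResult:
    """Repeatedly hold out a random sample fraction and regress on it.

    Per repeat the held-out samples are scored with the fixed model and two
    regressions are fitted on them (with and without the PRS term); PCs are
    computed on the held-out samples themselves.  The model must have been
    finalized without these labels.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must be in (0, 1)")
    n = g.n_samples
    n_hold = int(round(fraction * n))
    pruned = ld_prune(g, prune or PruneParams())
    # a rough covariate count: intercept + sex + age + PCs + PRS
    if n_hold < max_pcs + 5:
        max_pcs = max(n_hold - 6, 0)
    if n_hold < 8:
        raise ParameterError("holdout too small for the covariate count")

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        idx = rng.choice(n, size=n_hold, replace=False)
        sub_g = g.subset(samples=idx)
        basis = genotype_pca(sub_g, pruned, alpha=alpha, max_pcs=max_pcs)
        covars, _ = covariate_matrix(ph, basis, sample_ids=sub_g.samples)
        prof = score(model, sub_g)
        y = ph.aligned_to(sub_g.samples)[trait].to_numpy(float)
        r2_red = _fit_r2(y, covars)
        r2_full = _fit_r2(y, np.column_stack([prof.raw, covars]))
        if prof.raw.std() > 0 and y.std() > 0:
            r = float(np.corrcoef(prof.raw, y)[0, 1])
        else:
            r = 0.0
        rows.append({"full_r2": r2_full, "incremental_r2": r2_full - r2_red, "r": r})
    per = pd.DataFrame(rows)
    return ValidationResult(
        holdout_fraction=fraction,
        repeats=repeats,
        full_r2_mean=float(per["full_r2"].mean()),
        full_r2_sd=float(per["full_r2"].std(ddof=1)) if repeats > 1 else np.nan,
        incremental_r2_mean=float(per["incremental_r2"].mean()),
        incremental_r2_sd=float(per["incremental_r2"].std(ddof=1)) if repeats > 1 else np.nan,
        r_mean=float(per["r"].mean()),
        r_sd=float(per["r"].std(ddof=1)) if repeats > 1 else np.nan,
        per_repeat=per,
    )


def mean_gap(mean_group1: float, mean_group2: float) -> float:
    """Group difference as mean(group2) - mean(group1) (the table convention)."""
    return mean_group2 - mean_group1


def descriptives(
    ph: PhenotypeTable,
    group: str = "sex",
    variables: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Sex-stratified descriptives with two-sample tests.

    Continuous variables get mean +- SD per group, the group-2-minus-group-1
    difference and a pooled-variance t-test (Welch via ``equal_var=False``);
    binary 0/1 variables get proportions and a chi-square test.
    """
    df = ph.data
    if group not in df.columns:
        raise ParameterError(f"grouping column '{group}' absent")
    levels = sorted(df[group].dropna().unique())
    if len(levels) != 2:
        raise ParameterError(f"grouping column '{group}' must have exactly 2 levels")
    g1 = df[df[group] == levels[0]]
    g2 = df[df[group] == levels[1]]
    if variables is None:
        variables = [c for c in df.columns if c != group and pd.api.types.is_numeric_dtype(df[c])]

    rows = []
    for var in variables:
        a, b = g1[var].dropna(), g2[var].dropna()
        if len(a) < 2 or len(b) < 2:
            log.warning("variable '%s' skipped: a group has <2 observations", var)
            continue
        vals = pd.concat([a, b]).unique()
        binary = set(np.unique(vals)).issubset({0, 1, 0.0, 1.0})
        if binary:
            tab = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]])
            if tab[:, 0].sum() in (0, tab.sum()):
                stat, p = np.nan, 1.0
            else:
                stat, p, _, _ = sps.chi2_contingency(tab)
            rows.append(
                {
                    "variable": var,
                    "type": "binary",
                    f"prop_{levels[0]}": float(a.mean()),
                    f"prop_{levels[1]}": float(b.mean()),
                    "difference": float(b.mean() - a.mean()),
                    "statistic": float(stat),
                    "p": float(p),
                }
            )
        else:
            t, p = sps.ttest_ind(b, a, equal_var=equal_var)
            rows.append(
                {
                    "variable": var,
                    "type": "continuous",
                    f"mean_{levels[0]}": float(a.mean()),
                    f"sd_{levels[0]}": float(a.std(ddof=1)),
                    f"mean_{levels[1]}": float(b.mean()),
                    f"sd_{levels[1]}": float(b.std(ddof=1)),
                    "difference": mean_gap(float(a.mean()), float(b.mean())),
                    "statistic": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def secondary_association(
    profile: PRSProfile,
    ph: PhenotypeTable,
    outcome: str = "dbp",
    covariate_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Association of the scaled PRS with a secondary phenotype.

    Fits OLS ``outcome ~ scaled PRS + covariates`` for each named covariate
    set (defaults mirror blood-pressure modelling: model1 = age+sex+bmi,
    model2 adds the antihypertensive-medication flag) and reports the PRS
    beta, SE and p, plus the unadjusted Pearson correlation as row
    ``pearson``.
    """
    import statsmodels.api as sm

    if covariate_sets is None:
        covariate_sets = {
            "model1": ["age_years", "sex", "bmi"],
            "model2": ["age_years", "sex", "bmi", "antihtn"],
        }
    df = ph.data.join(profile.table[["scaled_score"]], how="inner")
    df = df.dropna(subset=[outcome, "scaled_score"])
    if df.empty or df[outcome].nunique() <= 1:
        raise ParameterError(f"outcome '{outcome}' is constant or absent")

    rows = []
    r, rp = sps.pearsonr(df["scaled_score"], df[outcome])
    rows.append({"model": "pearson", "beta": float(r), "se": np.nan, "p": float(rp), "n": len(df)})
    for name, covs in covariate_sets.items():
        sub = df.dropna(subset=covs)
        x = sm.add_constant(sub[["scaled_score", *covs]].astype(float))
        fit = sm.OLS(sub[outcome].astype(float), x).fit()
        rows.append(
            {
                "model": name,
                "beta": float(fit.params["scaled_score"]),
                "se": float(fit.bse["scaled_score"]),
                "p": float(fit.pvalues["scaled_score"]),
                "n": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows)


def overlap(model_a: PRSModel, external_variant_ids) -> dict:
    """Exact SNP-set intersection between a model and an external list."""
    a = pd.Index(model_a.variant_ids)
    if a.has_duplicates:
        log.warning("duplicate ids in model deduplicated for overlap")
        a = a.drop_duplicates()
    b = pd.Index(external_variant_ids)
    if b.has_duplicates:
        log.warning("duplicate ids in external list deduplicated for overlap")
        b = b.drop_duplicates()
    inter = a.intersection(b)
    return {
        "n_model": len(a),
        "n_external": len(b),
        "n_intersection": len(inter),
        "fraction_of_model": len(inter) / len(a) if len(a) else 0.0,
        "fraction_of_external": len(inter) / len(b) if len(b) else 0.0,
    }
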