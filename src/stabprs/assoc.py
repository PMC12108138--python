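"""Per-variant association scan: OLS of trait on dosage plus covariates.

One ordinary-least-squares engine serves every scan.  For each variant the
model is ``trait ~ dosage + sex + age + PC1..PCk`` fitted on the samples
with a non-missing dosage (per-variant sample dropping, not imputation, so
standard errors stay honest); p-values come from the t distribution with
the residual degrees of freedom.  Variants that are monomorphic within the
analysed subset are excluded and counted.

The scan is vectorized: covariates are projected out once via a QR
decomposition and per-variant slopes follow from the residualized cross
products; variants with missing dosages fall back to an exact per-variant
fit on their complete samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeMatrix, ParameterError, PhenotypeTable
from .pca import PCABasis

log = logging.getLogger(__name__)


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics plus provenance.

    ``table`` is indexed by variant id with columns chromosome,
    base_pair_location, effect_allele, other_allele, beta, standard_error,
    p_value, n.
    """

    table: pd.DataFrame = field(repr=False)
    covariates: list[str] = field(default_factory=list)
    subset_id: str = ""
    backend: str = "ols"
    n_monomorphic: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def beta(self) -> pd.Series:
        return self.table["beta"]

    def pvalues(self) -> pd.Series:
        return self.table["p_value"]


def covariate_matrix(
    ph: PhenotypeTable,
    pcs: PCABasis | np.ndarray | None = None,
    sample_ids=None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, sex, age, PC1..PCk] aligned to ``sample_ids``.

    When ``pcs`` is a :class:`PCABasis` its loadings must already be aligned
    with ``sample_ids`` (PCA computed on exactly those samples).
    """
    sub = ph.data if sample_ids is None else ph.data.loc[list(sample_ids)]
    cols = [np.ones(len(sub)), sub["sex"].to_numpy(float), sub["age_years"].to_numpy(float)]
    names = ["intercept", "sex", "age"]
    if pcs is not None:
        load = pcs.pcs() if isinstance(pcs, PCABasis) else np.asarray(pcs)
        if load.size:
            if load.shape[0] != len(sub):
                raise ParameterError("PC loadings are not aligned with the sample subset")
            for k in range(load.shape[1]):
                cols.append(load[:, k])
                names.append(f"PC{k + 1}")
    c = np.column_stack(cols)
    if np.linalg.matrix_rank(c) < c.shape[1]:
        bad = _collinear_columns(c, names)
        raise ParameterError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    return c, names


def _collinear_columns(c: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(c)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [names[i] for i in np.flatnonzero(diag < tol)]


def gwas_scan(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    pcs: PCABasis | np.ndarray | None = None,
    sample_subset=None,
    trait: str = "height_cm",
    backend: str = "ols",
) -> SummaryStats:
    """Scan every variant for association with ``trait``.

    ``sample_subset`` (sample ids) restricts the analysis; ``pcs`` loadings
    must be aligned with that subset.  Samples with incomplete covariates
    are dropped with a log message.
    """
    if sample_subset is not None:
        g = g.subset_by_sample_id(sample_subset)
    ids = g.samples
    sub = ph.data.loc[list(ids)]
    complete = ~sub[[trait, "sex", "age_years"]].isna().any(axis=1).to_numpy()
    if not complete.all():
        log.info("dropping %d samples with incomplete trait/covariates", (~complete).sum())
        g = g.subset(samples=complete)
        sub = sub.loc[complete]
    if g.n_samples == 0:
        raise ParameterError("sample subset is empty")

    c, cov_names = covariate_matrix(PhenotypeTable(sub.copy()), pcs=_subset_pcs(pcs, complete))
    y = sub[trait].to_numpy(float)
    n, k = c.shape

    q, _ = np.linalg.qr(c)
    y_r = y - q @ (q.T @ y)
    tss = y_r @ y_r

    x = g.dosage
    has_missing = np.isnan(x).any(axis=0)
    beta = np.full(g.n_variants, np.nan)
    se = np.full(g.n_variants, np.nan)
    pval = np.full(g.n_variants, np.nan)
    n_used = np.full(g.n_variants, 0, dtype=int)
    mono = np.zeros(g.n_variants, dtype=bool)

    comp = ~has_missing
    if comp.any():
        xc = x[:, comp]
        var0 = xc.std(axis=0) == 0
        x_r = xc - q @ (q.T @ xc)
        sxx = np.einsum("ij,ij->j", x_r, x_r)
        sxy = x_r.T @ y_r
        with np.errstate(invalid="ignore", divide="ignore"):
            b = sxy / sxx
            rss = np.maximum(tss - b * sxy, 0.0)
            df = n - k - 1
            s = np.sqrt(rss / df / sxx)
            t = b / s
        p = 2.0 * sps.t.sf(np.abs(t), df)
        idx = np.flatnonzero(comp)
        beta[idx], se[idx], pval[idx], n_used[idx] = b, s, p, n
        mono[idx[var0]] = True

    miss_idx = np.flatnonzero(has_missing)
    if miss_idx.size:
        # Exact per-variant OLS on complete rows via cross-product downdates:
        # zero-filling x makes every x-involving product an ok-row sum, and
        # the covariate blocks are corrected by that variant's missing rows.
        xm = x[:, miss_idx]
        nanm = np.isnan(xm)
        x0 = np.where(nanm, 0.0, xm)
        ctc = c.T @ c
        cty = c.T @ y
        yty = y @ y
        xtc = x0.T @ c
        xty = x0.T @ y
        xtx = np.einsum("ij,ij->j", x0, x0)
        xsum = x0.sum(axis=0)
        t_stat = np.full(miss_idx.size, np.nan)
        dfs = np.full(miss_idx.size, 1.0)
        for jj in range(miss_idx.size):
            rows_m = np.flatnonzero(nanm[:, jj])
            n_ok = n - rows_m.size
            if n_ok < k + 2:
                continue
            mean_ok = xsum[jj] / n_ok
            if xtx[jj] - n_ok * mean_ok**2 <= 1e-12:
                mono[miss_idx[jj]] = True
                continue
            cm = c[rows_m]
            ym = y[rows_m]
            a = np.empty((k + 1, k + 1))
            a[0, 0] = xtx[jj]
            a[0, 1:] = a[1:, 0] = xtc[jj]
            a[1:, 1:] = ctc - cm.T @ cm
            rhs = np.empty(k + 1)
            rhs[0] = xty[jj]
            rhs[1:] = cty - cm.T @ ym
            try:
                ainv = np.linalg.inv(a)
            except np.linalg.LinAlgError:
                continue
            sol = ainv @ rhs
            rss = max((yty - ym @ ym) - sol @ rhs, 0.0)
            df = n_ok - (k + 1)
            s2 = rss / df
            j = miss_idx[jj]
            beta[j] = sol[0]
            se[j] = np.sqrt(s2 * ainv[0, 0])
            n_used[j] = n_ok
            dfs[jj] = df
            if se[j] > 0:
                t_stat[jj] = sol[0] / se[j]
            else:
                pval[j] = 0.0
        ok_t = ~np.isnan(t_stat)
        pv = 2.0 * sps.t.sf(np.abs(t_stat[ok_t]), dfs[ok_t])
        pval[miss_idx[ok_t]] = pv

    keep = ~mono & ~np.isnan(beta)
    if mono.any():
        log.info("excluded %d monomorphic variants from the scan", int(mono.sum()))
    v = g.variants
    table = pd.DataFrame(
        {
            "chromosome": v["chrom"].to_numpy()[keep],
            "base_pair_location": v["pos"].to_numpy()[keep],
            "effect_allele": v["effect_allele"].to_numpy()[keep],
            "other_allele": v["other_allele"].to_numpy()[keep],
            "beta": beta[keep],
            "standard_error": se[keep],
            "p_value": np.clip(pval[keep], np.finfo(float).tiny, 1.0),
            "n": n_used[keep],
        },
        index=pd.Index(v["id"].to_numpy()[keep], name="variant_id"),
    )
    return SummaryStats(
        table=table,
        covariates=cov_names,
        subset_id="" if sample_subset is None else f"subset[{len(ids)}]",
        backend=backend,
        n_monomorphic=int(mono.sum()),
    )


def _subset_pcs(pcs, complete_mask: np.ndarray):
    if pcs is None or complete_mask.all():
        return pcs
    load = pcs.pcs() if isinstance(pcs, PCABasis) else np.asarray(pcs)
    return load[complete_mask]
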