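"""In-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "info"]

#: Phenotype/covariate columns expected by the pipeline.
PHENOTYPE_COLUMNS = [
    "sample_id",
    "height_cm",
    "sex",
    "age_years",
    "weight_kg",
    "bmi",
    "sbp",
    "dbp",
    "antihtn",
]


class ParameterError(ValueError):
    """An invalid parameter value, naming the offending field."""


class QCError(RuntimeError):
    """A quality-control step left nothing to analyse."""


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix.

    Dosages count copies of the effect allele (0/1/2, PLINK convention);
    missing genotypes are ``NaN``, never 0.  ``variants`` carries per-variant
    metadata (id, chrom, 1-based pos, effect/other allele, imputation INFO
    score); ``samples`` is an array of sample identifiers aligned with rows.
    """

    dosage: np.ndarray
    samples: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        self.samples = np.asarray(self.samples)
        if self.dosage.ndim != 2:
            raise ParameterError("dosage must be a 2-D samples x variants array")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ParameterError("samples length does not match dosage rows")
        if len(self.variants) != m:
            raise ParameterError("variants table length does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ParameterError(f"variants table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def variant_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency (folded to <= 0.5)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Dosage with missing entries replaced by the variant mean."""
        x = self.dosage.copy()
        nan = np.isnan(x)
        if nan.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            x[nan] = np.broadcast_to(col_mean, x.shape)[nan]
        return x

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index arrays."""
        s_idx = np.arange(self.n_samples) if samples is None else _as_index(samples, self.n_samples)
        v_idx = np.arange(self.n_variants) if variants is None else _as_index(variants, self.n_variants)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(s_idx, v_idx)],
            samples=self.samples[s_idx],
            variants=self.variants.iloc[v_idx].reset_index(drop=True),
        )

    def subset_by_sample_id(self, sample_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return self.subset(samples=idx)

    def subset_by_variant_id(self, variant_ids) -> "GenotypeMatrix":
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([lookup[v] for v in variant_ids], dtype=int)
        return self.subset(variants=idx)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), self.samples.copy(), self.variants.copy())


def _as_index(sel, n: int) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ParameterError("boolean selector has wrong length")
        return np.flatnonzero(sel)
    return sel.astype(int)


@dataclass
class PhenotypeTable:
    """Per-sample trait and covariate table.

    Thin wrapper around a DataFrame indexed by ``sample_id`` with the
    columns in :data:`PHENOTYPE_COLUMNS`; ``sex`` is 0 = female, 1 = male,
    ``antihtn`` is a 0/1 antihypertensive-medication flag.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        self.data = df

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    def aligned_to(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(sample_ids)].copy())
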