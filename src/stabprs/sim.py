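"""Synthetic cohort generator with a known additive genetic architecture.

Genotypes are simulated as two independent haplotypes per sample.  Allele
frequencies follow the Balding–Nichols model: each subpopulation draws its
variant frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
frequency p, so Fst controls differentiation.  Linkage disequilibrium is
induced by a latent-Gaussian copula: within an LD block the latent process
is AR(1) with parameter rho, so correlation decays as rho^distance —
adjacent variants are strongly correlated, distant ones nearly independent
— while blocks are mutually independent, mimicking real LD decay.

Phenotypes are additive: a configurable number of causal variants receive
i.i.d. Gaussian effects which are jointly rescaled so that the genetic
value explains exactly the requested fraction h2 of the covariate-adjusted
phenotypic variance (genetic + environmental noise).  Sex and age act as
fixed covariate effects on top.  A secondary blood-pressure phenotype
shares a configurable fraction of the genetic value, emulating a trait
genetically correlated with the primary one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix, ParameterError, PhenotypeTable

log = logging.getLogger(__name__)

# Target total phenotypic variance of the primary trait (height, cm^2):
# pooled-sex adult height SD ~10 cm once the sex gap is included.
_TOTAL_VAR_CM2 = 100.0
_FEMALE_MEAN_CM = 161.5
_DBP_SD = 10.5


@dataclass
class LDBlockSpec:
    """Layout of independent LD blocks of exchangeably correlated variants."""

    n_blocks: int = 40
    block_size: int = 50
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ParameterError("n_blocks must be >= 1")
        if self.block_size < 1:
            raise ParameterError("block_size must be >= 1")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ParameterError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class StructureSpec:
    """Population-structure settings (Balding–Nichols subpopulations)."""

    n_subpops: int = 1
    fst: float = 0.0
    mixing_weights: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_subpops < 1:
            raise ParameterError("n_subpops must be >= 1")
        if self.fst < 0:
            raise ParameterError("fst must be >= 0")
        if self.mixing_weights is not None:
            if len(self.mixing_weights) != self.n_subpops:
                raise ParameterError("mixing_weights length must equal n_subpops")
            if abs(sum(self.mixing_weights) - 1.0) > 1e-12:
                raise ParameterError("mixing_weights must sum to 1")

    def weights(self) -> np.ndarray:
        if self.mixing_weights is None:
            return np.full(self.n_subpops, 1.0 / self.n_subpops)
        return np.asarray(self.mixing_weights, dtype=float)


@dataclass
class TraitArchitecture:
    """Additive architecture of the primary trait.

    ``heritability`` is the fraction of *total* phenotypic variance carried
    by the genetic value; the environmental noise is scaled so the total
    variance meets a fixed height-like target, so sex/age covariate effects
    count against the non-genetic share.  ``sex_effect`` is the
    male-minus-female offset in trait units (default +12.7 cm, a typical
    adult-height sex gap); ``age_slope`` is trait units per year of age.
    With the default covariate effects the feasible ``heritability`` is
    roughly <= 0.55; beyond that the noise floor is clipped (logged).
    """

    n_causal: int = 200
    heritability: float = 0.5
    sex_effect: float = 12.7
    age_slope: float = -0.05
    effect_distribution: str = "gaussian"
    age_range: tuple[float, float] = (30.0, 80.0)

    def validate(self) -> None:
        if self.n_causal < 0:
            raise ParameterError("n_causal must be >= 0")
        if not (0.0 <= self.heritability <= 1.0):
            raise ParameterError("heritability must be in [0, 1]")
        if self.effect_distribution != "gaussian":
            raise ParameterError("effect_distribution: only 'gaussian' is supported")
        if self.age_range[0] > self.age_range[1]:
            raise ParameterError("age_range must be (low, high)")


@dataclass
class SimulatedCohort:
    """A simulated cohort with its generative ground truth attached."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    causal_index: pd.DataFrame = field(repr=False)  # columns: id, beta
    true_genetic_value: np.ndarray = field(repr=False)
    noise: np.ndarray = field(repr=False)

    @property
    def causal_ids(self) -> np.ndarray:
        return self.causal_index["id"].to_numpy()

    def realized_h2(self) -> float:
        """var(genetic value) / var(trait) actually realized in the sample."""
        trait = self.phenotypes["height_cm"].to_numpy(float)
        if np.var(trait) == 0:
            return 0.0
        return float(np.var(self.true_genetic_value) / np.var(trait))


_BASES = np.array(["A", "C", "G", "T"])


def _variant_table(ld: LDBlockSpec, info: np.ndarray | None, rng: np.random.Generator) -> pd.DataFrame:
    m = ld.n_variants
    block = np.repeat(np.arange(ld.n_blocks), ld.block_size)
    within = np.tile(np.arange(ld.block_size), ld.n_blocks)
    chrom = (block % 22) + 1
    # blocks on the same chromosome are spaced 2 Mb apart; 1 kb spacing inside
    block_on_chrom = block // 22
    pos = 1_000_000 + block_on_chrom * 2_000_000 + within * 1_000
    a_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    effect = _BASES[a_idx]
    other = _BASES[(a_idx + shift) % 4]
    return pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos.astype(int),
            "effect_allele": effect,
            "other_allele": other,
            "info": np.ones(m) if info is None else info,
        }
    )


def simulate_genotypes(
    n_samples: int,
    ld: LDBlockSpec | None = None,
    structure: StructureSpec | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate 0/1/2 effect-allele dosages with LD blocks and structure.

    Returns a complete (no missing) genotype matrix; use :func:`degrade`
    to add missingness and imputation INFO scores.  The subpopulation label
    of each sample is attached as a ``subpop`` attribute on the returned
    matrix (ground truth for structure checks).
    """
    ld = ld or LDBlockSpec()
    structure = structure or StructureSpec()
    ld.validate()
    structure.validate()
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")

    rng = np.random.default_rng(seed)
    m = ld.n_variants
    k = structure.n_subpops

    p_anc = rng.uniform(ld.maf_range[0], ld.maf_range[1], size=m)
    if k > 1 and structure.fst > 0:
        f = structure.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(k, m))
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
    else:
        p_sub = np.broadcast_to(p_anc, (k, m)).copy()

    subpop = rng.choice(k, size=n_samples, p=structure.weights())
    p_ind = p_sub[subpop, :]  # n x m per-individual allele frequency

    rho = ld.within_block_rho
    dosage = np.zeros((n_samples, m))
    b = ld.block_size
    # AR(1) latent within each block: z_j = rho z_{j-1} + sqrt(1-rho^2) e_j
    for _hap in range(2):
        eps = rng.standard_normal((n_samples, ld.n_blocks, b))
        z = np.empty_like(eps)
        z[:, :, 0] = eps[:, :, 0]
        for j in range(1, b):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1.0 - rho**2) * eps[:, :, j]
        u = norm.cdf(z.reshape(n_samples, m))
        dosage += (u < p_ind).astype(np.float64)

    g = GenotypeMatrix(dosage, _sample_ids(n_samples), _variant_table(ld, None, rng))
    g.subpop = subpop  # ground-truth labels, used by tests and structure checks
    return g


def _sample_ids(n: int) -> np.ndarray:
    return np.array([f"sample{i:05d}" for i in range(n)])


def simulate_phenotypes(
    g: GenotypeMatrix,
    arch: TraitArchitecture | None = None,
    secondary_rho: float = 0.3,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate the primary trait and covariates on top of genotypes.

    The trait is ``female mean + sex offset + age slope * (age - mean age)
    + genetic value + noise``.  The genetic value is built from
    standardized causal dosages and rescaled so its sample variance is
    exactly ``h2`` times the total-variance target; the noise absorbs the
    remainder after the realized covariate contribution, so
    var(genetic)/var(trait) lands on ``h2`` up to sampling error.  The
    secondary (diastolic blood pressure) phenotype shares fraction
    ``secondary_rho`` of the standardized genetic value, plus BMI and
    medication effects.
    """
    arch = arch or TraitArchitecture()
    arch.validate()
    if not (-1.0 <= secondary_rho <= 1.0):
        raise ParameterError("secondary_rho must be in [-1, 1]")
    if arch.n_causal > g.n_variants:
        raise ParameterError("n_causal exceeds the number of variants")

    rng = np.random.default_rng(seed)
    n = g.n_samples
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
    age = rng.uniform(arch.age_range[0], arch.age_range[1], size=n)

    causal_pos = np.sort(rng.choice(g.n_variants, size=arch.n_causal, replace=False))
    h2 = arch.heritability
    if arch.n_causal == 0 or h2 == 0.0:
        genetic = np.zeros(n)
        betas = np.zeros(len(causal_pos))
    else:
        x = g.mean_imputed()[:, causal_pos]
        sd = x.std(axis=0)
        keep = sd > 0
        xs = np.zeros_like(x)
        xs[:, keep] = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        raw_beta = rng.standard_normal(len(causal_pos))
        raw_beta[~keep] = 0.0
        genetic = xs @ raw_beta
        g_sd = genetic.std()
        if g_sd == 0:
            raise ParameterError("degenerate genetic value; increase n_causal or cohort size")
        scale = np.sqrt(h2 * _TOTAL_VAR_CM2) / g_sd
        genetic = genetic * scale
        betas = raw_beta * scale

    mean_age = np.mean(arch.age_range)
    cov_part = arch.sex_effect * sex + arch.age_slope * (age - mean_age)
    noise_var = _TOTAL_VAR_CM2 - np.var(cov_part) - h2 * _TOTAL_VAR_CM2
    if noise_var < 0:
        log.warning(
            "covariate effects plus h2=%.2f exceed the total-variance target; "
            "noise floor clipped to zero", h2
        )
        noise_var = 0.0
    noise = rng.standard_normal(n) * np.sqrt(noise_var)
    height = _FEMALE_MEAN_CM + cov_part + genetic + noise

    # anthropometrics: weight tracks height plus independent adiposity
    adiposity = rng.standard_normal(n)
    weight = -65.0 + 0.85 * height + 9.0 * adiposity + rng.standard_normal(n) * 4.0
    bmi = weight / (height / 100.0) ** 2

    # antihypertensive use: higher rate in males
    med_rate = np.where(sex == 1, 0.35, 0.12)
    antihtn = (rng.random(n) < med_rate).astype(int)

    g_std = genetic / genetic.std() if genetic.std() > 0 else np.zeros(n)
    shared = secondary_rho * g_std + np.sqrt(max(1 - secondary_rho**2, 0.0)) * rng.standard_normal(n)
    dbp = 76.0 + 4.0 * sex + 0.45 * (bmi - bmi.mean()) + 5.0 * antihtn + _DBP_SD * shared
    sbp = 124.0 + 7.0 * sex + 0.8 * (bmi - bmi.mean()) + 8.0 * antihtn + 15.0 * rng.standard_normal(n)

    ph = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": g.samples,
                "height_cm": height,
                "sex": sex.astype(int),
                "age_years": age,
                "weight_kg": weight,
                "bmi": bmi,
                "sbp": sbp,
                "dbp": dbp,
                "antihtn": antihtn,
            }
        )
    )
    causal = pd.DataFrame({"id": g.variant_ids[causal_pos], "beta": betas})
    return SimulatedCohort(g, ph, causal, genetic, noise)


def degrade(
    g: GenotypeMatrix,
    missing_rate: float = 0.0,
    info_dist: tuple[float, float] = (0.6, 1.0),
    bad_sample_fraction: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Inject missingness and per-variant INFO scores.

    ``bad_sample_fraction`` designates ``round(fraction * n)`` samples whose
    call rate is forced below 0.90 (15% of their genotypes are masked),
    emulating failed samples that sample QC must remove.  INFO scores are
    drawn uniform over ``info_dist``.  With ``missing_rate=0``,
    ``bad_sample_fraction=0`` and ``info_dist=(1, 1)`` the dosages and
    metadata are returned unchanged.
    """
    for name, v in [("missing_rate", missing_rate), ("bad_sample_fraction", bad_sample_fraction)]:
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1]")
    lo, hi = info_dist
    if not (0.0 <= lo <= hi <= 1.0):
        raise ParameterError("info_dist must satisfy 0 <= low <= high <= 1")

    rng = np.random.default_rng(seed)
    out = g.copy()
    n, m = out.dosage.shape
    if missing_rate > 0:
        out.dosage[rng.random((n, m)) < missing_rate] = np.nan
    n_bad = int(round(bad_sample_fraction * n))
    if n_bad > 0:
        bad = rng.choice(n, size=n_bad, replace=False)
        k = max(int(np.ceil(0.15 * m)), int(np.floor(0.10 * m)) + 1)
        for s in bad:
            cols = rng.choice(m, size=min(k, m), replace=False)
            out.dosage[s, cols] = np.nan
    if lo == hi:
        info = np.full(m, lo)
    else:
        info = rng.uniform(lo, hi, size=m)
    out.variants = out.variants.assign(info=info)
    return out


def simulate_cohort(
    n_samples: int = 1000,
    ld: LDBlockSpec | None = None,
    structure: StructureSpec | None = None,
    arch: TraitArchitecture | None = None,
    secondary_rho: float = 0.3,
    missing_rate: float = 0.01,
    info_dist: tuple[float, float] = (0.85, 1.0),
    bad_sample_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedCohort:
    """One-call cohort: genotypes, phenotypes, then QC-relevant degradation.

    Phenotypes are simulated from the clean genotypes (the true biology);
    degradation only affects what the pipeline observes.
    """
    g = simulate_genotypes(n_samples, ld=ld, structure=structure, seed=seed)
    cohort = simulate_phenotypes(g, arch=arch, secondary_rho=secondary_rho, seed=seed + 1)
    degraded = degrade(
        g,
        missing_rate=missing_rate,
        info_dist=info_dist,
        bad_sample_fraction=bad_sample_fraction,
        seed=seed + 2,
    )
    degraded.subpop = getattr(g, "subpop", None)
    return SimulatedCohort(
        degraded, cohort.phenotypes, cohort.causal_index, cohort.true_genetic_value, cohort.noise
    )
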