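"""Readers, writers, configuration and the end-to-end pipeline driver.

On-disk formats are all plain text: VCF (dosage in a ``DS`` FORMAT field,
imputation quality as an ``INFO=`` key), a dosage TSV (variants x samples
with a side-car variant metadata TSV), phenotype TSV, GWAS-SSF-style
summary-statistics TSV, PRS model TSV and score TSV.  Coordinates are
1-based (VCF convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, ParameterError, PhenotypeTable
from .ensemble import EnsembleConfig, stability_pipeline
from .evaluate import holdout_validate, secondary_association, descriptives
from .prs import CTParams, PRSModel, score
from .qc import PruneParams, QCThresholds, apply_qc
from .sim import LDBlockSpec, StructureSpec, TraitArchitecture, simulate_cohort

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages to a VCF with a DS FORMAT field and an INFO key."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.samples)) + "\n")
        v = g.variants
        for j in range(g.n_variants):
            dos = g.dosage[:, j]
            cells = [("." if np.isnan(d) else f"{d:g}") for d in dos]
            fh.write(
                f"{v.at[j, 'chrom']}\t{int(v.at[j, 'pos'])}\t{v.at[j, 'id']}\t"
                f"{v.at[j, 'other_allele']}\t{v.at[j, 'effect_allele']}\t.\t.\t"
                f"INFO={v.at[j, 'info']:g}\tDS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a dosage VCF (DS FORMAT field); the ALT allele is the effect allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ParameterError(f"record at {var.CHROM}:{var.POS} lacks a DS field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        ds = np.where((ds < -1) | (ds > 2.5), np.nan, ds)  # cyvcf2 missing sentinel
        rows.append(ds)
        info = var.INFO.get("INFO")
        meta.append(
            {
                "id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "effect_allele": var.ALT[0] if var.ALT else ".",
                "other_allele": var.REF,
                "info": float(info) if info is not None else np.nan,
            }
        )
    if not rows:
        raise ParameterError(f"no variant records in {path}")
    return GenotypeMatrix(np.array(rows).T, samples, pd.DataFrame(meta))


def write_dosage_tsv(g: GenotypeMatrix, dosage_path, variants_path) -> None:
    """Variants x samples dosage TSV plus a side-car variant metadata TSV."""
    mat = pd.DataFrame(g.dosage.T, index=g.variant_ids, columns=g.samples)
    mat.index.name = "variant_id"
    mat.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%g")
    g.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    mat = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values="NA")
    meta = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    if list(mat.index) != list(meta["id"]):
        meta = meta.set_index("id").loc[mat.index].reset_index().rename(columns={"index": "id"})
    return GenotypeMatrix(mat.to_numpy(float).T, np.array(mat.columns), meta)


def read_genotypes(path, fmt: str | None = None, variants_path=None) -> GenotypeMatrix:
    """Dispatch on format: ``vcf`` or ``dosage-tsv`` (side-car required)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage-tsv":
        if variants_path is None:
            variants_path = path.with_suffix(".variants.tsv")
        return read_dosage_tsv(path, variants_path)
    raise ParameterError(f"unknown genotype format '{fmt}'")


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(ph: PhenotypeTable, path) -> None:
    ph.data.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", na_values="NA"))


# ------------------------------------------------------------- other tables

def write_summary_stats(ss, path) -> None:
    ss.table.reset_index().to_csv(path, sep="\t", index=False)


def write_model(model: PRSModel, path) -> None:
    model.entries.reset_index().rename(columns={"index": "variant_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_model(path) -> PRSModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).set_index("variant_id")
    return PRSModel(entries=df)


def write_scores(profile, path) -> None:
    profile.table.reset_index().to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- config

@dataclass
class SimulateConfig:
    n_samples: int = 600
    ld: LDBlockSpec = field(default_factory=lambda: LDBlockSpec(n_blocks=40, block_size=50))
    structure: StructureSpec = field(default_factory=StructureSpec)
    arch: TraitArchitecture = field(default_factory=TraitArchitecture)
    secondary_rho: float = 0.3
    missing_rate: float = 0.01
    info_dist: tuple[float, float] = (0.85, 1.0)
    bad_sample_fraction: float = 0.0


@dataclass
class PipelineConfig:
    """Every threshold and path the pipeline needs; YAML round-trippable."""

    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    genotypes: str | None = None  # used when simulate is None
    phenotypes: str | None = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    holdout_fraction: float = 0.05
    holdout_repeats: int = 20
    secondary_outcome: str = "dbp"

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d)


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, d):
    if d is None:
        return None
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = {
            "simulate": SimulateConfig,
            "ld": LDBlockSpec,
            "structure": StructureSpec,
            "arch": TraitArchitecture,
            "ensemble": EnsembleConfig,
            "qc": QCThresholds,
            "prune": PruneParams,
            "ct": CTParams,
        }.get(f.name)
        if ftype is not None and isinstance(v, dict):
            v = _from_dict(ftype, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


# ----------------------------------------------------------------- full run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def full_run(config: PipelineConfig, outdir) -> pd.DataFrame:
    """Execute simulate (optional) -> QC -> ensemble -> finalize -> validate
    -> secondary association, writing every artifact plus a hash manifest.

    Returns the manifest (file, sha256) as a DataFrame; it is also written
    to ``manifest.tsv`` in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    if config.simulate is not None:
        sc = config.simulate
        cohort = simulate_cohort(
            n_samples=sc.n_samples,
            ld=sc.ld,
            structure=sc.structure,
            arch=sc.arch,
            secondary_rho=sc.secondary_rho,
            missing_rate=sc.missing_rate,
            info_dist=tuple(sc.info_dist),
            bad_sample_fraction=sc.bad_sample_fraction,
            seed=seed,
        )
        g, ph = cohort.genotypes, cohort.phenotypes
    else:
        if not config.genotypes or not config.phenotypes:
            raise ParameterError("genotypes and phenotypes paths required when simulate is off")
        g = read_genotypes(config.genotypes)
        ph = read_phenotypes(config.phenotypes)

    log.info("cohort: %d samples x %d variants (seed %d)", g.n_samples, g.n_variants, seed)
    g_qc, vrep, srep = apply_qc(g, config.ensemble.qc)
    qc_rows = [
        {"axis": r.axis, "rule": k, "removed": v}
        for r in (vrep, srep)
        for k, v in r.removed.items()
    ]
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)

    result = stability_pipeline(g_qc, ph, config.ensemble, seed=seed)

    iter_rows = [
        {
            "iteration": r.index,
            "failed": r.failed,
            "n_snps": 0 if r.failed else r.model.n_snps,
            "incremental_r2": r.incremental_r2,
            "prs_p": r.prs_p,
            "empirical_p": r.empirical_p,
        }
        for r in result.records
    ]
    pd.DataFrame(iter_rows).to_csv(outdir / "iterations.tsv", sep="\t", index=False)
    result.frequency.to_csv(outdir / "frequency.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "n_snp": c.n_snps,
                "mean_r2": c.mean_r2,
                "sd_r2": c.sd_r2,
                "frequency": c.min_freq,
                "bootstrap_p": c.bootstrap_p,
                "local_maximum": any(c is k for k in result.narrowed),
            }
            for c in result.candidates
        ]
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    write_model(result.final_model, outdir / "final_prs.tsv")
    write_summary_stats(result.whole_cohort_ss, outdir / "whole_cohort_summary_stats.tsv")

    profile = score(result.final_model, g_qc)
    write_scores(profile, outdir / "scores.tsv")
    descriptives(ph).to_csv(outdir / "descriptives.tsv", sep="\t", index=False)

    val = holdout_validate(
        result.final_model,
        g_qc,
        ph,
        fraction=config.holdout_fraction,
        repeats=config.holdout_repeats,
        seed=seed + 1,
        trait=config.ensemble.trait,
        prune=config.ensemble.prune,
        alpha=config.ensemble.alpha,
        max_pcs=config.ensemble.max_pcs,
    )
    sec = secondary_association(profile, ph, outcome=config.secondary_outcome)
    sec.to_csv(outdir / "secondary_association.tsv", sep="\t", index=False)

    summary = {
        "seed": seed,
        "n_samples_qc": g_qc.n_samples,
        "n_variants_qc": g_qc.n_variants,
        "final_n_snps": result.final_model.n_snps,
        "final_min_freq": result.final_candidate.min_freq,
        "final_mean_incremental_r2": result.final_candidate.mean_r2,
        "final_sd_incremental_r2": result.final_candidate.sd_r2,
        "final_bootstrap_p": result.final_candidate.bootstrap_p,
        "holdout_full_r2_mean": val.full_r2_mean,
        "holdout_incremental_r2_mean": val.incremental_r2_mean,
        "holdout_r_mean": val.r_mean,
        "secondary_beta_model2": float(sec.loc[sec["model"] == "model2", "beta"].iloc[0]),
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    save_config(config, outdir / "config.yaml")

    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.tsv" and p.is_file())
    manifest = pd.DataFrame({"file": [p.name for p in files], "sha256": [_sha256(p) for p in files]})
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
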