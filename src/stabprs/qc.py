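"""Variant/sample quality control and LD pruning.

Filter semantics: a variant is removed if its imputation INFO score, call
rate or minor-allele frequency is *strictly below* the threshold (defaults
INFO 0.9, call rate 0.95, MAF 0.05); a sample is removed if its call rate
is strictly below 0.90.  Filters are applied in the order INFO -> call
rate -> MAF, and variant filters precede sample filters, so sample call
rates are computed over the variants that survived.

LD pruning is a greedy left-to-right scan per chromosome: a variant is
dropped if it has squared correlation above ``r2_threshold`` with any
already-kept variant within ``window_kb``, leaving a panel with no
retained pair above the threshold inside a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, ParameterError, QCError

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_info: float = 0.9
    min_variant_callrate: float = 0.95
    min_maf: float = 0.05
    min_sample_callrate: float = 0.90

    def validate(self) -> None:
        for name in ("min_info", "min_variant_callrate", "min_maf", "min_sample_callrate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")


@dataclass
class PruneParams:
    window_kb: float = 250.0
    step: int = 25
    r2_threshold: float = 0.2

    def validate(self) -> None:
        if self.window_kb <= 0:
            raise ParameterError("window_kb must be > 0")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ParameterError("r2_threshold must be in (0, 1]")


@dataclass
class QCReport:
    """Bookkeeping for one QC pass; removal counts are sequential."""

    axis: str  # "variant" or "sample"
    n_in: int = 0
    n_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def record(self, rule: str, n_removed: int) -> None:
        self.removed[rule] = n_removed
        line = f"{self.axis} filter '{rule}': removed {n_removed}"
        self.log_lines.append(line)
        log.info(line)

    def reconciles(self) -> bool:
        return self.n_in - sum(self.removed.values()) == self.n_out


def filter_variants(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing INFO, call-rate or MAF thresholds (in that order)."""
    t = t or QCThresholds()
    t.validate()
    report = QCReport(axis="variant", n_in=g.n_variants)

    info = g.variants["info"].to_numpy(dtype=float)
    missing_info = np.isnan(info)
    if missing_info.any():
        log.warning("%d variants lack an INFO score; treated as directly genotyped (INFO=1.0)", missing_info.sum())
        info = np.where(missing_info, 1.0, info)
    keep = np.ones(g.n_variants, dtype=bool)

    fail = info < t.min_info
    report.record("info", int(fail.sum()))
    keep &= ~fail

    cr = g.variant_call_rate()
    fail = keep & (cr < t.min_variant_callrate)
    report.record("call_rate", int(fail.sum()))
    keep &= ~fail

    maf = g.maf()
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing variants are removable
    fail = keep & (maf < t.min_maf)
    report.record("maf", int(fail.sum()))
    keep &= ~fail

    if not keep.any():
        raise QCError("no variants survive QC")
    out = g.subset(variants=keep)
    report.n_out = out.n_variants
    return out, report


def filter_samples(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples with call rate strictly below the threshold."""
    t = t or QCThresholds()
    t.validate()
    if g.n_variants < 1:
        raise ParameterError("filter_samples requires at least one variant")
    report = QCReport(axis="sample", n_in=g.n_samples)
    cr = g.sample_call_rate()
    fail = cr < t.min_sample_callrate
    report.record("call_rate", int(fail.sum()))
    if fail.all():
        raise QCError("no samples survive QC")
    out = g.subset(samples=~fail)
    report.n_out = out.n_samples
    return out, report


def apply_qc(
    g: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport, QCReport]:
    """Variant filters then sample filters (the contract order)."""
    gv, vrep = filter_variants(g, t)
    gs, srep = filter_samples(gv, t)
    return gs, vrep, srep


def _standardized(g: GenotypeMatrix) -> np.ndarray:
    x = g.mean_imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def ld_prune(g: GenotypeMatrix, p: PruneParams | None = None) -> list[str]:
    """Greedy LD pruning; returns the retained variant ids in genome order.

    Scans each chromosome left to right in position order; the window is a
    physical one (position difference <= ``window_kb`` kb).  ``step`` is
    kept for interface compatibility with sliding-window implementations;
    the scan here advances one variant at a time, which satisfies the same
    no-correlated-pair guarantee.
    """
    p = p or PruneParams()
    p.validate()
    pos = g.variants["pos"]
    if pos.isna().any():
        raise ParameterError("ld_prune requires a position for every variant")

    x = _standardized(g)
    n = g.n_samples
    window = p.window_kb * 1000.0
    kept_ids: list[str] = []

    for _, sub in g.variants.groupby("chrom", sort=False):
        order = sub.sort_values(["pos", "id"], kind="mergesort").index.to_numpy()
        kept_idx: list[int] = []
        kept_pos: list[float] = []
        for j in order:
            pj = g.variants.at[j, "pos"]
            lo = np.searchsorted(kept_pos, pj - window, side="left")
            cand = kept_idx[lo:]
            if cand:
                r = x[:, cand].T @ x[:, j] / n
                if np.any(r * r > p.r2_threshold):
                    continue
            kept_idx.append(j)
            kept_pos.append(pj)
        kept_ids.extend(g.variants.loc[kept_idx, "id"])
    # return in original variant-table order for determinism
    id_set = set(kept_ids)
    return [v for v in g.variant_ids if v in id_set]
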