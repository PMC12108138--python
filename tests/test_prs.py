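"""Clumping, scoring and best-threshold PRS derivation."""

import numpy as np
import pandas as pd
import pytest

from stabprs import (
    CTParams,
    ParameterError,
    PRSModel,
    clump,
    derive_best_prs,
    score,
)
from stabprs.assoc import SummaryStats

from conftest import make_genotypes, make_phenotypes


def _summary(ids, p, chrom=None, pos=None, beta=None, effect=None):
    m = len(ids)
    return SummaryStats(
        table=pd.DataFrame(
            {
                "chromosome": ["1"] * m if chrom is None else list(chrom),
                "base_pair_location": list(range(1000, 1000 + m)) if pos is None else list(pos),
                "effect_allele": ["A"] * m if effect is None else list(effect),
                "other_allele": ["G"] * m,
                "beta": np.ones(m) if beta is None else np.asarray(beta, float),
                "standard_error": np.ones(m),
                "p_value": np.asarray(p, float),
                "n": np.full(m, 100),
            },
            index=pd.Index(ids, name="variant_id"),
        )
    )


def brute_force_clump(ss, g, params):
    """Exhaustive reference clumping re-checking every removal decision."""
    tab = ss.table
    x = g.mean_imputed()
    x = (x - x.mean(0)) / np.where(x.std(0) == 0, 1.0, x.std(0))
    col = {v: j for j, v in enumerate(g.variant_ids)}
    remaining = set(tab.index)
    out = []
    while remaining:
        best = min(
            remaining,
            key=lambda v: (tab.at[v, "p_value"], tab.at[v, "base_pair_location"], v),
        )
        remaining.discard(best)
        out.append(best)
        for v in list(remaining):
            if tab.at[v, "chromosome"] != tab.at[best, "chromosome"]:
                continue
            if abs(tab.at[v, "base_pair_location"] - tab.at[best, "base_pair_location"]) > params.clump_window_kb * 1000:
                continue
            r = np.corrcoef(x[:, col[best]], x[:, col[v]])[0, 1]
            if r * r > params.clump_r2:
                remaining.discard(v)
    return out


def brute_force_score(model, g):
    """Direct double-loop scoring oracle (average per observed allele)."""
    out = np.zeros(g.n_samples)
    col = {v: j for j, v in enumerate(g.variant_ids)}
    p_hat = {}
    for vid in model.variant_ids:
        j = col[vid]
        d = g.dosage[:, j]
        flip = model.entries.at[vid, "effect_allele"] == g.variants.at[j, "other_allele"]
        d = 2 - d if flip else d
        p_hat[vid] = np.nanmean(d)
    for i in range(g.n_samples):
        num, obs = 0.0, 0
        for vid in model.variant_ids:
            j = col[vid]
            d = g.dosage[i, j]
            flip = model.entries.at[vid, "effect_allele"] == g.variants.at[j, "other_allele"]
            if not np.isnan(d):
                num += model.entries.at[vid, "weight"] * (2 - d if flip else d)
                obs += 1
            else:
                num += model.entries.at[vid, "weight"] * p_hat[vid]
        denom = 2 * obs if obs else 2 * model.n_snps
        out[i] = num / denom
    return out


def _model(ids, weights, effect=None, pos=None):
    m = len(ids)
    return PRSModel(
        entries=pd.DataFrame(
            {
                "chrom": ["1"] * m,
                "pos": list(range(1000, 1000 + m)) if pos is None else list(pos),
                "effect_allele": ["A"] * m if effect is None else list(effect),
                "weight": np.asarray(weights, float),
                "p_source": np.full(m, 0.5),
            },
            index=pd.Index(ids, name="variant_id"),
        )
    )


class TestClump:
    def test_correlated_pair_keeps_smaller_p(self):
        col = np.random.default_rng(0).integers(0, 3, 60).astype(float)
        g = make_genotypes(np.column_stack([col, col]), pos=[1000, 1500])
        ss = _summary(["v0", "v1"], p=[1e-4, 1e-8], pos=[1000, 1500])
        assert clump(ss, g) == ["v1"]

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.binomial(2, 0.4, (400, 6)).astype(float))
        ss = _summary([f"v{j}" for j in range(6)], p=rng.uniform(0, 1, 6))
        assert sorted(clump(ss, g)) == [f"v{j}" for j in range(6)]

    def test_matches_brute_force_on_toy_panels(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, m = 80, 50
            base = rng.binomial(2, 0.4, (n, m)).astype(float)
            # induce correlation between neighbours
            for j in range(1, m):
                dup = rng.random(n) < 0.7
                base[dup, j] = base[dup, j - 1]
            pos = np.sort(rng.integers(1, 400_000, m))
            g = make_genotypes(base, pos=pos)
            ss = _summary([f"v{j}" for j in range(m)], p=rng.uniform(0, 1, m), pos=pos)
            params = CTParams(clump_window_kb=100, clump_r2=0.2)
            assert clump(ss, g, params) == brute_force_clump(ss, g, params)

    def test_index_choice_p_monotone(self):
        rng = np.random.default_rng(9)
        g = make_genotypes(rng.binomial(2, 0.4, (100, 20)).astype(float))
        ss = _summary([f"v{j}" for j in range(20)], p=rng.uniform(0, 1, 20))
        kept = clump(ss, g, CTParams(clump_r2=0.05))
        assert set(kept) <= set(ss.table.index)


class TestScore:
    def test_cancelling_weights(self):
        g = make_genotypes(np.array([[2.0, 2.0]]))
        prof = score(_model(["v0", "v1"], [1.0, -1.0]), g)
        assert prof.raw[0] == 0.0

    def test_zero_weights_give_midpoint_scaled(self):
        g = make_genotypes(np.random.default_rng(2).integers(0, 3, (5, 3)).astype(float))
        prof = score(_model(["v0", "v1", "v2"], [0, 0, 0]), g)
        assert (prof.raw == 0).all()
        assert (prof.scaled == 0.5).all()

    def test_matches_double_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dos = rng.integers(0, 3, (5, 10)).astype(float)
            dos[rng.random((5, 10)) < 0.2] = np.nan
            effect = rng.choice(["A", "G"], 10)
            g = make_genotypes(dos)
            model = _model([f"v{j}" for j in range(10)], rng.standard_normal(10), effect=effect)
            prof = score(model, g)
            assert np.allclose(prof.raw, brute_force_score(model, g), atol=1e-12)

    def test_allele_flip_preserves_association(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, (100, 4)).astype(float)
        g = make_genotypes(dos)
        w = rng.standard_normal(4)
        m1 = _model([f"v{j}" for j in range(4)], w)
        # recode variant 0: swap alleles, negate weight
        m2 = _model([f"v{j}" for j in range(4)], [-w[0], *w[1:]], effect=["G", "A", "A", "A"])
        y = dos @ w + 0.1 * rng.standard_normal(100)
        r1 = np.corrcoef(score(m1, g).raw, y)[0, 1]
        r2 = np.corrcoef(score(m2, g).raw, y)[0, 1]
        assert abs(abs(r1) - abs(r2)) < 1e-10

    def test_unmatchable_majority_errors(self):
        g = make_genotypes(np.ones((3, 2)) * 1.0)
        model = _model(["v0", "zz1", "zz2"], [1, 1, 1])
        with pytest.raises(ParameterError, match="unmatchable"):
            score(model, g)


class TestDeriveBestPRS:
    def _cohort_with_one_causal(self, seed, n=800):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, 0.3, (n, 20)).astype(float)
        x = (dos[:, 7] - dos[:, 7].mean()) / dos[:, 7].std()
        y = np.sqrt(0.2) * x + np.sqrt(0.8) * rng.standard_normal(n)
        g = make_genotypes(dos)
        ph = make_phenotypes(g.samples, height=y)
        return g, ph, y

    def test_recovers_single_causal_variant(self):
        g, ph, y = self._cohort_with_one_causal(0)
        src = np.arange(400)
        tgt = np.arange(400, 800)
        from stabprs import gwas_scan

        ss = gwas_scan(g.subset(samples=src), ph)
        covars = np.ones((400, 1))
        model, fit = derive_best_prs(
            ss, g.subset(samples=tgt), ph, covars,
            params=CTParams(p_grid=(1.0,), n_permutations=200), seed=1,
        )
        assert "v7" in model.variant_ids
        assert abs(fit.attrs["best_incremental_r2"] - 0.2) < 0.07
        assert fit.attrs["empirical_p"] <= 0.05

    def test_permutation_p_deterministic(self):
        g, ph, _ = self._cohort_with_one_causal(4, n=300)
        from stabprs import gwas_scan

        ss = gwas_scan(g.subset(samples=np.arange(150)), ph)
        covars = np.ones((150, 1))
        args = (ss, g.subset(samples=np.arange(150, 300)), ph, covars)
        _, f1 = derive_best_prs(*args, params=CTParams(n_permutations=300), seed=42)
        _, f2 = derive_best_prs(*args, params=CTParams(n_permutations=300), seed=42)
        assert f1.attrs["empirical_p"] == f2.attrs["empirical_p"]

    def test_null_summary_stats_give_small_r2(self):
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.4, (1000, 40)).astype(float)
        g = make_genotypes(dos)
        y = rng.standard_normal(1000)
        ph = make_phenotypes(g.samples, height=y)
        from stabprs import gwas_scan

        r2s = []
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(1000)
            src, tgt = perm[:500], perm[500:]
            ss = gwas_scan(g.subset(samples=src), ph)
            _, fit = derive_best_prs(
                ss, g.subset(samples=tgt), ph, np.ones((500, 1)),
                params=CTParams(n_permutations=0), seed=seed,
            )
            r2s.append(fit.attrs["best_incremental_r2"])
        assert np.median(r2s) < 0.02

    def test_no_passing_variant_errors(self):
        g = make_genotypes(np.random.default_rng(1).binomial(2, 0.4, (50, 3)).astype(float))
        ss = _summary(["v0", "v1", "v2"], p=[0.5, 0.6, 0.9])
        ph = make_phenotypes(g.samples, height=np.random.default_rng(2).standard_normal(50))
        with pytest.raises(ParameterError):
            derive_best_prs(ss, g, ph, np.ones((50, 1)), params=CTParams(p_grid=(1e-8,)), seed=0)
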