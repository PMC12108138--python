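"""Bootstrap ensemble, frequency aggregation, candidates and finalization."""

import numpy as np
import pandas as pd
import pytest

from stabprs import (
    CTParams,
    EnsembleConfig,
    LDBlockSpec,
    ParameterError,
    TraitArchitecture,
    aggregate,
    bootstrap_p,
    build_candidates,
    finalize,
    narrow_down,
    run_ensemble,
    simulate_cohort,
    stability_pipeline,
)
from stabprs.ensemble import CandidatePRS, IterationRecord
from stabprs.prs import PRSModel, _incremental_r2_columns
from stabprs.qc import apply_qc


def _fake_record(i, snp_ids):
    entries = pd.DataFrame(
        {
            "chrom": ["1"] * len(snp_ids),
            "pos": range(len(snp_ids)),
            "effect_allele": ["A"] * len(snp_ids),
            "weight": np.ones(len(snp_ids)),
            "p_source": np.full(len(snp_ids), 0.01),
        },
        index=pd.Index(snp_ids, name="variant_id"),
    )
    return IterationRecord(index=i, source_ids=np.array([]), target_ids=np.array([]),
                           model=PRSModel(entries=entries), incremental_r2=0.05)


@pytest.fixture(scope="module")
def tiny_run():
    cohort = simulate_cohort(
        n_samples=160,
        ld=LDBlockSpec(n_blocks=10, block_size=12),
        arch=TraitArchitecture(n_causal=15, heritability=0.5),
        missing_rate=0.01,
        seed=17,
    )
    g, _, _ = apply_qc(cohort.genotypes)
    config = EnsembleConfig(n_iterations=6, min_freq_floor=1, max_pcs=3,
                            ct=CTParams(n_permutations=0))
    records, baseline = run_ensemble(g, cohort.phenotypes, config, seed=5)
    return cohort, g, config, records, baseline


class TestRunEnsemble:
    def test_split_sizes_and_disjointness(self, tiny_run):
        _, g, config, records, _ = tiny_run
        n_src = int(np.floor(0.8 * g.n_samples))
        for r in records:
            assert len(r.source_ids) == n_src
            assert set(r.source_ids).isdisjoint(r.target_ids)
            assert len(r.source_ids) + len(r.target_ids) == g.n_samples

    def test_deterministic_rerun(self, tiny_run):
        cohort, g, config, records, baseline = tiny_run
        records2, baseline2 = run_ensemble(g, cohort.phenotypes, config, seed=5)
        assert np.array_equal(baseline, baseline2)
        for a, b in zip(records, records2):
            assert list(a.model.variant_ids) == list(b.model.variant_ids)
            assert a.incremental_r2 == b.incremental_r2

    def test_baseline_above_null_run(self, tiny_run):
        _, _, config, _, baseline = tiny_run
        null = simulate_cohort(
            n_samples=160,
            ld=LDBlockSpec(n_blocks=10, block_size=12),
            arch=TraitArchitecture(n_causal=15, heritability=0.0),
            missing_rate=0.01,
            seed=18,
        )
        g0, _, _ = apply_qc(null.genotypes)
        _, base0 = run_ensemble(g0, null.phenotypes, config, seed=6)
        assert baseline.mean() > base0.mean()


class TestAggregate:
    def test_counts_match_brute_force(self, tiny_run):
        _, _, _, records, _ = tiny_run
        freq = aggregate(records)
        brute = {}
        for r in records:
            if r.failed:
                continue
            for v in set(r.model.variant_ids):
                brute[v] = brute.get(v, 0) + 1
        assert dict(freq) == brute

    def test_always_and_never_selected(self):
        recs = [_fake_record(i, ["a", f"b{i}"]) for i in range(100)]
        freq = aggregate(recs)
        assert freq["a"] == 100
        assert "zzz" not in freq.index

    def test_empty_raises(self):
        with pytest.raises(ParameterError):
            aggregate([])


class TestBuildCandidates:
    def test_sets_match_brute_force_and_nest(self, tiny_run):
        cohort, g, _, records, _ = tiny_run
        freq = aggregate(records)
        cands = build_candidates(freq, records, g, cohort.phenotypes, min_freq_floor=1)
        counts = dict(freq)
        for cand in cands:
            expect = {v for v, c in counts.items() if c >= cand.min_freq}
            assert set(cand.snp_ids) == expect
        for a, b in zip(cands, cands[1:]):
            assert set(b.snp_ids) <= set(a.snp_ids)

    def test_floor_above_max_gives_empty(self, tiny_run):
        cohort, g, _, records, _ = tiny_run
        freq = aggregate(records)
        assert build_candidates(freq, records, g, cohort.phenotypes, min_freq_floor=1000) == []

    def test_r2_values_match_rescoring_oracle(self, tiny_run):
        cohort, g, _, records, _ = tiny_run
        freq = aggregate(records)
        cands = build_candidates(freq, records, g, cohort.phenotypes, min_freq_floor=1)
        cand = cands[min(1, len(cands) - 1)]
        col = {v: j for j, v in enumerate(g.variant_ids)}
        for k, r in enumerate(rec for rec in records if not rec.failed):
            ids = [v for v in cand.snp_ids]
            cols = np.array([col[v] for v in ids])
            tgt = g.subset_by_sample_id(r.target_ids).subset(variants=cols)
            w = r.betas.reindex(ids)
            have = ~w.isna().to_numpy()
            wv = np.where(have, w.to_numpy(float), 0.0)
            d = tgt.mean_imputed()
            obs = ((~np.isnan(tgt.dosage)) & have[None, :]).sum(axis=1)
            s = (d * wv).sum(axis=1) / (2 * np.where(obs > 0, obs, len(ids)))
            y = cohort.phenotypes.aligned_to(r.target_ids)["height_cm"].to_numpy()
            r2 = _incremental_r2_columns(s[:, None], y, r.target_covars)[0]
            assert abs(r2 - cand.r2_values[k]) < 1e-10


class TestNarrowDown:
    def _cand(self, f, mean):
        return CandidatePRS(min_freq=f, snp_ids=np.array(["x"]), r2_values=np.full(4, mean))

    def test_monotone_decreasing_keeps_first(self):
        cands = [self._cand(f, m) for f, m in zip([10, 20, 30], [0.3, 0.2, 0.1])]
        assert [c.min_freq for c in narrow_down(cands)] == [10]

    def test_definition_example(self):
        cands = [self._cand(f, m) for f, m in zip([10, 20, 30, 40], [0.10, 0.06, 0.07, 0.05])]
        assert [c.min_freq for c in narrow_down(cands)] == [10, 30]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            means = rng.random(rng.integers(1, 9))
            cands = [self._cand(10 + i, m) for i, m in enumerate(means)]
            got = {c.min_freq for c in narrow_down(cands)}
            expect = set()
            for i in range(len(means)):
                left = means[i] > means[i - 1] if i > 0 else True
                right = means[i] > means[i + 1] if i < len(means) - 1 else True
                if left and right:
                    expect.add(10 + i)
            assert got == expect


class TestBootstrapP:
    def _cand(self, vals):
        return CandidatePRS(min_freq=10, snp_ids=np.array(["x"]), r2_values=np.asarray(vals, float))

    def test_extremes(self):
        baseline = np.array([0.01, 0.02, 0.03])
        assert bootstrap_p(self._cand([0.5, 0.5]), baseline) == 0.0
        assert bootstrap_p(self._cand([0.001, 0.001]), baseline) == 1.0

    def test_interleaved_hand_count(self):
        baseline = np.array([0.10, 0.04, 0.07, 0.02, 0.09])
        cand = self._cand([0.05, 0.05])  # mean 0.05; baseline above: 0.10, 0.07, 0.09
        assert bootstrap_p(cand, baseline) == 3 / 5

    def test_monotone_in_candidate_mean(self):
        rng = np.random.default_rng(1)
        baseline = rng.random(50)
        means = np.sort(rng.random(10))
        ps = [bootstrap_p(self._cand([m]), baseline) for m in means]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestFinalize:
    def test_whole_cohort_weights_carried(self, tiny_run):
        cohort, g, _, records, _ = tiny_run
        from stabprs import genotype_pca, gwas_scan
        from stabprs.qc import ld_prune

        basis = genotype_pca(g, ld_prune(g), max_pcs=3)
        whole = gwas_scan(g, cohort.phenotypes, pcs=basis)
        snps = whole.table.index[:3]
        cand = CandidatePRS(min_freq=2, snp_ids=np.array(snps), r2_values=np.array([0.1]))
        model = finalize(cand, whole)
        assert np.allclose(model.weights(), whole.table.loc[snps, "beta"])
        # per-iteration source weights differ from whole-cohort weights
        rec = next(r for r in records if not r.failed)
        common = [v for v in snps if v in rec.betas.index]
        if common:
            assert not np.allclose(whole.table.loc[common, "beta"], rec.betas.loc[common])

    def test_empty_intersection_errors(self, tiny_run):
        cohort, g, _, records, _ = tiny_run
        from stabprs import genotype_pca, gwas_scan
        from stabprs.qc import ld_prune

        whole = gwas_scan(g, cohort.phenotypes, pcs=genotype_pca(g, ld_prune(g), max_pcs=3))
        cand = CandidatePRS(min_freq=2, snp_ids=np.array(["nope1", "nope2"]), r2_values=np.array([0.1]))
        with pytest.raises(ParameterError):
            finalize(cand, whole)


def test_pipeline_enriches_causal_variants(tiny_run):
    cohort, g, config, _, _ = tiny_run
    res = stability_pipeline(g, cohort.phenotypes, config, seed=5)
    causal = set(cohort.causal_ids)
    sel = set(res.final_model.variant_ids)
    base_rate = len(causal & set(g.variant_ids)) / g.n_variants
    assert len(sel & causal) / len(sel) > base_rate
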