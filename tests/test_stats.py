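import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pwaskit import (
    ForestConfig,
    MrmrConfig,
    PathwaySnpPool,
    bh_adjust,
    combined_r2,
    metric_ci,
    nagelkerke_r2,
    pathway_pvalue,
    permute_labels,
    run_pathway,
    run_pwas,
    stratified_split,
)
from pwaskit.errors import ClassBalanceError, DegenerateInputError
from pwaskit.stats import results_frame

from oracles import bh_oracle, nagelkerke_grid_oracle


class TestStratifiedSplit:
    def test_exact_80_20_arithmetic(self):
        y = np.array([1] * 100 + [0] * 100)
        sel, test = stratified_split(y, 0.8, rng=1)
        assert (y[sel] == 1).sum() == 80 and (y[sel] == 0).sum() == 80
        assert (y[test] == 1).sum() == 20 and (y[test] == 0).sum() == 20
        assert len(np.intersect1d(sel, test)) == 0
        assert len(sel) + len(test) == 200

    def test_round_half_up(self):
        y = np.array([1] * 101 + [0] * 10)
        sel, _ = stratified_split(y, 0.8, rng=0)
        assert (y[sel] == 1).sum() == 81  # floor(80.8 + 0.5)
        assert (y[sel] == 0).sum() == 8

    def test_different_seeds_same_counts_different_partitions(self):
        y = np.tile([0, 1], 50)
        s1, _ = stratified_split(y, 0.8, rng=1)
        s2, _ = stratified_split(y, 0.8, rng=2)
        assert len(s1) == len(s2)
        assert not np.array_equal(s1, s2)

    def test_tiny_class_rejected(self):
        with pytest.raises(ClassBalanceError):
            stratified_split(np.array([0, 0, 0, 1]), 0.8, rng=0)


class TestPermutation:
    def test_class_counts_preserved(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        p = permute_labels(y, rng)
        assert p.sum() == 30 and len(p) == 100

    def test_identity_on_single_element(self):
        np.testing.assert_array_equal(permute_labels(np.array([1]), 0), [1])

    def test_positionwise_uniformity(self):
        y = np.array([1] * 3 + [0] * 7)
        hits = np.zeros(10)
        n = 2000
        for seed in range(n):
            hits += permute_labels(y, seed)
        freq = hits / n
        se = np.sqrt(0.3 * 0.7 / n)
        assert np.all(np.abs(freq - 0.3) < 3.5 * se)


class TestPathwayPvalue:
    def test_identical_samples_give_p_one(self):
        ors = [1.0, 1.2, 0.9, 1.1]
        assert pathway_pvalue(ors, ors) == pytest.approx(1.0)

    def test_separated_means_give_tiny_p(self, rng):
        real = rng.normal(1.2, 0.01, 100)
        perm = rng.normal(1.0, 0.01, 100)
        assert pathway_pvalue(real, perm) < 1e-10

    def test_type_one_error_calibrated(self):
        rejections = 0
        n = 1000
        for seed in range(n):
            r = np.random.default_rng((seed, 0)).normal(1.0, 0.1, 50)
            q = np.random.default_rng((seed, 1)).normal(1.0, 0.1, 50)
            rejections += pathway_pvalue(r, q) < 0.05
        assert 0.03 <= rejections / n <= 0.07

    def test_matches_welch_closed_form(self, rng):
        a, b = rng.normal(1.1, 0.2, 40), rng.normal(1.0, 0.3, 60)
        assert pathway_pvalue(a, b) == pytest.approx(
            sps.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_degenerate_variances(self):
        with pytest.raises(DegenerateInputError):
            pathway_pvalue([1.0, 1.0], [2.0, 2.0])


class TestBhAdjust:
    def test_canonical_flattening_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_inputs(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_hand_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            ps = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(ps), bh_oracle(ps), atol=1e-12)

    def test_monotone_and_order_preserving(self, rng):
        ps = rng.random(30)
        adj = bh_adjust(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)
        # order restored: adjusting a permuted copy permutes identically
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(ps[perm]), adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestMetricCi:
    def test_constant_vector(self):
        assert metric_ci([0.7] * 10) == pytest.approx((0.7, 0.7, 0.7))

    def test_bernoulli_closed_form(self):
        values = [0.0] * 50 + [1.0] * 50
        mean, lo, hi = metric_ci(values)
        sd = np.std(values, ddof=1)
        half = sps.norm.ppf(0.975) * sd / 10
        assert mean == pytest.approx(0.5)
        assert hi - mean == pytest.approx(half)

    def test_width_shrinks_with_sqrt_n(self, rng):
        v = rng.normal(0, 1, 400)
        _, lo1, hi1 = metric_ci(v[:100])
        _, lo2, hi2 = metric_ci(v)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_percentile_method(self, rng):
        v = rng.normal(0, 1, 1000)
        mean, lo, hi = metric_ci(v, method="percentile")
        assert lo == pytest.approx(np.quantile(v, 0.025))
        assert hi == pytest.approx(np.quantile(v, 0.975))

    def test_needs_two_values(self):
        with pytest.raises(DegenerateInputError):
            metric_ci([0.5])


class TestNagelkerke:
    def test_matches_grid_search_oracle_on_toy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        res = nagelkerke_r2(y, x)
        assert res.r2 == pytest.approx(nagelkerke_grid_oracle(y, x), abs=1e-4)

    def test_null_scores_near_zero(self, rng):
        y = rng.integers(0, 2, 2000).astype(float)
        x = rng.normal(size=2000)
        assert nagelkerke_r2(y, x).r2 < 0.01

    def test_separation_flagged_at_upper_bound(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.array([-1.0] * 10 + [1.0] * 10)
        res = nagelkerke_r2(y, x)
        assert res.separation
        assert res.r2 == pytest.approx(1.0)

    def test_constant_score_is_null_model(self):
        y = np.array([0.0, 1.0] * 10)
        res = nagelkerke_r2(y, np.full(20, 0.5))
        assert res.r2 == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 50).astype(float)
            if len(np.unique(y)) < 2:
                continue
            x = rng.normal(size=50)
            assert 0.0 <= nagelkerke_r2(y, x).r2 <= 1.0


class TestCombinedR2:
    def test_union_of_one_equals_single(self, small_study):
        ds = small_study.dataset
        snps = ds.snp_ids.tolist()[:4]
        single = nagelkerke_r2(ds.phenotypes, ds.genotypes[:, ds.snp_indices(snps)])
        assert combined_r2([snps], ds).r2 == pytest.approx(single.r2)

    def test_duplicated_pathway_is_idempotent(self, small_study):
        ds = small_study.dataset
        snps = ds.snp_ids.tolist()[:4]
        assert combined_r2([snps, snps], ds).r2 == pytest.approx(combined_r2([snps], ds).r2)

    def test_adding_informative_snps_cannot_reduce_fit(self):
        import pwaskit

        cfg = pwaskit.SimulationConfig(
            n_cases=400, n_controls=400, n_genes=12, snps_per_gene=2, n_pathways=2,
            genes_per_pathway=4, n_causal_pathways=2, causal_snps_per_pathway=3,
            effect_size_beta=0.6, missing_rate=0.0, seed=21,
        )
        study = pwaskit.simulate_study(cfg)
        ds = study.dataset
        meta = ds.snp_meta
        sets = [
            meta.loc[meta["causal_pathway"] == pid, "snp_id"].tolist()
            for pid in study.causal_pathways
        ]
        r_single = combined_r2([sets[0]], ds).r2
        r_both = combined_r2(sets, ds).r2
        assert r_both >= r_single - 1e-9


class TestRunPathway:
    def test_single_snp_pool_is_excluded(self, small_study):
        ds = small_study.dataset
        pool = PathwaySnpPool("tiny", ["G0001"], [ds.snp_ids.iloc[0]])
        res, trace = run_pathway(
            pool, ds, mrmr=MrmrConfig(k_features=3), forest=ForestConfig(n_trees=5),
            n_iterations=3, master_seed=0,
        )
        assert res.excluded
        assert np.isnan(res.p_raw)
        assert trace.n_iterations == 3

    def test_full_run_deterministic_and_bh_filled(self, small_study):
        ds = small_study.dataset
        ids = ds.snp_ids.tolist()
        pools = [
            PathwaySnpPool("A", [], ids[:6]),
            PathwaySnpPool("B", [], ids[6:12]),
            PathwaySnpPool("C", [], ids[:1]),  # excluded
        ]
        kwargs = dict(mrmr=MrmrConfig(k_features=3), forest=ForestConfig(n_trees=10),
                      n_iterations=4, master_seed=7)
        res1, tr1 = run_pwas(pools, ds, **kwargs)
        res2, tr2 = run_pwas(list(reversed(pools)), ds, **kwargs)
        df1 = results_frame(res1).set_index("pathway_id").sort_index()
        df2 = results_frame(res2).set_index("pathway_id").sort_index()
        pd.testing.assert_frame_equal(df1, df2)
        assert df1.loc["C", "excluded"]
        tested = df1.loc[~df1["excluded"]]
        assert tested["p_bh"].notna().all()
        assert (tested["p_bh"] >= tested["p_raw"] - 1e-15).all()
        # traces identical regardless of execution order
        assert tr1["A"].iterations == tr2["A"].iterations

    def test_validation_cohort_drives_estimates(self, small_study):
        import pwaskit

        ds = small_study.dataset
        cfg2 = pwaskit.SimulationConfig(
            n_cases=150, n_controls=150, n_genes=30, snps_per_gene=3, n_pathways=8,
            genes_per_pathway=3, n_causal_pathways=0, causal_snps_per_pathway=0,
            effect_size_beta=0.0, missing_rate=0.01, seed=99,
        )
        validation = pwaskit.simulate_study(cfg2).dataset
        pool = PathwaySnpPool("A", [], ds.snp_ids.tolist()[:6])
        kwargs = dict(mrmr=MrmrConfig(k_features=3), forest=ForestConfig(n_trees=10),
                      n_iterations=3, master_seed=1)
        res_test, _ = run_pathway(pool, ds, None, **kwargs)
        res_val, _ = run_pathway(pool, ds, validation, **kwargs)
        assert not np.isnan(res_val.p_raw)
        # same selection trace but different evaluation cohort -> different ORs
        assert not np.allclose(res_val.or_real, res_test.or_real)
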