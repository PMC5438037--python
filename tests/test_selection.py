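import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwaskit import (
    MrmrConfig,
    appearance_rates,
    consensus_select,
    gene_appearance_rate,
    greedy_tag_snps,
    ld_r2,
    mrmr_select,
    mutual_information,
)
from pwaskit.errors import ClassBalanceError, DegenerateInputError, SelectionError
from pwaskit.selection import SelectionTrace

from oracles import mi_oracle, mrmr_oracle


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_constant_genotype_gives_zero(self):
        x = np.zeros(40, dtype=np.int8)
        y = np.array([0, 1] * 20)
        assert mutual_information(x, y) == 0.0

    def test_perfect_binary_dependence_is_one_bit(self):
        x = np.array([0] * 30 + [2] * 30, dtype=np.int8)
        y = (x > 0).astype(np.int8)
        assert mutual_information(x, y) == pytest.approx(1.0)

    def test_hand_computed_contingency_table(self):
        # joint counts {(0,ctrl):2, (0,case):1, (2,ctrl):1, (2,case):2}
        x = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
        y = np.array([0, 0, 1, 0, 1, 1], dtype=np.int8)
        expected = sum(
            c / 6 * math.log2((c / 6) / (0.5 * 0.5)) for c in (2, 1, 1, 2)
        )
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    def test_missing_entries_pairwise_deleted(self):
        x = np.array([0, 0, 2, 2, -1, -1], dtype=np.int8)
        y = np.array([0, 0, 1, 1, 0, 1], dtype=np.int8)
        assert mutual_information(x, y) == pytest.approx(1.0)

    def test_constant_label_raises(self):
        with pytest.raises(DegenerateInputError):
            mutual_information(np.array([0, 1, 2]), np.array([1, 1, 1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_entropy_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        x = rng.integers(0, 3, n).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.int8)
        if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
            return
        mi_xy = mutual_information(x, y)
        assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)
        hx = -sum(p * math.log2(p) for p in np.bincount(x) / n if p > 0)
        hy = -sum(p * math.log2(p) for p in np.bincount(y) / n if p > 0)
        assert -1e-12 <= mi_xy <= min(hx, hy) + 1e-12


# ---------------------------------------------------------------------------
# mRmR
# ---------------------------------------------------------------------------

class TestMrmr:
    def test_k1_is_argmax_mi(self, rng):
        X = rng.integers(0, 3, (100, 6)).astype(np.int8)
        y = rng.integers(0, 2, 100).astype(np.int8)
        pick = mrmr_select(X, y, MrmrConfig(k_features=1))
        rels = [mi_oracle(X[:, j], y) for j in range(6)]
        assert pick == [int(np.argmax(rels))]

    @pytest.mark.parametrize("criterion", ["difference", "quotient"])
    def test_matches_brute_force_oracle(self, criterion, rng):
        for _ in range(30):
            p = int(rng.integers(2, 7))
            X = rng.integers(0, 3, (80, p)).astype(np.int8)
            y = rng.integers(0, 2, 80).astype(np.int8)
            if len(np.unique(y)) < 2:
                continue
            k = int(rng.integers(1, p + 1))
            assert mrmr_select(X, y, MrmrConfig(k_features=k, criterion=criterion)) \
                == mrmr_oracle(X, y, k, criterion)

    def test_duplicate_of_top_snp_penalized(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 60, dtype=np.int8)
        strong = np.where(y == 1, 2, 0).astype(np.int8)
        flip = rng.random(120) < 0.15
        strong[flip] = 2 - strong[flip]
        weak = np.where(y == 1, 1, 0).astype(np.int8)
        noise = rng.random(120) < 0.45
        weak[noise] = rng.integers(0, 3, int(noise.sum()))
        X = np.column_stack([strong, strong.copy(), weak])
        picks = mrmr_select(X, y, MrmrConfig(k_features=2))
        assert picks[0] == 0
        assert picks[1] == 2  # the exact duplicate is maximally redundant

    def test_empty_pool_and_single_class_errors(self):
        with pytest.raises(SelectionError):
            mrmr_select(np.empty((5, 0), dtype=np.int8), np.array([0, 1, 0, 1, 0]),
                        MrmrConfig())
        with pytest.raises(ClassBalanceError):
            mrmr_select(np.zeros((4, 2), dtype=np.int8), np.zeros(4, dtype=np.int8),
                        MrmrConfig())


class TestConsensus:
    def _data(self, rng, n=120, p=6):
        X = rng.integers(0, 3, (n, p)).astype(np.int8)
        y = np.tile([0, 1], n // 2).astype(np.int8)
        return X, y

    def test_min_one_is_union_and_min_max_is_intersection(self, rng):
        X, y = self._data(rng)
        cfg_union = MrmrConfig(k_features=2, consensus_min=1, seed=5)
        cfg_inter = MrmrConfig(k_features=2, consensus_min=10, seed=5)
        union, runs = consensus_select(X, y, cfg_union)
        inter, runs2 = consensus_select(X, y, cfg_inter)
        assert set(union) == set().union(*[set(r) for r in runs])
        assert set(inter) == set.intersection(*[set(r) for r in runs2])

    def test_overwhelming_snp_always_selected(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = self._data(rng, n=200)
            X[:, 3] = np.where(y == 1, 2, 0)  # perfectly informative
            consensus, runs = consensus_select(X, y, MrmrConfig(k_features=2), rng)
            assert all(3 in r for r in runs)
            assert 3 in consensus

    def test_subsamples_preserve_class_ratio(self, rng):
        from pwaskit.selection import _stratified_take

        y = np.array([0] * 90 + [1] * 30)
        idx = _stratified_take(y, 0.8, rng)
        assert (y[idx] == 0).sum() == 72
        assert (y[idx] == 1).sum() == 24


# ---------------------------------------------------------------------------
# appearance rates
# ---------------------------------------------------------------------------

class TestAppearanceRates:
    def test_definition(self):
        iters = [("a", "b")] * 37 + [("b",)] * 63
        rates = appearance_rates(iters)
        assert rates["a"] == pytest.approx(0.37)
        assert rates["b"] == pytest.approx(1.0)
        assert "c" not in rates

    def test_invariant_to_iteration_order(self, rng):
        iters = [tuple(rng.choice(["a", "b", "c"], size=rng.integers(0, 3), replace=False))
                 for _ in range(50)]
        shuffled = list(iters)
        rng.shuffle(shuffled)
        assert appearance_rates(iters) == appearance_rates(shuffled)

    def test_trace_frame_consistency(self):
        trace = SelectionTrace("P1", [("a",), ("a", "b"), ()])
        df = trace.to_frame()
        a_row = df[df["snp_id"] == "a"].iloc[0]
        assert a_row["appearance_rate"] == pytest.approx(2 / 3)
        assert a_row["n_iterations_selected"] == 2


# ---------------------------------------------------------------------------
# LD and tag SNPs
# ---------------------------------------------------------------------------

class TestLd:
    def test_self_and_flip_give_one(self, rng):
        g = rng.integers(0, 3, 50).astype(np.int8)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self, rng):
        r2s = [ld_r2(rng.integers(0, 3, 2000), rng.integers(0, 3, 2000)) for _ in range(30)]
        assert np.mean(r2s) < 0.01

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            ld_r2(np.zeros(10), np.arange(10) % 3)

    def test_tag_counts_on_engineered_matrices(self, rng):
        indep = rng.integers(0, 3, (500, 3)).astype(np.int8)
        assert greedy_tag_snps(indep)[0] == 3
        g = rng.integers(0, 3, 500).astype(np.int8)
        identical = np.column_stack([g, g, g])
        assert greedy_tag_snps(identical)[0] == 1

    def test_tagging_matches_brute_force_on_random_panels(self, rng):
        for _ in range(20):
            G = rng.integers(0, 3, (200, 5)).astype(np.int8)
            # mix in some correlated copies
            G[:, 3] = np.where(rng.random(200) < 0.9, G[:, 0], rng.integers(0, 3, 200))
            count, kept = greedy_tag_snps(G, 0.5)
            kept_oracle = []
            for j in range(5):
                ok = True
                for t in kept_oracle:
                    try:
                        if ld_r2(G[:, t], G[:, j]) >= 0.5:
                            ok = False
                            break
                    except DegenerateInputError:
                        continue
                if ok:
                    kept_oracle.append(j)
            assert kept == kept_oracle
            assert count == len(kept_oracle)


class TestGeneRates:
    def test_single_snp_identity(self):
        assert gene_appearance_rate({"s1": 0.8}, {"G": ["s1"]}, {"G": 1}) == {"G": 0.8}

    def test_correlated_snps_share_one_tag(self):
        rates = {"s1": 0.5, "s2": 0.3}
        out = gene_appearance_rate(rates, {"G": ["s1", "s2"]}, {"G": 1})
        assert out["G"] == pytest.approx(0.8)

    def test_three_gene_toy_matches_hand_computation(self):
        rates = {"a": 0.9, "b": 0.1, "c": 0.4, "d": 0.0}
        genes = {"G1": ["a", "b"], "G2": ["c"], "G3": ["d", "missing"]}
        tags = {"G1": 2, "G2": 1, "G3": 2}
        out = gene_appearance_rate(rates, genes, tags)
        assert out == pytest.approx({"G1": 0.5, "G2": 0.4, "G3": 0.0})

    def test_gene_without_snps_omitted(self):
        out = gene_appearance_rate({"a": 1.0}, {"G1": ["a"], "G2": []}, {"G1": 1})
        assert "G2" not in out
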