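"""dbRDA variation partitioning, envfit, ANOVA + Tukey letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from chemoclass.eco_stats import (anova_tukey_cld, compact_letter_display,
                                  dbrda, envfit, factor_design, varpart)
from chemoclass.tree_comparison import DistanceMatrix


def euclidean_dm(X, labels=None):
    labels = labels or tuple(f"s{i}" for i in range(len(X)))
    return DistanceMatrix(tuple(labels), squareform(pdist(X)))


class TestDbrda:
    def test_perfect_group_separation_explains_everything(self):
        X = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        X = X + np.array([[0, 0], [0.0001, 0], [0, 0], [0.0001, 0]])  # break exact ties
        groups = ["a", "a", "b", "b"]
        res = dbrda(euclidean_dm(X), factor_design(groups))
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-6)

    def test_saturated_model_explains_everything(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        res = dbrda(euclidean_dm(X), np.eye(5))
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-8)

    def test_random_predictor_matches_expected_null_fraction(self):
        """Orthogonal 2-level factor explains ~ (levels-1)/(n-1)."""
        rng = np.random.default_rng(1)
        n = 36
        fracs = []
        for _ in range(30):
            X = rng.normal(size=(n, 8))
            groups = list(np.repeat(["a", "b"], n // 2))
            rng.shuffle(groups)
            fracs.append(dbrda(euclidean_dm(X), factor_design(groups))
                         .constrained_fraction)
        assert np.mean(fracs) == pytest.approx(1 / (n - 1), abs=0.01)

    def test_euclidean_input_reduces_to_classical_rda_r2(self):
        """With Euclidean distances the fraction equals multivariate
        regression R^2 computed directly on the (centered) data."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        groups = list(np.repeat(["a", "b", "c"], 4))
        res = dbrda(euclidean_dm(X), factor_design(groups))
        Xc = X - X.mean(axis=0)
        D = factor_design(groups).to_numpy()
        Dc = D - D.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Dc, Xc, rcond=None)
        r2_direct = (Dc @ beta).__pow__(2).sum() / (Xc ** 2).sum()
        assert res.constrained_fraction == pytest.approx(r2_direct, abs=1e-10)

    def test_fraction_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        groups = list(np.repeat(["a", "b"], 5))
        dm = euclidean_dm(X)
        res1 = dbrda(dm, factor_design(groups))
        perm = rng.permutation(10)
        dm2 = DistanceMatrix(tuple(dm.labels[i] for i in perm),
                             dm.d[np.ix_(perm, perm)])
        res2 = dbrda(dm2, factor_design([groups[i] for i in perm]))
        assert res1.constrained_fraction == pytest.approx(
            res2.constrained_fraction, abs=1e-10)

    def test_fraction_in_unit_interval(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(5.0, size=(10, 6)).astype(float) + 0.1
        d = squareform(pdist(X, "braycurtis"))
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(10)), d)
        res = dbrda(dm, factor_design(list(np.repeat(["a", "b"], 5))))
        assert 0.0 <= res.constrained_fraction <= 1.0

    def test_predictor_row_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="rows"):
            dbrda(euclidean_dm(X), np.ones((3, 1)))


class TestVarpart:
    def make_case(self, seed=0, n_rep=3):
        rng = np.random.default_rng(seed)
        a_levels = ["a1", "a2", "a3"]
        b_levels = ["b1", "b2"]
        rows, fa, fb = [], [], []
        for a in a_levels:
            for b in b_levels:
                for _ in range(n_rep):
                    effect_a = {"a1": 0.0, "a2": 3.0, "a3": 6.0}[a]
                    rows.append(rng.normal(size=4) + effect_a)
                    fa.append(a)
                    fb.append(b)
        return euclidean_dm(np.array(rows)), fa, fb

    def test_null_factor_has_tiny_unique_fraction(self):
        dm, fa, fb = self.make_case()
        out = varpart(dm, fa, fb)
        assert out.loc["unadjusted", "unique_b"] < 0.12
        assert out.loc["unadjusted", "unique_a"] > 0.5

    def test_fractions_sum_to_one(self):
        for seed in range(5):
            dm, fa, fb = self.make_case(seed)
            out = varpart(dm, fa, fb)
            total = (out.loc["unadjusted", ["unique_a", "unique_b", "shared",
                                            "residual"]].sum())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_independent_crossed_factors_share_nothing(self):
        rng = np.random.default_rng(2)
        shared = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows, fa, fb = [], [], []
            for a in range(3):
                for b in range(3):
                    for _ in range(2):
                        rows.append(rng.normal(size=5)
                                    + np.eye(5)[a] * 3 + np.eye(5)[4 - b] * 3)
                        fa.append(f"a{a}")
                        fb.append(f"b{b}")
            out = varpart(euclidean_dm(np.array(rows)), fa, fb)
            shared.append(out.loc["unadjusted", "shared"])
        assert abs(np.mean(shared)) < 0.02


class TestEnvfit:
    def ordination(self, seed=0, n=36):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        return dbrda(euclidean_dm(X), np.eye(n))

    def test_variable_equal_to_axis_one(self):
        ordn = self.ordination()
        v = pd.DataFrame({"v": ordn.site_scores[:, 0]})
        (res,) = envfit(ordn, v, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-8)
        assert res.p == pytest.approx(1 / 100)

    def test_r2_matches_normal_equations_oracle(self):
        ordn = self.ordination(seed=4, n=8)
        rng = np.random.default_rng(3)
        v = rng.normal(size=8)
        (res,) = envfit(ordn, pd.DataFrame({"v": v}), n_perm=9, seed=0)
        Y = ordn.site_scores[:, :2]
        Yc = Y - Y.mean(axis=0)
        vc = v - v.mean()
        beta = np.linalg.solve(Yc.T @ Yc, Yc.T @ vc)
        expect = float((Yc @ beta) @ (Yc @ beta) / (vc @ vc))
        assert res.r2 == pytest.approx(expect, abs=1e-10)

    def test_r2_invariant_to_affine_transform(self):
        ordn = self.ordination(seed=5)
        rng = np.random.default_rng(6)
        v = rng.normal(size=36)
        (r1,) = envfit(ordn, pd.DataFrame({"v": v}), n_perm=9, seed=1)
        (r2,) = envfit(ordn, pd.DataFrame({"v": 5 * v - 3}), n_perm=9, seed=1)
        assert r1.r2 == pytest.approx(r2.r2)
        assert r1.p == r2.p

    def test_constant_variable_flagged(self):
        ordn = self.ordination()
        (res,) = envfit(ordn, pd.DataFrame({"v": np.ones(36)}), n_perm=9, seed=0)
        assert res.constant and res.r2 == 0.0 and res.p == 1.0

    def test_seeded_reproducibility(self):
        ordn = self.ordination(seed=7)
        rng = np.random.default_rng(8)
        v = pd.DataFrame({"v": rng.normal(size=36)})
        r1 = envfit(ordn, v, n_perm=99, seed=5)
        r2 = envfit(ordn, v, n_perm=99, seed=5)
        assert r1[0].p == r2[0].p


def brute_force_letters_consistent(padj, letters, alpha):
    """Letters encode exactly the non-significance graph."""
    groups = list(padj.index)
    for g1, g2 in itertools.combinations(groups, 2):
        share = bool(set(letters[g1]) & set(letters[g2]))
        non_sig = padj.loc[g1, g2] >= alpha
        if share != non_sig:
            return False
    return True


class TestTukeyCLD:
    def test_null_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        vals = {g: rng.normal(size=10) for g in ("a", "b", "c")}
        res = anova_tukey_cld(vals)
        common = set(res.letters["a"]) & set(res.letters["b"]) & set(res.letters["c"])
        assert common

    def test_clear_outlier_group_gets_own_letter(self):
        rng = np.random.default_rng(1)
        vals = {"g1": rng.normal(0, 0.1, 12), "g2": rng.normal(0, 0.1, 12),
                "g3": rng.normal(10, 0.1, 12)}
        res = anova_tukey_cld(vals)
        assert res.letters["g1"] == res.letters["g2"]
        assert not set(res.letters["g3"]) & set(res.letters["g1"])

    def test_letters_match_significance_graph_on_random_instances(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            k = int(rng.integers(2, 7))
            means = rng.uniform(0, 4, size=k)
            vals = {f"g{i}": rng.normal(means[i], 1.0, size=8)
                    for i in range(k)}
            res = anova_tukey_cld(vals, alpha=0.05)
            assert brute_force_letters_consistent(res.p_adjusted, res.letters,
                                                  0.05), f"trial {trial}"

    def test_constant_equal_groups_all_lettered_a(self):
        vals = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        res = anova_tukey_cld(vals)
        assert res.letters == {"a": "a", "b": "a"}

    def test_pairwise_p_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(4)
        vals = {g: rng.normal(i, 1.0, size=6) for i, g in enumerate("abc")}
        res = anova_tukey_cld(vals)
        flat = np.concatenate([vals[g] for g in "abc"])
        labels = np.concatenate([[g] * 6 for g in "abc"])
        tk = pairwise_tukeyhsd(flat, labels)
        for row in tk.summary().data[1:]:
            g1, g2, p = str(row[0]), str(row[1]), float(row[3])
            assert res.p_adjusted.loc[g1, g2] == pytest.approx(p, abs=1e-12)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey_cld({"a": [1.0, 2.0]})

    def test_insert_absorb_on_explicit_matrix(self):
        groups = ["a", "b", "c"]
        padj = pd.DataFrame(1.0, index=groups, columns=groups)
        padj.loc["a", "c"] = padj.loc["c", "a"] = 0.001
        letters = compact_letter_display(padj, alpha=0.05)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
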