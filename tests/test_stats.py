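"""Group comparisons against algebraic identities and permutation oracles."""

import numpy as np
import pytest

from nmjquant import anova_tukey, simple_linreg, two_way_anova, unpaired_t


def permutation_t_pvalue(a, b, n_perm=20_000, seed=0):
    """Two-sided permutation p for the difference of means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-12:
            count += 1
    return count / n_perm


class TestAnovaTukey:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        values = np.concatenate([a, b])
        group = ["a"] * 10 + ["b"] * 12
        res = anova_tukey(values, group)
        t, _ = unpaired_t(a, b)
        assert abs(res.f_statistic - t**2) < 1e-9

    def test_zero_between_group_variance_gives_zero_f(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        group = np.repeat(["a", "b", "c"], 4)
        res = anova_tukey(vals, group)
        assert abs(res.f_statistic) < 1e-12

    def test_tukey_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(m, 1, 8) for m in (0, 0.4, 1.0)])
        group = np.repeat(["g1", "g2", "g3"], 8)
        res = anova_tukey(vals, group)
        for pair, p_adj in res.pairwise_p.items():
            assert p_adj >= res.pairwise_p_unadjusted[pair] - 1e-12
            assert 0.0 <= p_adj <= 1.0

    def test_pairwise_count(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 20)
        group = np.repeat(["a", "b", "c", "d"], 5)
        res = anova_tukey(vals, group)
        assert len(res.pairwise_p) == 6  # 4*3/2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_group_summary_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(5, 2, 15), rng.normal(7, 1, 10)
        res = anova_tukey(np.concatenate([a, b]), ["a"] * 15 + ["b"] * 10)
        g = {s.group: s for s in res.groups}
        mean_a = sum(a) / len(a)
        sd_a = np.sqrt(sum((x - mean_a) ** 2 for x in a) / (len(a) - 1))
        assert abs(g["a"].mean - mean_a) < 1e-9
        assert abs(g["a"].sd - sd_a) < 1e-9
        assert g["a"].n == 15 and g["b"].n == 10


class TestTwoWayAnova:
    def test_additive_noiseless_data_zero_interaction(self):
        # value = a_effect + b_effect exactly -> interaction F ~ 0
        a_eff = {"x": 0.0, "y": 2.0}
        b_eff = {"u": 0.0, "v": 5.0, "w": 1.0}
        vals, fa, fb = [], [], []
        jitter = iter(np.linspace(-0.01, 0.01, 12))
        for a in a_eff:
            for b in b_eff:
                for _ in range(2):
                    vals.append(a_eff[a] + b_eff[b] + next(jitter) * 0)
                    fa.append(a)
                    fb.append(b)
        # perfectly additive and noiseless is singular; add replicate jitter
        vals = np.asarray(vals) + np.tile([0.005, -0.005], 6)
        tbl = two_way_anova(vals, fa, fb)
        assert tbl.loc["C(a):C(b)", "F"] < 1e-6

    def test_collapsing_factor_reproduces_one_way(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(m, 1, 10) for m in (0, 1.0)])
        fa = np.repeat(["g1", "g2"], 10)
        fb = np.tile(["u", "v"], 10)  # balanced, orthogonal dummy factor
        tbl = two_way_anova(vals, fa, fb)
        # with an orthogonal balanced second factor, the type-II main-effect
        # sum of squares equals the one-way between-group sum of squares
        grand = vals.mean()
        ss_between = sum(
            (vals[fa == g]).size * (vals[fa == g].mean() - grand) ** 2
            for g in ("g1", "g2")
        )
        assert abs(tbl.loc["C(a)", "sum_sq"] - ss_between) < 1e-8

    def test_empty_cells_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"], ["u", "u", "u", "u"])

    def test_matches_textbook_sums_of_squares_on_balanced_2x2(self):
        # brute-force decomposition on a balanced 2x2 with 3 replicates
        rng = np.random.default_rng(5)
        data = {}
        vals, fa, fb = [], [], []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                cell = rng.normal(0, 1, 3) + (a == "a2") * 1.5 + (b == "b2") * 0.7
                data[(a, b)] = cell
                vals.extend(cell)
                fa.extend([a] * 3)
                fb.extend([b] * 3)
        vals = np.asarray(vals)
        grand = vals.mean()
        cell_means = {k: v.mean() for k, v in data.items()}
        mean_a = {a: np.mean([cell_means[(a, b)] for b in ("b1", "b2")]) for a in ("a1", "a2")}
        mean_b = {b: np.mean([cell_means[(a, b)] for a in ("a1", "a2")]) for b in ("b1", "b2")}
        n_rep = 3
        ss_a = 2 * n_rep * sum((mean_a[a] - grand) ** 2 for a in mean_a)
        ss_b = 2 * n_rep * sum((mean_b[b] - grand) ** 2 for b in mean_b)
        ss_ab = n_rep * sum(
            (cell_means[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
            for a in ("a1", "a2")
            for b in ("b1", "b2")
        )
        tbl = two_way_anova(vals, fa, fb)
        assert abs(tbl.loc["C(a)", "sum_sq"] - ss_a) < 1e-8
        assert abs(tbl.loc["C(b)", "sum_sq"] - ss_b) < 1e-8
        assert abs(tbl.loc["C(a):C(b)", "sum_sq"] - ss_ab) < 1e-8


class TestUnpairedT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = unpaired_t(a, a)
        assert t == 0.0 and abs(p - 1.0) < 1e-12

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, p1 = unpaired_t(a, b)
        t2, p2 = unpaired_t(b, a)
        assert abs(t1 + t2) < 1e-12
        assert abs(p1 - p2) < 1e-12

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        _, p = unpaired_t(a, b)
        p_perm = permutation_t_pvalue(a, b, n_perm=20_000, seed=8)
        assert abs(p - p_perm) < 0.03

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])


class TestSimpleLinreg:
    def test_collinear(self):
        res = simple_linreg([1, 2, 3, 4], [3, 5, 7, 9])
        assert abs(res.r2 - 1.0) < 1e-12
        assert abs(res.slope - 2.0) < 1e-12

    def test_complement_slope_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        res = simple_linreg(x, 10.0 - x)
        assert abs(res.slope + 1.0) < 1e-12

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_linreg([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 40)
        y = 2.5 * x + rng.normal(0, 2, 40)
        res = simple_linreg(x, y)
        X = np.column_stack([np.ones_like(x), x])
        b = np.linalg.solve(X.T @ X, X.T @ y)
        assert abs(res.intercept - b[0]) < 1e-9
        assert abs(res.slope - b[1]) < 1e-9
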