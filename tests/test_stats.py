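"""Statistical primitives against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from netpolarity.stats import (
    ContingencyTable2x2,
    bh_fdr,
    binary_encode,
    exact_sign_test,
    fisher_2x2,
    kruskal_wallis,
    mann_whitney,
    partial_spearman,
    residualize,
    spearman,
)


class TestExactSignTest:
    def test_symmetry(self):
        for a, b in [(3, 9), (15, 10), (446, 352)]:
            assert exact_sign_test(a, b).p_value == pytest.approx(
                exact_sign_test(b, a).p_value)

    def test_balanced_counts_give_p_one(self):
        for k in (1, 5, 12):
            assert exact_sign_test(k, k).p_value == pytest.approx(1.0)

    def test_matches_binomial_enumeration_small_n(self):
        # independent oracle: sum all outcome probabilities not exceeding
        # the observed outcome's probability (two-sided, fair coin)
        for n in range(1, 13):
            for k in range(n + 1):
                probs = [math.comb(n, j) * 0.5 ** n for j in range(n + 1)]
                expected = sum(p for p in probs
                               if p <= probs[k] * (1 + 1e-12))
                got = exact_sign_test(k, n - k).p_value
                assert got == pytest.approx(expected, abs=1e-12)

    def test_p_decreases_with_asymmetry(self):
        total = 20
        ps = [exact_sign_test(k, total - k).p_value
              for k in range(total // 2, total + 1)]
        assert all(ps[i + 1] < ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_no_informative_pairs_errors(self):
        with pytest.raises(ValueError):
            exact_sign_test(0, 0)

    def test_large_n_continuity_corrected_normal(self):
        # above the exact-computation cutoff the implementation switches to
        # the continuity-corrected normal approximation
        res = exact_sign_test(450, 348)
        n = 798
        z = (abs(450 - n / 2) - 0.5) / math.sqrt(n / 4)
        assert res.p_value == pytest.approx(2 * sps.norm.sf(z))


class TestMannWhitney:
    def test_identical_samples_nonsignificant(self):
        vals = list(range(20))
        assert mann_whitney(vals, vals).p_value >= 0.99

    def test_separated_triples_hit_exact_minimum(self):
        # with groups of 3 and 3 there are C(6,3)=20 arrangements; full
        # separation is the single most extreme one in each direction
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(2 / 20)

    def test_asymptotic_close_to_exact_enumeration(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 8)
            p_exact = mann_whitney(a, b).p_value  # tie-free 8+8 -> exact
            p_asym = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_reports_group_summaries(self):
        res = mann_whitney([1, 2, 3, 4], [5, 6, 7])
        assert res.n == (4, 3)
        assert res.extras["median_a"] == 2.5
        assert res.extras["mean_b"] == 6.0

    def test_missing_values_removed(self):
        res = mann_whitney([1, 2, np.nan], [3, 4])
        assert res.n == (2, 2)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(0, 5, 20)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -x ** 3).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.5 * x
        y[3] = y[7]  # introduce a tie
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(oracle)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_no_controls_equals_spearman(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = partial_spearman(x, y)
        b = spearman(x, y)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_perfect_mediation_gives_near_zero(self, rng):
        # y is the control plus negligible noise: controlling for it must
        # wipe out an otherwise perfect correlation with x
        z = rng.normal(size=500)
        x = z + 0.1 * rng.normal(size=500)
        y = z + 0.1 * rng.normal(size=500)
        assert spearman(x, y).statistic > 0.95
        assert abs(partial_spearman(x, y, [z]).statistic) < 0.15

    def test_recovers_known_partial_correlation(self):
        rng = np.random.default_rng(42)
        n = 2000
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n)
        resid_sd = math.sqrt(1 - 0.25)
        y = 0.8 * z + 0.5 * (x - 0.8 * z) + resid_sd * rng.normal(size=n)
        est = partial_spearman(x, y, [z]).statistic
        assert abs(est - 0.5) < 0.05

    def test_matches_independent_partial_corr_routine(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        n = 150
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.5 * z + 0.3 * x + rng.normal(size=n)
        mine = partial_spearman(x, y, [z])
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z", method="spearman")
        assert mine.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert mine.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_collinear_controls_named(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="z_dup"):
            partial_spearman(x, y, [z, z], control_names=["z", "z_dup"])

    def test_independent_controls_barely_change_rho(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain = spearman(x, y).statistic
        partial = partial_spearman(x, y, [z]).statistic
        assert abs(plain - partial) < 0.05


class TestFisher:
    def test_reconstructed_extracellular_table(self):
        res = fisher_2x2(ContingencyTable2x2(48, 285, 26, 223))
        assert res.p_value == pytest.approx(0.168, abs=5e-4)

    def test_uniform_table_gives_p_one(self):
        assert fisher_2x2(ContingencyTable2x2(5, 5, 5, 5)).p_value == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                continue
            # enumerate all tables with the same margins
            r1, r2 = a + b, c + d
            c1 = a + c
            obs = sps.hypergeom.pmf(a, r1 + r2, r1, c1)
            total = 0.0
            for k in range(max(0, c1 - r2), min(r1, c1) + 1):
                pk = sps.hypergeom.pmf(k, r1 + r2, r1, c1)
                if pk <= obs * (1 + 1e-9):
                    total += pk
            got = fisher_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            assert got == pytest.approx(min(total, 1.0), abs=1e-9)

    def test_invariant_under_row_and_column_swap(self):
        t1 = fisher_2x2(ContingencyTable2x2(3, 8, 9, 2))
        t2 = fisher_2x2(ContingencyTable2x2(2, 9, 8, 3))
        assert t1.p_value == pytest.approx(t2.p_value)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_2x2(ContingencyTable2x2(0, 0, 3, 4))


class TestKruskalWallis:
    def test_two_groups_agrees_with_mann_whitney(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        p_kw = kruskal_wallis([a, b]).p_value
        p_mw = mann_whitney(a, b).p_value
        assert abs(p_kw - p_mw) < 0.02

    def test_identical_observations_give_zero_statistic(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_groups_detected(self, rng):
        groups = [rng.normal(mu, 1, 30) for mu in (-3, 0, 3)]
        assert kruskal_wallis(groups).p_value < 0.001

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_constant_mp_over_j(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_double_loop_definition(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1)
                          for j in range(rank_pos, m)]
            expected[idx] = min(1.0, min(candidates))
        assert np.allclose(q, expected)

    def test_order_preserving_and_idempotent(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        i, j = np.argsort(p)[:2]
        assert q[i] <= q[j] + 1e-15
        assert np.allclose(bh_fdr(q), bh_fdr(bh_fdr(q)))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestResidualize:
    def test_exact_linear_relation_gives_zero(self):
        x = np.arange(10, dtype=float)
        assert np.allclose(residualize(2 * x + 1, x), 0.0)

    def test_orthogonal_predictor_returns_centered_y(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.allclose(residualize(y, x), y - y.mean())

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(size=100)
        slope = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sum((x - x.mean()) ** 2))
        intercept = y.mean() - slope * x.mean()
        assert np.allclose(residualize(y, x), y - intercept - slope * x)

    def test_residual_mean_and_correlation_vanish(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200) + x
        r = residualize(y, x)
        assert abs(np.nanmean(r)) < 1e-10
        assert abs(np.corrcoef(r, x)[0, 1]) < 1e-10

    def test_missing_rows_propagate(self):
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        r = residualize(y, x)
        assert np.isnan(r[1]) and np.isnan(r[3])
        assert not np.isnan(r[[0, 2, 4]]).any()

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            residualize([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestBinaryEncode:
    def test_mapping(self):
        enc = binary_encode({"A": "upstream", "B": "downstream",
                             "C": "intermediate", "D": "isolated"})
        assert enc["A"] == 1.0 and enc["B"] == 0.0
        assert math.isnan(enc["C"]) and math.isnan(enc["D"])

    def test_spearman_on_binary_agrees_with_mann_whitney(self, rng):
        # rank correlation against a binary group code is the Mann-Whitney
        # test in disguise; p-values agree closely across random splits
        for _ in range(100):
            n1 = int(rng.integers(20, 150))
            n2 = int(rng.integers(20, 150))
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.normal(0, 0.5), 1, n2)
            p_mw = mann_whitney(a, b).p_value
            code = np.r_[np.ones(n1), np.zeros(n2)]
            p_sp = spearman(code, np.r_[a, b]).p_value
            assert abs(p_mw - p_sp) < 0.02
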