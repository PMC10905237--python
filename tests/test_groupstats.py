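"""Stratified CMH, clustered rank-sum, Welch t, and Krippendorff's alpha."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mpnull import groupstats as gs
from mpnull.records import assign_brood_size_cluster


def table_1(a, b, c, d):
    return gs.StratifiedTable((((a, b), (c, d)),))


class TestStratifiedBuild:
    def test_counts_partition_records(self, make_record):
        recs = [make_record(population_id=f"p{i}", mean_brood_size=1.5 + i,
                            prop_mp=0.2, mean_n_sires=1.25)
                for i in range(6)]
        t = gs.build_stratified_table(
            recs, group_by=lambda r: r.clade, outcome=lambda r: r.prop_mp == 0,
            groups=("bird", "mammal"),
        )
        assert t.total == 6
        counts = t.counts
        assert counts[:, 0, 1].sum() == 6  # all bird, all outcome "no"

    def test_order_invariance(self, make_record):
        recs = [make_record(population_id=f"p{i}", mean_brood_size=2 + i,
                            clade=("bird" if i % 2 else "mammal"))
                for i in range(8)]
        t1 = gs.build_stratified_table(recs, lambda r: r.clade,
                                       lambda r: r.prop_mp > 0)
        t2 = gs.build_stratified_table(recs[::-1], lambda r: r.clade,
                                       lambda r: r.prop_mp > 0)
        assert t1 == t2

    def test_undefined_group_excluded_with_warning(self, make_record):
        recs = [make_record(population_id="a"), make_record(population_id="b",
                                                            clade="mammal")]
        with pytest.warns(UserWarning, match="excluded"):
            t = gs.build_stratified_table(
                recs + [make_record(population_id="c")],
                lambda r: None if r.population_id == "c" else r.clade,
                lambda r: True,
            )
        assert t.total == 2


class TestMantelHaenszel:
    def test_single_stratum_is_odds_ratio(self):
        assert gs.mantel_haenszel_cor(table_1(10, 5, 2, 8)) == pytest.approx(8.0)

    def test_duplicating_strata_invariant(self):
        one = table_1(10, 5, 2, 8)
        two = gs.StratifiedTable((((10, 5), (2, 8)),) * 2)
        assert gs.mantel_haenszel_cor(two) == pytest.approx(
            gs.mantel_haenszel_cor(one))

    def test_homogeneous_odds_ratios_recovered(self):
        # strata with identical OR = 6 but different sizes
        t = gs.StratifiedTable((((6, 2), (1, 2)), ((12, 4), (2, 4))))
        assert gs.mantel_haenszel_cor(t) == pytest.approx(6.0)

    def test_matches_statsmodels_pooled_oddsratio(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for _ in range(5):
            counts = rng.integers(1, 30, size=(4, 2, 2))
            t = gs.StratifiedTable(tuple(map(tuple, (tuple(map(tuple, s))
                                                     for s in counts))))
            st = sm.StratifiedTable([np.asarray(c) for c in counts])
            assert gs.mantel_haenszel_cor(t) == pytest.approx(
                float(st.oddsratio_pooled), rel=1e-10)

    def test_zero_denominator_warns_inf(self):
        with pytest.warns(UserWarning):
            assert math.isinf(gs.mantel_haenszel_cor(table_1(3, 0, 0, 3)))


class TestStratumLOR:
    def test_plain_value(self):
        assert gs.stratum_lor(table_1(10, 5, 2, 8)) == [pytest.approx(math.log(8))]

    def test_zero_cell_continuity(self):
        (val,) = gs.stratum_lor(table_1(0, 5, 2, 8))
        assert math.isfinite(val)
        assert val == pytest.approx(math.log((0.5 * 8.5) / (5.5 * 2.5)))

    def test_row_swap_flips_sign(self):
        (fwd,) = gs.stratum_lor(table_1(10, 5, 2, 8))
        (rev,) = gs.stratum_lor(table_1(2, 8, 10, 5))
        assert rev == pytest.approx(-fwd)


class TestCMHPermutation:
    def test_exact_matches_hypergeometric_enumeration(self):
        a, b, c, d = 3, 2, 1, 4
        t = table_1(a, b, c, d)
        res = gs.cmh_permutation_test(t, mode="exact")
        # independent route: single-stratum conditional (hypergeometric) null
        # over |log odds ratio|, zero cells giving an infinitely extreme value
        n, row1, col1 = a + b + c + d, a + b, a + c
        obs = abs(math.log((a * d) / (b * c)))

        def stat(av):
            bv, cv, dv = row1 - av, col1 - av, n - row1 - col1 + av
            if av * dv == 0 or bv * cv == 0:
                return math.inf
            return abs(math.log((av * dv) / (bv * cv)))

        p = sum(
            stats.hypergeom.pmf(av, n, col1, row1)
            for av in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if stat(av) >= obs - 1e-12
        )
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_monte_carlo_agrees_with_exact(self):
        t = table_1(10, 5, 2, 8)
        exact = gs.cmh_permutation_test(t, mode="exact")
        mc = gs.cmh_permutation_test(t, mode="monte_carlo", n_perm=20000, seed=3)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_group_label_symmetry(self):
        t = gs.StratifiedTable((((7, 3), (2, 6)), ((4, 4), (5, 1))))
        swapped = gs.StratifiedTable((((2, 6), (7, 3)), ((5, 1), (4, 4))))
        p1 = gs.cmh_permutation_test(t, n_perm=4999, seed=9).p_value
        p2 = gs.cmh_permutation_test(swapped, n_perm=4999, seed=9).p_value
        assert p1 == pytest.approx(p2)

    def test_degenerate_margins_give_p_one(self):
        t = gs.StratifiedTable((((0, 0), (3, 4)),))
        with pytest.warns(UserWarning, match="degenerate"):
            assert gs.cmh_permutation_test(t).p_value == 1.0

    def test_type_one_error_under_simulated_null(self, rng):
        # same outcome probability in both groups, 6 strata
        reps, alpha = 400, 0.05
        rejections = 0
        for i in range(reps):
            counts = np.empty((6, 2, 2), dtype=int)
            for s in range(6):
                pa = rng.uniform(0.2, 0.6)
                na, nb = rng.integers(5, 20, size=2)
                ya = rng.binomial(na, pa)
                yb = rng.binomial(nb, pa)
                counts[s] = [[ya, na - ya], [yb, nb - yb]]
            t = gs.StratifiedTable(tuple(map(tuple, (tuple(map(tuple, s))
                                                     for s in counts))))
            res = gs.cmh_permutation_test(t, n_perm=399, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= alpha
        rate = rejections / reps
        # binomial 99.7% envelope around the nominal level
        assert rate < alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps) + 0.01


class TestClusteredRankSum:
    def test_identical_groups_give_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = gs.clustered_rank_sum_test(vals, list("AAABBB"), [1] * 6,
                                         n_perm=200, seed=1)
        assert res.w == pytest.approx(0.0)

    def test_single_cluster_matches_plain_permutation_wilcoxon(self, rng):
        vals = rng.normal(size=14)
        group = ["A"] * 7 + ["B"] * 7
        res = gs.clustered_rank_sum_test(vals, group, [1] * 14,
                                         n_perm=4000, seed=2)
        # independent oracle: permutation two-sample rank-sum via scipy
        ref = stats.permutation_test(
            (vals[:7], vals[7:]),
            lambda x, y: stats.rankdata(np.concatenate([x, y]))[: len(x)].sum(),
            permutation_type="independent", n_resamples=4000,
            alternative="two-sided", rng=2,
        )
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.04)

    def test_exhaustive_enumeration_small_case(self):
        vals = np.array([0.1, 0.9, 0.5, 0.3, 0.8, 0.2])
        group = np.array(["A", "B", "A", "B", "A", "B"])
        cluster = np.array([1, 1, 1, 2, 2, 2])
        res = gs.clustered_rank_sum_test(vals, group, cluster, n_perm=6000, seed=4)
        w_obs = abs(res.w)
        # enumerate all within-cluster label arrangements
        hits = total = 0
        for c1 in itertools.permutations([True, False, True]):
            for c2 in itertools.permutations([False, True, False]):
                perm = np.array(c1 + c2)
                w = gs._clustered_w(vals, perm, cluster)
                total += 1
                hits += abs(w) >= w_obs - 1e-12
        assert res.p_value == pytest.approx(hits / total, abs=0.05)

    def test_all_tied_values(self):
        res = gs.clustered_rank_sum_test([1.0] * 8, list("AABBAABB"),
                                         [1, 1, 1, 1, 2, 2, 2, 2],
                                         n_perm=100, seed=5)
        assert res.w == 0.0 and res.p_value == 1.0

    def test_type_one_error_under_simulated_null(self, rng):
        reps, alpha = 300, 0.05
        rejections = 0
        for _ in range(reps):
            vals = rng.normal(size=60)
            group = np.array(list("AB") * 30)
            cluster = np.repeat(np.arange(6), 10)
            res = gs.clustered_rank_sum_test(
                vals, group, cluster, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= alpha
        rate = rejections / reps
        assert rate < alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps) + 0.01


class TestWelch:
    def test_identical_samples(self):
        res = gs.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_unit_shift_closed_form(self):
        a = np.tile([1.0, -1.0], 500)  # mean 0, sample var ~1
        b = a + 1.0
        res = gs.welch_t(a, b)
        assert abs(res.t) == pytest.approx(1.0 / math.sqrt(2 * a.var(ddof=1) / 1000),
                                           rel=1e-12)
        assert abs(res.t) == pytest.approx(22.36, abs=0.05)

    def test_antisymmetry(self):
        a, b = [0.0, 1.0, 2.0], [3.0, 5.0, 7.0]
        assert gs.welch_t(a, b).t == pytest.approx(-gs.welch_t(b, a).t)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            gs.welch_t([1.0, 1.0], [1.0, 1.0])


class TestKrippendorff:
    def test_perfect_agreement(self):
        assert gs.krippendorff_alpha([[1, 1], [5, 5], [9, 9]]) == pytest.approx(1.0)

    def test_hand_enumerated_negative_case(self):
        # D_o = 1, D_e = 2/3 -> alpha = -0.5
        assert gs.krippendorff_alpha([[0, 1], [1, 0]]) == pytest.approx(-0.5)

    def test_affine_invariance_interval_metric(self, rng):
        m = rng.normal(size=(6, 3))
        a1 = gs.krippendorff_alpha(m)
        a2 = gs.krippendorff_alpha(3.0 * m - 7.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_missing_cells_ignored(self):
        m = [[1.0, 1.0, np.nan], [2.0, 2.1, np.nan], [np.nan, np.nan, 5.0]]
        # third unit has a single value: unpairable, dropped
        assert gs.krippendorff_alpha(m) == gs.krippendorff_alpha(
            [[1.0, 1.0], [2.0, 2.1]])

    def test_too_few_units_error(self):
        with pytest.raises(ValueError):
            gs.krippendorff_alpha([[1.0, 2.0]])

    def test_bootstrap_ci_deterministic_and_degenerate(self):
        m = [[1, 1], [5, 5], [9, 9]]
        r1 = gs.alpha_bootstrap_ci(m, n_boot=200, seed=7)
        r2 = gs.alpha_bootstrap_ci(m, n_boot=200, seed=7)
        assert r1.ci == r2.ci
        assert r1.ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) * 2
        res = gs.alpha_bootstrap_ci(m, n_boot=500, seed=8)
        assert res.ci[0] <= res.alpha <= res.ci[1]
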