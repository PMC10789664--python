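import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

from commrep.records import profile_individuals
from commrep.repertoires import Repertoire, build_repertoires
from commrep.similarity import (
    DiceMatrix,
    build_dice_matrix,
    dice_coefficient,
    exact_permutation_test,
    matrix_permutation_test,
    mean_dice_table,
    overlap_statistic,
)

labels = st.sets(st.sampled_from([f"t{i}" for i in range(12)]))


def make_matrix(values, settings):
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 1.0)
    n = len(settings)
    return DiceMatrix(
        individual_ids=tuple(f"i{k}" for k in range(n)),
        values=(values + values.T) / 2 if not np.allclose(values, values.T)
        else values,
        settings=tuple(settings),
    )


def random_matrix(rng, n, n_captive):
    v = rng.uniform(0, 1, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    settings = ["captive"] * n_captive + ["wild"] * (n - n_captive)
    return make_matrix(v, settings)


class TestDiceCoefficient:
    def test_identical_repertoires(self):
        assert dice_coefficient({"a", "b", "c"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_repertoires(self):
        assert dice_coefficient({"a", "b"}, {"c", "d"}) == 0.0

    def test_direct_formula_evaluation(self):
        # 2 * |{b, c}| / (3 + 3)
        assert dice_coefficient({"a", "b", "c"}, {"b", "c", "d"}) == (
            pytest.approx(2 / 3)
        )

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            dice_coefficient(set(), set())

    @given(a=labels, b=labels)
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        d = dice_coefficient(a, b)
        assert d == dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == (a == b and bool(a))
        assert (d == 0.0) == (not a & b)

    @given(a=labels, b=labels)
    def test_shared_type_never_decreases_similarity(self, a, b):
        if not a and not b:
            return
        d0 = dice_coefficient(a, b)
        shared = "new_shared"
        assert dice_coefficient(a | {shared}, b | {shared}) >= d0 - 1e-12

    @given(a=st.sets(st.sampled_from([f"t{i}" for i in range(12)]), min_size=1),
           b=labels)
    def test_private_type_never_increases_similarity(self, a, b):
        d0 = dice_coefficient(a, b)
        assert dice_coefficient(a | {"private"}, b) <= d0 + 1e-12


class TestDiceMatrix:
    def test_identical_repertoires_fill_matrix_with_ones(self):
        reps = [
            Repertoire(f"i{k}", "other", frozenset({"a", "b"}), 40)
            for k in range(3)
        ]
        m = build_dice_matrix(reps, {f"i{k}": "wild" for k in range(3)})
        off = m.values[~np.eye(3, dtype=bool)]
        assert (off == 1.0).all()

    def test_informative_entry_count(self):
        reps = [
            Repertoire(f"i{k}", "other", frozenset({f"t{k}", "shared"}), 40)
            for k in range(4)
        ]
        settings = {f"i{k}": ("wild" if k < 2 else "captive") for k in range(4)}
        m = build_dice_matrix(reps, settings)
        assert len(m.pair_table()) == 6

    def test_matrix_matches_elementwise_recomputation(self, small_dataset):
        records, _, _ = small_dataset
        profiles = profile_individuals(records)
        reps = [
            r for r in build_repertoires(records, profiles, "other")
            if {p.individual_id: p.species for p in profiles}[r.individual_id]
            == "bornean"
        ]
        settings = {p.individual_id: p.setting for p in profiles}
        m = build_dice_matrix(reps, settings)
        for i, j in itertools.combinations(range(len(reps)), 2):
            assert m.values[i, j] == pytest.approx(
                dice_coefficient(reps[i].signal_types, reps[j].signal_types)
            )

    def test_fewer_than_two_individuals_rejected(self):
        rep = Repertoire("i0", "other", frozenset({"a"}), 40)
        with pytest.raises(ValueError):
            build_dice_matrix([rep], {"i0": "wild"})

    def test_asymmetry_rejected(self):
        v = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DiceMatrix(("a", "b"), v, ("wild", "captive"))


class TestOverlapStatistic:
    def test_hand_set_within_between_contrast(self):
        v = np.full((4, 4), 0.5)
        v[0, 1] = v[1, 0] = 0.8  # wild-wild
        v[2, 3] = v[3, 2] = 0.8  # captive-captive
        m = make_matrix(v, ["wild", "wild", "captive", "captive"])
        assert overlap_statistic(m, "within_vs_between") == pytest.approx(0.3)

    def test_constant_matrix_gives_zero(self):
        m = make_matrix(np.full((4, 4), 0.6), ["wild", "wild", "captive",
                                               "captive"])
        assert overlap_statistic(m, "within_vs_between") == pytest.approx(0.0)
        assert overlap_statistic(
            m, "captive_within_vs_wild_within"
        ) == pytest.approx(0.0)

    def test_captive_vs_wild_contrast_hand_computed(self):
        v = np.full((4, 4), 0.1)
        v[0, 1] = v[1, 0] = 0.2   # wild-wild
        v[2, 3] = v[3, 2] = 0.9   # captive-captive
        m = make_matrix(v, ["wild", "wild", "captive", "captive"])
        assert overlap_statistic(
            m, "captive_within_vs_wild_within"
        ) == pytest.approx(0.7)

    def test_unknown_comparison_rejected(self):
        m = random_matrix(np.random.default_rng(0), 4, 2)
        with pytest.raises(ValueError, match="comparison"):
            overlap_statistic(m, "east_vs_west")


class TestPermutationTest:
    def test_extreme_separation_is_detected(self):
        # within pairs all 1, between pairs all 0: only the observed
        # labelling and its setting swap attain the maximum, so the exact
        # upper-tail p is 2 / C(8,4) = 1/35, and ties are counted.
        n = 8
        settings = ["wild"] * 4 + ["captive"] * 4
        v = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if settings[i] == settings[j]:
                v[i, j] = v[j, i] = 1.0
        m = make_matrix(v, settings)
        exact = exact_permutation_test(m, "within_vs_between")
        assert exact.p_value == pytest.approx(2 / comb(8, 4))
        mc = matrix_permutation_test(m, "within_vs_between", n_perm=1000,
                                     seed=5)
        assert mc.decision == "significant_high"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 1000)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 2 / 1001

    def test_same_seed_is_bit_identical(self):
        m = random_matrix(np.random.default_rng(3), 7, 3)
        a = matrix_permutation_test(m, "within_vs_between", 500, seed=11)
        b = matrix_permutation_test(m, "within_vs_between", 500, seed=11)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_stats, b.null_stats)

    def test_different_seeds_agree_within_binomial_error(self):
        m = random_matrix(np.random.default_rng(4), 8, 4)
        a = matrix_permutation_test(m, "within_vs_between", 2000, seed=1)
        b = matrix_permutation_test(m, "within_vs_between", 2000, seed=2)
        p = (a.p_value + b.p_value) / 2
        se = np.sqrt(2 * p * (1 - p) / 2000)
        assert abs(a.p_value - b.p_value) < 4 * se + 1e-3

    def test_null_distribution_centred_under_exchangeability(self):
        m = random_matrix(np.random.default_rng(5), 10, 5)
        r = matrix_permutation_test(m, "within_vs_between", 4000, seed=9)
        spread = r.null_stats.std()
        assert abs(r.null_stats.mean()) < 4 * spread / np.sqrt(4000) + 1e-3

    def test_degenerate_labels_rejected(self):
        v = np.full((4, 4), 0.5)
        m = make_matrix(v, ["wild"] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            matrix_permutation_test(m, "within_vs_between")

    def test_invalid_n_perm_rejected(self):
        m = random_matrix(np.random.default_rng(0), 4, 2)
        with pytest.raises(ValueError, match="n_perm"):
            matrix_permutation_test(m, "within_vs_between", n_perm=0)


class TestExactTest:
    def test_constant_matrix_all_ties(self):
        m = make_matrix(np.full((5, 5), 0.4),
                        ["wild", "wild", "captive", "captive", "captive"])
        r = exact_permutation_test(m, "within_vs_between")
        assert r.p_value == 1.0

    def test_two_plus_two_hand_enumeration(self):
        # distinct pair values; enumerate the 6 assignments by hand via
        # independent code below and compare
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 4, 2)
        r = exact_permutation_test(m, "within_vs_between")
        stats = []
        for captive_pair in itertools.combinations(range(4), 2):
            labs = np.array(
                ["captive" if k in captive_pair else "wild" for k in range(4)]
            )
            within = [
                m.values[i, j]
                for i, j in itertools.combinations(range(4), 2)
                if labs[i] == labs[j]
            ]
            between = [
                m.values[i, j]
                for i, j in itertools.combinations(range(4), 2)
                if labs[i] != labs[j]
            ]
            stats.append(np.mean(within) - np.mean(between))
        observed = stats[0]  # original labelling is captive = {0, 1}
        expected = np.mean([s >= observed - 1e-12 for s in stats])
        assert r.n_perm == 6
        assert r.p_value == pytest.approx(expected)

    def test_cap_on_assignment_count(self):
        m = random_matrix(np.random.default_rng(1), 8, 4)
        with pytest.raises(ValueError, match="cap"):
            exact_permutation_test(m, "within_vs_between", max_assignments=10)


class TestMeanDiceTable:
    def test_single_pair_per_category(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5    # wild-wild
        v[0, 2] = v[2, 0] = 0.25   # between
        v[1, 2] = v[2, 1] = 0.25   # between
        m = make_matrix(v, ["wild", "wild", "captive"])
        table = mean_dice_table({("bornean", "other"): m})
        col = table[("bornean", "other")]
        assert col["within_settings"] == pytest.approx(0.5)
        assert col["between_settings"] == pytest.approx(0.25)
        assert col["within_wild_only"] == pytest.approx(0.5)
        assert np.isnan(col["within_captive_only"])  # no captive pair

    def test_identical_repertoires_give_unit_means(self):
        m = make_matrix(np.ones((4, 4)), ["wild", "wild", "captive",
                                          "captive"])
        table = mean_dice_table({("sumatran", "mother"): m})
        assert (table[("sumatran", "mother")] == 1.0).all()

    def test_matches_brute_force_category_means(self, small_dataset):
        records, _, _ = small_dataset
        profiles = profile_individuals(records)
        settings = {p.individual_id: p.setting for p in profiles}
        species = {p.individual_id: p.species for p in profiles}
        reps = [
            r for r in build_repertoires(records, profiles, "other")
            if species[r.individual_id] == "bornean"
        ]
        m = build_dice_matrix(reps, settings)
        table = mean_dice_table({("bornean", "other"): m})
        pairs = m.pair_table()
        assert table[("bornean", "other")]["within_settings"] == (
            pytest.approx(pairs.loc[pairs["within"], "dice"].mean())
        )
        assert table[("bornean", "other")]["between_settings"] == (
            pytest.approx(pairs.loc[~pairs["within"], "dice"].mean())
        )
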