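import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_mine, random_instance
from runsit.geo_context import national_quantile_bins
from runsit.situation_miner import (
    FrequentItemset,
    WeightedFPTree,
    build_header,
    feature_variability,
    item_supports,
    mine,
    top_situations,
    value_histogram,
    weighted_support,
)


TD = [("A", "B"), ("A",)]
TW = np.array([0.5, -0.2])


class TestWeightedSupport:
    def test_direct_summation(self):
        assert weighted_support(["A"], TD, TW) == (pytest.approx(0.3), 2)
        assert weighted_support(["A", "B"], TD, TW) == (pytest.approx(0.5), 1)

    def test_absent_item(self):
        assert weighted_support(["Z"], TD, TW) == (0.0, 0)

    def test_empty_itemset_is_total(self):
        w, n = weighted_support([], TD, TW)
        assert w == pytest.approx(TW.sum())
        assert n == 2


class TestHeader:
    def test_ordering_and_pruning(self):
        td = [("a",)] * 9 + [("b",)] * 5 + [("c",)] * 1
        tw = np.array([0.1] * 9 + [-0.1] * 5 + [0.1])
        header = build_header(td, tw, sigma=0.3)
        assert list(header["item"]) == ["a", "b"]  # |0.9| then |-0.5|; c pruned
        assert build_header(td, tw, sigma=5.0).empty

    def test_name_tie_break(self):
        td = [("x",), ("y",)]
        tw = np.array([0.4, -0.4])
        header = build_header(td, tw, sigma=0.1)
        assert list(header["item"]) == ["x", "y"]

    def test_zero_weight_item_pruned_at_any_sigma(self):
        td = [("a", "z"), ("a",)]
        tw = np.array([0.0, 0.5])
        header = build_header(td, tw, sigma=1e-9)
        assert "z" not in set(header["item"])


class TestFPTree:
    def test_node_weights_sum_to_item_support(self):
        rng = np.random.default_rng(0)
        td, tw = random_instance(rng, n_items=8, n_tx=60)
        sup = item_supports(td, tw)
        rank = {item: i for i, item in enumerate(sorted(sup["item"]))}
        tree = WeightedFPTree(rank)
        for t, w in zip(td, tw):
            tree.insert(t, w)
        for _, row in sup.iterrows():
            w, c = tree.item_support(row["item"])
            assert w == pytest.approx(row["weight"])
            assert c == row["count"]

    def test_root_carries_no_item(self):
        tree = WeightedFPTree({"a": 0})
        tree.insert(("a",), 1.0)
        assert tree.root.item is None


class TestMine:
    def test_exhaustive_equals_brute_force_small_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            td, tw = random_instance(
                rng, n_items=int(rng.integers(4, 10)), n_tx=int(rng.integers(20, 120))
            )
            sigma = float(rng.uniform(0.3, 2.0))
            got = {s.items: (s.weight, s.count) for s in mine(td, tw, sigma, max_len=None)}
            expected = brute_force_mine(td, tw, sigma, max_len=None)
            assert set(got) == set(expected)
            for k in expected:
                assert got[k][0] == pytest.approx(expected[k][0])
                assert got[k][1] == expected[k][1]

    def test_max_len_cap(self):
        rng = np.random.default_rng(7)
        td, tw = random_instance(rng, n_items=6, n_tx=80)
        got = mine(td, tw, sigma=0.4, max_len=2)
        assert all(len(s.items) <= 2 for s in got)
        expected = brute_force_mine(td, tw, 0.4, max_len=2)
        assert {s.items for s in got} == set(expected)

    def test_pruned_subset_of_exhaustive(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            td, tw = random_instance(rng, n_items=8, n_tx=100)
            sigma = float(rng.uniform(0.3, 1.5))
            pruned = {s.items for s in mine(td, tw, sigma, mode="pruned", max_len=None)}
            exhaustive = {s.items for s in mine(td, tw, sigma, max_len=None)}
            assert pruned <= exhaustive

    def test_signed_supports_report_direction(self):
        td = [("Morning", "Sunday"), ("Morning", "Sunday"), ("Night", "Sunday")]
        tw = np.array([0.8, 0.7, -0.9])
        got = {frozenset(s.items): s for s in mine(td, tw, sigma=0.5, max_len=None)}
        assert got[frozenset({"Morning", "Sunday"})].weight == pytest.approx(1.5)
        assert got[frozenset({"Morning", "Sunday"})].sign == 1
        assert got[frozenset({"Night"})].weight == pytest.approx(-0.9)
        assert got[frozenset({"Night"})].sign == -1

    def test_huge_sigma_empty_and_bad_mode(self):
        assert mine(TD, TW, sigma=1e9) == []
        with pytest.raises(ValueError):
            mine(TD, TW, sigma=0.1, mode="quantum")
        with pytest.raises(ValueError):
            mine(TD, TW, sigma=-1.0)

    def test_subset_supports_consistent_with_direct_computation(self):
        rng = np.random.default_rng(9)
        td, tw = random_instance(rng, n_items=7, n_tx=90)
        for s in mine(td, tw, sigma=0.3, max_len=None)[:20]:
            for item in s.items:
                sub = s.items - {item}
                if sub:
                    w_direct, _ = weighted_support(sub, td, tw)
                    w_mined, _ = weighted_support(s.items, td, tw)
                    assert w_mined == pytest.approx(s.weight)


def tx_frame(rows):
    """Rows of (weekday, weight) as a minimal transaction table."""
    return pd.DataFrame(
        {"tid": range(len(rows)), "weight": [w for _, w in rows], "weekday": [d for d, _ in rows]}
    )


class TestVariability:
    def test_hand_computed_three_category_std(self):
        df = tx_frame([("Monday", 0.6), ("Tuesday", 0.0), ("Sunday", -0.6)])
        out = feature_variability(df)
        row = out[out["feature"] == "weekday"].iloc[0]
        assert row["std_weighted_support"] == pytest.approx(np.sqrt(0.24))
        assert row["n_categories"] == 3

    def test_zero_weights_give_zero_std(self):
        df = tx_frame([("Monday", 0.0), ("Sunday", 0.0)])
        assert (feature_variability(df)["std_weighted_support"] == 0).all()

    def test_equal_supports_give_zero_std(self):
        df = tx_frame([("Monday", 0.3), ("Sunday", 0.3)])
        assert feature_variability(df)["std_weighted_support"].iloc[0] == 0.0

    def test_normalized_variant_scales_by_n(self):
        df = tx_frame([("Monday", 0.6), ("Sunday", -0.6)])
        raw = feature_variability(df)["std_weighted_support"].iloc[0]
        norm = feature_variability(df, normalize=True)["std_weighted_support"].iloc[0]
        assert norm == pytest.approx(raw / 2)


class TestValueHistogram:
    def test_single_transaction_full_vocabulary(self):
        df = tx_frame([("Sunday", 0.4)])
        scheme = national_quantile_bins({})
        out = value_histogram(df, "weekday", scheme)
        assert len(out) == 7
        sun = out[out["category"] == "Sunday"].iloc[0]
        assert (sun["count"], sun["weighted_support"]) == (1, pytest.approx(0.4))
        others = out[out["category"] != "Sunday"]
        assert (others["count"] == 0).all() and (others["weighted_support"] == 0).all()

    def test_sums_match_totals(self):
        rng = np.random.default_rng(1)
        days = rng.choice(["Monday", "Saturday", "Sunday"], size=50)
        df = tx_frame(list(zip(days, rng.uniform(-1, 1, 50))))
        out = value_histogram(df, "weekday")
        assert out["count"].sum() == 50
        assert out["weighted_support"].sum() == pytest.approx(df["weight"].sum())

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            value_histogram(tx_frame([("Monday", 0.1)]), "astrology")


class TestTopSituations:
    def sets(self):
        return [
            FrequentItemset(frozenset({"weekday=Sunday", "hour=[09,12)"}), 5.0, 10),
            FrequentItemset(frozenset({"weekday=Tuesday"}), -4.0, 8),
            FrequentItemset(frozenset({"weekday=Sunday", "temperature=[6,14)"}), 6.0, 9),
            FrequentItemset(frozenset({"dist_parks=0"}), 3.0, 7),
        ]

    def test_temporal_filter_excludes_mixed_sets(self):
        pos, neg = top_situations(self.sets(), "temporal", k=5)
        assert list(pos["items"]) == ["hour=[09,12)|weekday=Sunday"]
        assert list(neg["items"]) == ["weekday=Tuesday"]

    def test_all_filter_ranks_by_abs_support(self):
        pos, _ = top_situations(self.sets(), "all", k=2)
        assert pos["weighted_support"].tolist() == [6.0, 5.0]

    def test_k_zero_and_bad_filter(self):
        pos, neg = top_situations(self.sets(), "all", k=0)
        assert pos.empty and neg.empty
        with pytest.raises(ValueError):
            top_situations(self.sets(), "astral")


def test_conservation_over_simulated_transactions(world, stack, bins):
    from runsit import make_runners, simulate_runs
    from runsit.preprocess import build_transactions, clean_runs, filter_sparse_users

    runs = simulate_runs(21, make_runners(21, 25), world, horizon_years=2)
    kept = filter_sparse_users(clean_runs(runs, stack)[0])
    tx = build_transactions(kept, stack, bins)
    total = tx["weight"].sum()
    var = feature_variability(tx)
    assert len(var) == 29
    for f in var["feature"]:
        hist = value_histogram(tx, f, bins)
        assert hist["count"].sum() == len(tx)
        assert hist["weighted_support"].sum() == pytest.approx(total, rel=1e-9, abs=1e-9)
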