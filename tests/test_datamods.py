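"""Data-set modification procedures: balancing, NN removal, partitioning."""

from collections import Counter

import numpy as np
import pytest

from potencybench.containers import ActivityClass, CompoundRecord
from potencybench.datamods import (
    AnalogSeries,
    BalanceConfig,
    analog_partition,
    balance_potency,
    extract_analog_series,
    nearest_neighbor_similarities,
    potency_bin,
    random_reduce,
    random_split,
    remove_nearest_neighbors,
)


def class_with_bins(counts, class_id="BINS"):
    """A class whose potencies realize the given six-bin occupancy."""
    records = []
    i = 0
    for b, n in enumerate(counts):
        for _ in range(n):
            records.append(CompoundRecord(f"{class_id}-{i:04d}", class_id, "CCO", 5.0 + b + 0.5))
            i += 1
    return ActivityClass(class_id, records)


def quota_round_robin_oracle(counts, target):
    """Independent brute-force re-implementation of the balancing rule."""
    n_bins = len(counts)
    take = [min(target // n_bins, c) for c in counts]
    while sum(take) < target:
        for b in range(n_bins):
            if sum(take) == target:
                break
            if take[b] < counts[b]:
                take[b] += 1
    return take


class TestBalancePotency:
    def test_single_bin_class_halved(self):
        cls = class_with_bins([100, 0, 0, 0, 0, 0])
        out = balance_potency(cls)
        assert len(out) == 50
        assert all(5.0 <= r.potency < 6.0 for r in out.records)
        assert out.provenance == "balanced"

    @pytest.mark.parametrize(
        "counts",
        [
            [20, 20, 20, 20, 20, 20],
            [60, 20, 10, 6, 3, 1],
            [90, 5, 2, 1, 1, 1],
            [37, 25, 18, 11, 6, 3],
        ],
    )
    def test_per_bin_counts_match_brute_force_oracle(self, counts):
        cls = class_with_bins(counts)
        target = round(0.5 * sum(counts))
        out = balance_potency(cls, BalanceConfig(seed=3))
        got = Counter(potency_bin(r.potency, BalanceConfig().bin_edges) for r in out.records)
        expected = quota_round_robin_oracle(counts, target)
        assert [got.get(b, 0) for b in range(6)] == expected
        assert len(out) == target

    def test_balancing_reduces_bin_count_spread(self):
        cls = class_with_bins([60, 20, 10, 6, 3, 1])
        out = balance_potency(cls, BalanceConfig(seed=0))
        edges = BalanceConfig().bin_edges
        orig = [60, 20, 10, 6, 3, 1]
        got = Counter(potency_bin(r.potency, edges) for r in out.records)
        new = [got.get(b, 0) for b in range(6)]
        assert np.std(new) <= np.std(orig)

    def test_seeded_selection_deterministic(self, small_class):
        a = balance_potency(small_class, BalanceConfig(seed=5))
        b = balance_potency(small_class, BalanceConfig(seed=5))
        assert a.compound_ids == b.compound_ids

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_with_bins([0, 0, 0, 0, 0, 0])

    def test_out_of_support_potency_rejected(self):
        cls = ActivityClass("X", [CompoundRecord("a", "X", "C", 4.2),
                                  CompoundRecord("b", "X", "C", 6.0)])
        with pytest.raises(ValueError):
            balance_potency(cls)


class TestRemoveNearestNeighbors:
    def test_fraction_zero_is_identity(self, tiny_class):
        out = remove_nearest_neighbors(tiny_class, 0.0)
        assert out.compound_ids == tiny_class.compound_ids

    def test_structural_duplicates_removed_first(self):
        records = [
            CompoundRecord("dupA", "X", "c1ccccc1CCNC(=O)C1CCCCC1", 6.0),
            CompoundRecord("dupB", "X", "O=C(NCCc1ccccc1)C1CCCCC1", 6.5),  # same molecule
            CompoundRecord("lone1", "X", "OCC(O)C(O)CO", 7.0),
            CompoundRecord("lone2", "X", "Clc1ccc(Br)nc1", 8.0),
        ]
        cls = ActivityClass("X", records)
        out = remove_nearest_neighbors(cls, 0.5)
        assert set(out.compound_ids) == {"lone1", "lone2"}

    def test_removed_have_higher_nn_similarity_than_kept(self, small_class):
        nn = nearest_neighbor_similarities(small_class)
        out = remove_nearest_neighbors(small_class, 0.5)
        kept = set(out.compound_ids)
        removed = set(small_class.compound_ids) - kept
        assert min(nn[c] for c in removed) >= max(nn[c] for c in kept)
        assert len(removed) == int(np.floor(0.5 * len(small_class)))

    def test_invalid_fraction_rejected(self, tiny_class):
        with pytest.raises(ValueError):
            remove_nearest_neighbors(tiny_class, 1.0)


class TestRandomReduce:
    def test_full_fraction_identity_up_to_order(self, tiny_class):
        out = random_reduce(tiny_class, 1.0, seed=0)
        assert set(out.compound_ids) == set(tiny_class.compound_ids)

    def test_half_fraction_size(self, small_class):
        assert len(random_reduce(small_class, 0.5, seed=1)) == 100

    def test_seeded_determinism(self, tiny_class):
        a = random_reduce(tiny_class, 0.5, seed=7)
        b = random_reduce(tiny_class, 0.5, seed=7)
        assert a.compound_ids == b.compound_ids


class TestExtractAnalogSeries:
    def test_recovers_ground_truth_partition(self, noise_free_class):
        truth = {}
        for r in noise_free_class.records:
            truth.setdefault(r.series_id, set()).add(r.compound_id)
        recovered = {frozenset(s.member_ids) for s in extract_analog_series(noise_free_class)}
        assert recovered == {frozenset(v) for v in truth.values()}

    def test_unrelated_singletons_give_no_series(self):
        smiles = ["c1ccccc1", "C1CC1", "C1CCC1", "C1CCCCCC1"]
        records = [CompoundRecord(f"s{i}", "X", s, 6.0) for i, s in enumerate(smiles)]
        assert extract_analog_series(ActivityClass("X", records)) == []

    def test_every_series_has_at_least_two_members(self, small_class):
        series = extract_analog_series(small_class)
        assert series and all(len(s.member_ids) >= 2 for s in series)

    def test_partition_is_disjoint(self, small_class):
        series = extract_analog_series(small_class)
        all_ids = [cid for s in series for cid in s.member_ids]
        assert len(all_ids) == len(set(all_ids))


class TestAnalogPartition:
    def series(self, sizes):
        out = []
        i = 0
        for k, n in enumerate(sizes):
            out.append(AnalogSeries(core=f"core{k}", member_ids=tuple(f"m{i+j}" for j in range(n))))
            i += n
        return out

    def test_exact_split_chosen_over_overshoot(self):
        plan = analog_partition(self.series([8, 2]), ratio=0.8, seed=0)
        assert len(plan.test_ids) == 2 and len(plan.train_ids) == 8

    def test_equal_series_fill_one_test_series(self):
        for seed in range(5):
            plan = analog_partition(self.series([2, 2, 2, 2, 2]), ratio=0.8, seed=seed)
            assert len(plan.test_ids) == 2

    def test_no_member_overlap(self):
        plan = analog_partition(self.series([4, 3, 3, 2]), ratio=0.8, seed=1)
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == {f"m{i}" for i in range(12)}

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            analog_partition(self.series([5]), ratio=0.8, seed=0)

    def test_core_sets_disjoint_by_construction(self, small_class):
        series = extract_analog_series(small_class)
        plan = analog_partition(series, ratio=0.8, seed=3)
        core_of = {cid: s.core for s in series for cid in s.member_ids}
        train_cores = {core_of[c] for c in plan.train_ids}
        test_cores = {core_of[c] for c in plan.test_ids}
        assert train_cores.isdisjoint(test_cores)


class TestRandomSplit:
    @pytest.mark.parametrize("n, ratio, n_train", [(500, 0.8, 400), (500, 0.5, 250)])
    def test_split_sizes(self, n, ratio, n_train):
        records = [CompoundRecord(f"c{i}", "X", "CCO", 6.0) for i in range(n)]
        plan = random_split(ActivityClass("X", records), ratio, seed=0)
        assert len(plan.train_ids) == n_train
        assert len(plan.test_ids) == n - n_train

    def test_trials_distinct_and_reproducible(self, tiny_class):
        plans = [random_split(tiny_class, 0.8, trial_index=t, seed=100 + t) for t in range(10)]
        assert len({plan.train_ids for plan in plans}) == 10
        again = [random_split(tiny_class, 0.8, trial_index=t, seed=100 + t) for t in range(10)]
        assert [p.train_ids for p in plans] == [p.train_ids for p in again]

    def test_degenerate_split_rejected(self):
        records = [CompoundRecord(f"c{i}", "X", "CCO", 6.0) for i in range(3)]
        with pytest.raises(ValueError):
            random_split(ActivityClass("X", records), 0.99, seed=0)
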