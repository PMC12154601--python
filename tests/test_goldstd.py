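"""Gold-standard labeling: size filter, grouping, 3:1 negatives, splits."""

import numpy as np
import pytest

from coelute.errors import ParameterError
from coelute.goldstd import (ComplexSet, filter_complex_size, group_complexes,
                             make_labels, negative_cap, read_complexes,
                             split_train_test, stratify_positives)
from coelute.pairs import all_pairs


def _cs(*member_lists):
    return ComplexSet({f"c{i}": frozenset(m)
                       for i, m in enumerate(member_lists)})


class TestSizeFilter:
    def test_boundary_complexes_of_exactly_30_members_kept(self):
        cs = _cs([f"a{i}" for i in range(3)],
                 [f"b{i}" for i in range(30)],
                 [f"c{i}" for i in range(31)])
        kept = filter_complex_size(cs, 30)
        assert sorted(len(m) for m in kept.complexes.values()) == [3, 30]

    def test_max_size_two_keeps_only_dimers(self):
        cs = _cs(["a", "b"], ["c", "d", "e"])
        kept = filter_complex_size(cs, 2)
        assert sorted(len(m) for m in kept.complexes.values()) == [2]

    def test_random_complexes_match_brute_force(self):
        rng = np.random.default_rng(0)
        members = [
            [f"p{j}" for j in rng.choice(400, size=rng.integers(2, 50),
                                         replace=False)]
            for _ in range(100)
        ]
        cs = _cs(*members)
        kept = filter_complex_size(cs, 30)
        expect = {n for n, m in cs.complexes.items() if len(m) <= 30}
        assert set(kept.complexes) == expect


class TestGrouping:
    def test_disjoint_complexes_get_distinct_groups(self):
        labels = group_complexes(_cs(["a", "b"], ["c", "d"]))
        assert len(set(labels.values())) == 2

    def test_shared_members_chain_transitively(self):
        labels = group_complexes(_cs(["a", "b"], ["b", "c"], ["c", "d"]))
        assert len(set(labels.values())) == 1

    def test_random_overlapping_family_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        members = [
            [f"p{j}" for j in rng.choice(40, size=rng.integers(2, 6),
                                         replace=False)]
            for _ in range(25)
        ]
        cs = _cs(*members)
        labels = group_complexes(cs)

        # independent union-find over complex indices
        parent = list(range(len(members)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        names = list(cs.complexes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if cs.complexes[a] & cs.complexes[b]:
                    parent[find(names.index(a))] = find(names.index(b))
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                same_oracle = find(i) == find(names.index(b))
                assert (labels[a] == labels[b]) == same_oracle


class TestLabels:
    def test_three_to_one_negative_cap(self):
        assert negative_cap(5, 40, 3) == 15
        assert negative_cap(5, 10, 3) == 10  # saturation

    def test_make_labels_counts_and_ratio(self):
        # two disjoint complexes with cross-complex negative candidates
        cs = _cs(["a", "b", "c"], ["d", "e"])
        observed = {"a", "b", "c", "d", "e"}
        gold = make_labels(cs, observed, neg_ratio=3, seed=0)
        assert len(gold.positives) == 4  # 3 + 1
        # 6 cross-complex candidates < 12 cap -> saturation
        assert len(gold.negatives) == 6

    def test_single_complex_has_no_negative_candidates(self):
        cs = _cs(["a", "b", "c"])
        gold = make_labels(cs, {"a", "b", "c"}, seed=0)
        assert gold.positives == {("a", "b"), ("a", "c"), ("b", "c")}
        assert gold.negatives == set()

    def test_negatives_respect_the_unfiltered_complex_set(self):
        """Members of a removed giant complex are never labeled negative
        with each other."""
        giant = [f"g{i}" for i in range(40)]
        cs_all = _cs(["a", "b"], ["c", "d"], giant + ["a", "c"])
        kept = filter_complex_size(cs_all, 30)
        observed = {"a", "b", "c", "d"}
        gold = make_labels(kept, observed, neg_ratio=10, seed=0,
                           exclude=cs_all)
        # a-c co-occur in the giant complex: excluded from negatives
        assert ("a", "c") not in gold.negatives
        assert gold.negatives <= {("a", "d"), ("b", "c"), ("b", "d")}

    def test_negative_sampling_reproducible(self):
        cs = _cs(["a", "b", "c"], ["d", "e"], ["f", "g"])
        obs = {"a", "b", "c", "d", "e", "f", "g"}
        g1 = make_labels(cs, obs, seed=5)
        g2 = make_labels(cs, obs, seed=5)
        assert g1.negatives == g2.negatives

    def test_zero_positives_errors(self):
        cs = _cs(["a", "b"])
        with pytest.raises(ParameterError):
            make_labels(cs, {"x", "y"}, seed=0)


class TestSplits:
    def _gold(self, n_groups=10, seed=0):
        rng = np.random.default_rng(seed)
        members = [[f"g{i}_p{j}" for j in range(rng.integers(3, 6))]
                   for i in range(n_groups)]
        cs = _cs(*members)
        obs = {m for ms in members for m in ms}
        return make_labels(cs, obs, seed=0)

    def test_no_group_spans_train_and_test(self):
        gold = split_train_test(self._gold(), train_frac=0.75, n_splits=5,
                                seed=1)
        for fold in range(5):
            roles = gold.fold_roles(fold)
            tab = gold.table
            tr_groups = set(tab.group[roles == "train"])
            te_groups = set(tab.group[roles == "test"])
            assert not (tr_groups & te_groups)
            assert not (set(zip(tab.id1[roles == "train"],
                                tab.id2[roles == "train"]))
                        & set(zip(tab.id1[roles == "test"],
                                  tab.id2[roles == "test"])))

    def test_train_fraction_near_target_across_seeds(self):
        fracs = []
        for seed in range(5):
            gold = split_train_test(self._gold(50, seed), train_frac=0.75,
                                    n_splits=5, seed=seed)
            for fold in range(5):
                roles = gold.fold_roles(fold)
                gtab = gold.table.groupby("group").size()
                tr_groups = set(gold.table.group[roles == "train"])
                fracs.append(gtab[list(tr_groups)].sum() / gtab.sum())
        assert abs(np.mean(fracs) - 0.75) < 0.1

    def test_fewer_than_two_groups_errors(self):
        cs = _cs(["a", "b", "c"])
        gold = make_labels(cs, {"a", "b", "c"}, seed=0)
        with pytest.raises(ParameterError):
            split_train_test(gold)

    def test_splits_deterministic_per_seed(self):
        g = self._gold()
        a = split_train_test(g, seed=3).table
        b = split_train_test(g, seed=3).table
        assert a.equals(b)


class TestStratification:
    def test_cap_applies_only_to_oversized_groups(self):
        big = [f"p{i}" for i in range(25)]  # C(25,2) = 300 positives
        cs = _cs(big, ["x", "y"], ["w", "z"])
        obs = set(big) | {"x", "y", "w", "z"}
        gold = make_labels(cs, obs, neg_ratio=3, seed=0)
        strat = stratify_positives(gold, per_group_cap=100, seed=0)
        pos_by_group = strat.table[strat.table.label == 1].groupby("group").size()
        assert pos_by_group.max() == 100
        assert (pos_by_group >= 1).all()

    def test_under_cap_is_identity(self):
        cs = _cs(["a", "b", "c"], ["d", "e"])
        gold = make_labels(cs, {"a", "b", "c", "d", "e"}, seed=0)
        strat = stratify_positives(gold, per_group_cap=100, seed=0)
        assert strat.positives == gold.positives

    def test_ratio_restored_when_candidates_suffice(self):
        big = [f"p{i}" for i in range(30)]
        others = [[f"q{i}a", f"q{i}b"] for i in range(20)]
        cs = _cs(big, *others)
        obs = set(big) | {m for ms in others for m in ms}
        gold = make_labels(cs, obs, neg_ratio=3, seed=0)
        strat = stratify_positives(gold, per_group_cap=50, seed=0)
        n_pos = len(strat.positives)
        assert len(strat.negatives) == 3 * n_pos


class TestComplexFile:
    def test_round_trip_with_auto_name_detection(self, tmp_path):
        p = tmp_path / "cpx.tsv"
        p.write_text("ribosome\tr1\tr2\tr3\nproteasome\tq1\tq2\n")
        cs = read_complexes(p)
        assert cs.complexes["ribosome"] == {"r1", "r2", "r3"}

    def test_nameless_file_autodetected(self, tmp_path):
        p = tmp_path / "cpx.tsv"
        # first fields reappear as members elsewhere -> no name column
        p.write_text("r1\tr2\tr3\nr3\tq2\n")
        cs = read_complexes(p)
        assert frozenset({"r1", "r2", "r3"}) in cs.complexes.values()
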