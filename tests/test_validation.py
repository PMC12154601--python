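"""External-evidence enrichment, seed propagation, AUROC, ontology mapping."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from coelute.errors import ParameterError, UndefinedResultError
from coelute.pairs import pair_key
from coelute.scoring import ScoredNetwork
from coelute.validation import (ExternalEvidence, auroc, bin_scores,
                                count_tested_pairs, cross_dataset_correlation,
                                enrichment_from_sets, enrichment_score,
                                evaluate_seed_set, propagate_annotations,
                                random_seed_null, seed_score)
from coelute.validation import tested_pair_count_bait_prey as bp_pair_count


def _net(edges):
    df = pd.DataFrame(edges, columns=["id1", "id2", "weight"])
    return ScoredNetwork(df, threshold=0.0)


def _pairs_series(d):
    idx = pd.MultiIndex.from_tuples(sorted(d), names=["id1", "id2"])
    return pd.Series([d[k] for k in sorted(d)], index=idx)


class TestTestedPairs:
    def test_all_by_all_counts_choose_two(self):
        ev = ExternalEvidence("all_by_all", frozenset(),
                              frozenset("abcd"))
        pairs, n = count_tested_pairs(ev)
        assert n == 6 and len(pairs) == 6

    def test_bait_prey_worked_example(self):
        ev = ExternalEvidence("bait_prey", frozenset(),
                              frozenset("abc"),
                              baits=frozenset("ab"), preys=frozenset("bc"))
        pairs, n = count_tested_pairs(ev)
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}
        assert n == 3 == 2 * 2 - 1 - 0

    def test_degenerate_single_shared_protein(self):
        assert bp_pair_count({"a"}, {"a"}) == 0

    def test_closed_form_equals_enumeration_on_random_sets(self):
        rng = np.random.default_rng(0)
        pool = [f"p{i}" for i in range(30)]
        for _ in range(200):
            b = set(rng.choice(pool, size=rng.integers(1, 21), replace=False))
            p = set(rng.choice(pool, size=rng.integers(1, 21), replace=False))
            brute = {pair_key(x, y) for x in b for y in p if x != y}
            assert bp_pair_count(b, p) == len(brute)


class TestBins:
    def test_decile_assignment_and_terminal_bin(self):
        s = _pairs_series({("a", "b"): 0.0, ("a", "c"): 0.95,
                           ("b", "c"): 1.0})
        bins = bin_scores(s)
        assert ("a", "b") in bins[0].members      # bin 1: [0.0, 0.1)
        assert ("a", "c") in bins[9].members      # bin 10: [0.9, 1.0)
        assert ("b", "c") in bins[10].members     # terminal [1.0, 1.0]
        assert bins[10].interval == "[1.0, 1.0]"

    def test_merged_top_scheme_closes_the_tenth_bin(self):
        s = _pairs_series({("a", "b"): 1.0})
        bins = bin_scores(s, scheme="merged_top")
        assert len(bins) == 10
        assert ("a", "b") in bins[9].members

    def test_bins_partition_all_scores(self):
        rng = np.random.default_rng(1)
        keys = [(f"x{i}", f"y{i}") for i in range(1000)]
        s = _pairs_series(dict(zip(keys, rng.random(1000))))
        bins = bin_scores(s)
        counts = [len(b.members) for b in bins]
        assert sum(counts) == 1000
        seen = set()
        for b in bins:
            assert not (b.members & seen)
            seen |= b.members

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ParameterError):
            bin_scores(_pairs_series({("a", "b"): 1.2}))


class TestEnrichment:
    def test_worked_set_arithmetic_example(self):
        res = enrichment_from_sets(
            cfms_pos={("a", "b"), ("a", "c")},
            cfms_all={("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")},
            e_pos={("a", "b"), ("b", "c")},
            e_neg={("a", "c"), ("a", "d")},
        )
        assert res.a == pytest.approx(0.5)
        assert res.b == pytest.approx(0.5)
        assert res.enrichment == pytest.approx(1.0)
        assert res.flag == "ok"

    def test_perfect_agreement_flags_infinite(self):
        res = enrichment_from_sets(
            cfms_pos={("a", "b")},
            cfms_all={("a", "b"), ("a", "c")},
            e_pos={("a", "b")},
            e_neg={("a", "c")},
        )
        assert res.flag == "infinite"

    def test_no_external_positive_overlap_flags_undefined(self):
        res = enrichment_from_sets(
            cfms_pos={("a", "b")}, cfms_all={("a", "b")},
            e_pos=set(), e_neg={("a", "b")},
        )
        assert res.flag == "undefined"

    def test_full_recipe_restricts_universe_to_shared_proteins(self):
        ev = ExternalEvidence(
            "all_by_all",
            positives=frozenset({pair_key("a", "b")}),
            universe=frozenset({"a", "b", "zzz"}),
        )
        res = enrichment_score({("a", "b"), ("c", "d")}, ev)
        # zzz is outside the bin's proteins; c,d outside the assay
        assert res.e_single_cfms == {"a", "b"}
        assert res.e_all == {("a", "b")}

    def test_independent_evidence_centers_near_one(self):
        """Random external assignment over the same universe gives median
        enrichment ~ 1."""
        rng = np.random.default_rng(2)
        proteins = [f"p{i}" for i in range(24)]
        universe_pairs = sorted(pair_key(a, b)
                                for a, b in combinations(proteins, 2))
        bin_pairs = set(map(tuple, rng.choice(
            universe_pairs, size=60, replace=False)))
        vals = []
        for _ in range(500):
            pos = set(map(tuple, rng.choice(
                universe_pairs, size=90, replace=False)))
            ev = ExternalEvidence("all_by_all", frozenset(pos),
                                  frozenset(proteins))
            res = enrichment_score(bin_pairs, ev)
            if res.flag == "ok":
                vals.append(res.enrichment)
        med = float(np.median(vals))
        assert 0.8 <= med <= 1.25

    def test_empty_bin_errors(self):
        ev = ExternalEvidence("all_by_all", frozenset(), frozenset("ab"))
        with pytest.raises(ParameterError):
            enrichment_score(set(), ev)


class TestSeedScore:
    def test_star_graph_by_formula(self):
        net = _net([("hub", f"leaf{i}", 0.7) for i in range(5)])
        s = seed_score(net, {"hub"})
        assert s["hub"] == 0.0  # no self-link
        assert all(s[f"leaf{i}"] == pytest.approx(0.7) for i in range(5))

    def test_seed_disconnected_from_rest_scores_zero(self):
        net = _net([("a", "b", 0.5), ("c", "d", 0.9)])
        s = seed_score(net, {"a", "b"})
        assert s["c"] == s["d"] == 0.0
        assert s["a"] == s["b"] == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if rng.random() < 0.4:
                    edges.append((u, v, float(rng.uniform(0.1, 1.0))))
        net = _net(edges)
        w = {}
        for u, v, wt in edges:
            w[(u, v)] = w[(v, u)] = wt
        seeds = {"n1", "n4", "n7"}
        s = seed_score(net, seeds)
        for i in net.node_index:
            brute = sum(w.get((i, j), 0.0) for j in seeds if j != i)
            assert s[i] == pytest.approx(brute)

    def test_linearity_over_disjoint_seed_sets(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(10)]
        edges = [(u, v, float(rng.uniform(0.1, 1.0)))
                 for i, u in enumerate(nodes) for v in nodes[i + 1:]
                 if rng.random() < 0.5]
        net = _net(edges)
        s1, s2 = {"n0", "n1"}, {"n5", "n6"}
        combined = seed_score(net, s1 | s2)
        split = seed_score(net, s1) + seed_score(net, s2)
        assert np.allclose(combined.to_numpy(), split.to_numpy())

    def test_missing_seed_policy(self):
        net = _net([("a", "b", 0.5)])
        with pytest.raises(ParameterError):
            seed_score(net, {"a", "zzz"})
        s = seed_score(net, {"a", "zzz"}, missing="drop")
        assert s["b"] == pytest.approx(0.5)


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc(np.array([3.0, 2.0, 1.0]),
                     np.array([True, True, False])) == 1.0

    def test_rank_sum_derived_value(self):
        # positive {2} vs negatives {1, 3}: 1 concordant of 2
        assert auroc(np.array([2.0, 1.0, 3.0]),
                     np.array([True, False, False])) == pytest.approx(0.5)

    def test_equivalent_to_normalized_rank_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = rng.choice(10, size=n).astype(float)  # many ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            u = mannwhitneyu(scores[labels], scores[~labels]).statistic
            expect = u / (labels.sum() * (~labels).sum())
            assert auroc(scores, labels) == pytest.approx(expect)

    def test_label_shuffle_centers_on_half(self):
        rng = np.random.default_rng(6)
        scores = rng.random(60)
        vals = []
        for _ in range(1000):
            labels = np.zeros(60, dtype=bool)
            labels[rng.choice(60, size=15, replace=False)] = True
            vals.append(auroc(scores, labels))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(ParameterError):
            auroc(np.array([1.0, 2.0]), np.array([True, True]))


class TestSeedEvaluationAndNull:
    def test_minimum_annotation_size_enforced(self):
        net = _net([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5),
                    ("d", "e", 0.5), ("e", "f", 0.5)])
        with pytest.raises(ParameterError):
            evaluate_seed_set(net, {"a", "b"}, min_annotation_size=5)
        res = evaluate_seed_set(net, {"a", "b", "c", "d", "e"},
                                min_annotation_size=5)
        assert 0 <= res.auroc <= 1

    def test_null_reproducible_for_fixed_seed(self, null_network):
        _, net = null_network
        a = random_seed_null(net, 10, n_reps=3, seed=9)
        b = random_seed_null(net, 10, n_reps=3, seed=9)
        assert np.array_equal(a, b)

    def test_oversized_seed_set_errors(self):
        net = _net([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5),
                    ("a", "c", 0.5), ("a", "d", 0.5)])
        with pytest.raises(ParameterError):
            random_seed_null(net, 10, n_reps=1, min_annotation_size=1)


class TestCrossDataset:
    def test_planted_pairs_outcorrelate_random_in_second_species(
            self, default_truth, default_params, default_experiments):
        """Co-complex pairs measured in one species stay correlated in a
        different species' experiment from the same truth."""
        other = default_experiments["sp2"][0]
        pairs = default_truth.cocomplex_pairs()
        res = cross_dataset_correlation(pairs, other, n_random=300, seed=0)
        assert res.median_observed > res.median_random
        assert res.p_value < 1e-3

    def test_no_random_draws_returns_observed_only(self, default_truth,
                                                   default_experiments):
        other = default_experiments["sp1"][0]
        res = cross_dataset_correlation(default_truth.cocomplex_pairs(),
                                        other, n_random=0, seed=0)
        assert res.random_r.size == 0 and res.p_value is None

    def test_unmappable_pairs_error(self, default_experiments):
        with pytest.raises(ParameterError):
            cross_dataset_correlation({("zz1", "zz2")},
                                      default_experiments["sp1"][0],
                                      n_random=1, seed=0)


class TestOntologyMapping:
    def test_child_identical_to_parent_is_removed(self):
        terms = {"parent": {"a", "b"}, "child": set()}
        mapping = propagate_annotations(terms, [("child", "parent")])
        assert "parent" in mapping.term_to_ogs
        assert "child" in mapping.removed
        # inheritance happened before dedup
        assert mapping.term_to_ogs["parent"] == {"a", "b"}

    def test_jaccard_flagging_at_threshold(self):
        terms = {"t": {"a", "b"}}
        mapping = propagate_annotations(terms, [],
                                        training_complexes=[{"b", "c"}])
        assert mapping.max_jaccard["t"] == pytest.approx(1 / 3)
        assert mapping.high_overlap["t"] is False

    def test_identical_siblings_under_kept_ancestor_removed(self):
        terms = {"root": {"a"}, "s1": {"b"}, "s2": {"b"}}
        edges = [("s1", "root"), ("s2", "root")]
        mapping = propagate_annotations(terms, edges)
        # s1, s2 both become {a, b}: identical, sharing kept ancestor root
        assert {"s1", "s2"} <= mapping.removed
        assert "root" in mapping.term_to_ogs

    def test_cycle_detection(self):
        with pytest.raises(ParameterError):
            propagate_annotations({"a": set(), "b": set()},
                                  [("a", "b"), ("b", "a")])

    def test_conventional_direction_mode(self):
        terms = {"parent": set(), "child": {"x"}}
        mapping = propagate_annotations(terms, [("child", "parent")],
                                        direction="child_to_ancestor")
        assert mapping.term_to_ogs.get("parent", None) == {"x"} or \
            "parent" in mapping.removed

    def test_random_dag_matches_brute_force_dedup_oracle(self):
        rng = np.random.default_rng(8)
        names = [f"T{i}" for i in range(20)]
        edges = []
        for i in range(1, 20):
            for parent in rng.choice(i, size=min(i, 2), replace=False):
                edges.append((names[i], names[int(parent)]))
        pool = [f"og{i}" for i in range(15)]
        terms = {n: set(rng.choice(pool, size=rng.integers(0, 4),
                                   replace=False)) for n in names}
        mapping = propagate_annotations(terms, edges)

        # brute force: transitive inheritance + the two dedup rules
        g = nx.DiGraph(edges)
        g.add_nodes_from(names)
        anc = {t: nx.descendants(g, t) for t in names}
        full = {t: set(terms[t]) | set().union(
            *(terms[a] for a in anc[t]), set()) for t in names}
        removed = set()
        for t in names:
            if any(full[t] == full[a] for a in anc[t]):
                removed.add(t)
        groups = {}
        for t in names:
            if t not in removed:
                groups.setdefault(frozenset(full[t]), []).append(t)
        for grp in groups.values():
            if len(grp) < 2:
                continue
            common = set.intersection(*(anc[t] for t in grp))
            if any(a not in removed for a in common):
                removed.update(grp)
        assert mapping.removed == removed
        for t in names:
            if t not in removed:
                assert set(mapping.term_to_ogs[t]) == full[t]
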