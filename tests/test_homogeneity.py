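"""Similarity metrics, permutation nulls and cluster-vs-null testing."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combinet.homogeneity import (
    Fingerprint,
    compare_distributions,
    dice_similarity,
    harmonic_similarity,
    jaccard_distance,
    mutation_profile,
    pairwise_set_intersections,
    pathway_intersections,
    random_grouping_null,
    secondary_targets,
)


def fp(bits):
    return Fingerprint(bits=np.array(bits, dtype=bool))


class TestDice:
    def test_identical_is_one(self):
        f = fp([1, 0, 1, 1, 0])
        assert dice_similarity(f, f) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert dice_similarity(fp([1, 1, 0, 0]), fp([0, 0, 1, 1])) == 0.0

    def test_hand_computed(self):
        # a = 4 ON, b = 6 ON, c = 2 shared → 2·2/(4+6) = 0.4
        a = fp([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        b = fp([1, 1, 0, 0, 1, 1, 1, 1, 0, 0])
        assert dice_similarity(a, b) == pytest.approx(0.4)

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            assert dice_similarity(fp([0, 0]), fp([0, 0])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dice_similarity(fp([1, 0]), fp([1, 0, 1]))

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = fp(rng.integers(0, 2, 64)), fp(rng.integers(0, 2, 64))
        d1, d2 = dice_similarity(a, b), dice_similarity(b, a)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


class TestSetIntersections:
    def test_examples(self):
        groups = {"A": {"p1", "p2"}, "B": {"p2", "p3"}, "C": {"x", "y", "z"}}
        got = pairwise_set_intersections(groups, [("A", "B"), ("C", "C"), ("A", "C")])
        assert got[("A", "B")] == 1
        assert got[("C", "C")] == 3
        assert got[("A", "C")] == 0

    def test_unknown_drug_skipped(self):
        with pytest.warns(UserWarning):
            got = pairwise_set_intersections({"A": {"p"}}, [("A", "ZZZ")])
        assert got == {}


class TestSecondaryTargets:
    def test_two_hop_chain(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "d")])
        assert secondary_targets({"a"}, g) == {"a", "b", "c"}

    def test_isolated_target_kept(self):
        g = nx.DiGraph([("x", "y")])
        assert secondary_targets({"zzz"}, g) == {"zzz"}

    def test_directionality_respected(self):
        g = nx.DiGraph([("s", "l1"), ("s", "l2"), ("s", "l3")])
        assert secondary_targets({"l1"}, g) == {"l1"}  # leaves have no out-edges
        assert secondary_targets({"s"}, g) == {"s", "l1", "l2", "l3"}


class TestPathwayIntersections:
    def test_shared_and_disjoint_profiles(self):
        pathways = {"P1": {"g1", "g2"}, "P2": {"g3"}, "P3": {"g4"}, "P4": {"g5"}}
        targets = {
            "A": {"g1", "g3", "g4"},   # profile {P1, P2, P3}
            "B": {"g2", "g3", "g5"},   # profile {P1, P2, P4}
            "C": {"g9"},               # profile ∅
        }
        got = pathway_intersections(targets, pathways, [("A", "B"), ("A", "C")])
        assert got[("A", "B")] == 2
        assert got[("A", "C")] == 0


class TestExpressionMetrics:
    def test_harmonic_self_reduces_to_sum(self):
        P = np.array([1.0, 2.0, 3.0])
        assert harmonic_similarity(P, P) == pytest.approx(P.sum())

    def test_harmonic_hand_computed(self):
        assert harmonic_similarity([1.0, 1.0], [1.0, 3.0]) == pytest.approx(2.5)

    def test_harmonic_orthogonal_support(self):
        assert harmonic_similarity([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_harmonic_zero_sum_genes_dropped(self):
        with pytest.warns(UserWarning):
            v = harmonic_similarity([1.0, -2.0], [1.0, 2.0])
        assert v == pytest.approx(1.0)

    def test_jaccard_self_distance_forms(self):
        P = np.array([1.0, 2.0])
        assert jaccard_distance(P, P, form="standard") == pytest.approx(0.0)
        assert jaccard_distance(P, P, form="as_printed") == pytest.approx(2 / 3)

    def test_jaccard_orthogonal_is_one(self):
        P, Q = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert jaccard_distance(P, Q, "standard") == pytest.approx(1.0)
        assert jaccard_distance(P, Q, "as_printed") == pytest.approx(1.0)

    def test_jaccard_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        P, Q = rng.random(20), rng.random(20)
        pq, pp, qq = (P * Q).sum(), (P * P).sum(), (Q * Q).sum()
        assert jaccard_distance(P, Q, "standard") == pytest.approx(1 - pq / (pp + qq - pq))
        assert jaccard_distance(P, Q, "as_printed") == pytest.approx(1 - pq / (pp + qq + pq))

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = rng.normal(size=15), rng.normal(size=15)
        assert jaccard_distance(P, Q) == pytest.approx(jaccard_distance(Q, P))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert harmonic_similarity(P, Q) == pytest.approx(harmonic_similarity(Q, P))


class TestRandomGroupingNull:
    def test_constant_metric_degenerate(self):
        null = random_grouping_null(list("abcdef"), lambda a, b: 7.0,
                                    [3, 3], n_perm=100, seed=1)
        assert np.all(null == 7.0)
        assert len(null) == 100 * (3 + 3)

    def test_zero_permutations_error(self):
        with pytest.raises(ValueError):
            random_grouping_null(list("abcd"), lambda a, b: 0.0, [2, 2], n_perm=0, seed=1)

    def test_seed_reproducible(self):
        rng_metric = {(a, b): hash((a, b)) % 10 for a in "abcdef" for b in "abcdef"}
        fn = lambda a, b: float(rng_metric[(a, b)])
        n1 = random_grouping_null(list("abcdef"), fn, [3, 3], n_perm=150, seed=42)
        n2 = random_grouping_null(list("abcdef"), fn, [3, 3], n_perm=150, seed=42)
        assert np.array_equal(n1, n2)
        n3 = random_grouping_null(list("abcdef"), fn, [3, 3], n_perm=150, seed=43)
        assert not np.array_equal(n1, n3)

    def test_planted_fingerprints_beat_null(self, small_annotations, small_spec):
        from combinet.homogeneity import dice_similarity
        from combinet.synthetic import cluster_labels

        fps = small_annotations.fingerprints
        dclu, _ = cluster_labels(small_spec)
        clusters = {c: list(dclu[dclu == c].index) for c in dclu.unique()}
        within = [
            dice_similarity(fps[a], fps[b])
            for ms in clusters.values()
            for i, a in enumerate(ms) for b in ms[i + 1:]
        ]
        null = random_grouping_null(
            list(fps), lambda a, b: dice_similarity(fps[a], fps[b]),
            [len(v) for v in clusters.values()], n_perm=100, seed=5,
        )
        assert np.median(within) > np.median(null)


class TestCompareDistributions:
    def test_identical_distributions_nonsignificant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        report = compare_distributions({0: vals[:100]}, vals[100:])
        assert report.kruskal_p_adjusted > 0.01

    def test_strong_shift_significant(self):
        rng = np.random.default_rng(1)
        null = rng.normal(0, 1, 100)
        within = {0: rng.normal(10, 1, 100)}
        report = compare_distributions(within, null)
        assert report.kruskal_p_adjusted < 1e-6
        assert report.pairwise_wilcoxon["p_adjusted"].iloc[0] < 1e-6

    def test_only_shifted_cluster_significant(self):
        rng = np.random.default_rng(2)
        null = rng.normal(0, 1, 200)
        within = {0: rng.normal(5, 1, 80), 1: rng.normal(0, 1, 80)}
        report = compare_distributions(within, null)
        pw = report.pairwise_wilcoxon.set_index("cluster")
        assert pw.loc[0, "p_adjusted"] < 1e-6
        assert pw.loc[1, "p_adjusted"] > 0.01

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            report = compare_distributions({0: [1.0] * 5}, [1.0] * 5)
        assert report.kruskal_p_adjusted == 1.0
        assert report.tie_warning

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            compare_distributions({0: [1.0, 2.0]}, [1.0, 2.0, 3.0])


class TestMutationProfile:
    def test_planted_frequency(self):
        rows = [{"sample_id": f"s{i}", "gene": "NPM1", "damage_probability": 0.9}
                for i in range(38)]
        rows += [{"sample_id": "s0", "gene": "TP53", "damage_probability": 0.7}]
        muts = pd.DataFrame(rows)
        partition = {f"s{i}": 0 for i in range(100)}
        prof = mutation_profile(muts, partition)
        npm1 = prof[(prof.cluster == 0) & (prof.gene == "NPM1")].iloc[0]
        assert npm1.frequency == pytest.approx(0.38)
        assert npm1["rank"] == 1.0

    def test_boundary_probability_excluded(self):
        muts = pd.DataFrame([
            {"sample_id": "s0", "gene": "G1", "damage_probability": 0.5},
            {"sample_id": "s0", "gene": "G2", "damage_probability": 0.51},
        ])
        prof = mutation_profile(muts, {"s0": 0, "s1": 0})
        assert set(prof.gene) == {"G2"}

    def test_gene_absent_from_cluster_ranks_last(self):
        muts = pd.DataFrame([
            {"sample_id": "a0", "gene": "G1", "damage_probability": 0.9},
            {"sample_id": "a0", "gene": "G2", "damage_probability": 0.9},
            {"sample_id": "b0", "gene": "G2", "damage_probability": 0.9},
        ])
        prof = mutation_profile(muts, {"a0": 0, "b0": 1})
        c1 = prof[prof.cluster == 1].set_index("gene")
        assert c1.loc["G1", "frequency"] == 0.0
        assert c1.loc["G1", "rank"] == c1["rank"].max()
        # rank shift of G1 between clusters is reported
        assert c1.loc["G1", "rank_shift"] == pytest.approx(1.0)
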