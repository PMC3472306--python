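"""Cluster matching, attribute selection, class mapping, conservation tests."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import random_dna
from tfbslens.containers import SequenceRecord
from tfbslens.correspondence import (
    bootstrap_select_attributes,
    cluster_sequences,
    conservation_correspondence,
    encode_and_map,
    encoding_attributes,
    intersection_rate,
    sequences_link,
    tf_conservation_score,
    tf_mean_vectors,
    tfbs_conservation_score,
    transform_and_match,
    attribute_frequency,
)
from tfbslens.features import MotifCatalog
from tfbslens.models import TrainedModel


def mutate(seq, rate, rng):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = "ACGT"["ACGT".index(out[i]) - rng.integers(1, 4)]
    return "".join(out)


class TestClusterSequences:
    def test_identical_pair_single_cluster(self):
        recs = [SequenceRecord("a", "ACGTACGTACGT"), SequenceRecord("b", "ACGTACGTACGT")]
        assert cluster_sequences(recs, 0.9, 90) == [{"a", "b"}]

    def test_dissimilar_pair_two_singletons(self):
        recs = [SequenceRecord("a", "A" * 20), SequenceRecord("b", "C" * 20)]
        assert cluster_sequences(recs, 0.9, 90) == [{"a"}, {"b"}]

    def test_two_mutated_families_recovered(self, rng):
        base1, base2 = random_dna(60, rng), random_dna(60, rng)
        recs = [
            SequenceRecord("f1_0", base1),
            SequenceRecord("f1_1", mutate(base1, 0.05, rng)),
            SequenceRecord("f1_2", mutate(base1, 0.05, rng)),
            SequenceRecord("f2_0", base2),
            SequenceRecord("f2_1", mutate(base2, 0.05, rng)),
            SequenceRecord("f2_2", mutate(base2, 0.05, rng)),
        ]
        clusters = cluster_sequences(recs, 0.9, 90)
        assert sorted(clusters, key=min) == [
            {"f1_0", "f1_1", "f1_2"},
            {"f2_0", "f2_1", "f2_2"},
        ]

    def test_agrees_with_brute_force_components(self, rng):
        recs = [SequenceRecord(f"s{i}", random_dna(20, rng)) for i in range(12)]
        # seed a couple of near-duplicates so some links exist
        recs[5] = SequenceRecord("s5", mutate(recs[0].sequence, 0.1, rng))
        recs[7] = SequenceRecord("s7", mutate(recs[1].sequence, 0.05, rng))
        clusters = cluster_sequences(recs, 0.8, 70)
        # independent oracle: adjacency from the pair predicate + BFS
        n = len(recs)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if sequences_link(recs[i].sequence, recs[j].sequence, 0.8, 70, "dna"):
                    adj[i].add(j)
                    adj[j].add(i)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            comps.append({recs[v].id for v in comp})
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, comps))

    def test_parameter_validation(self):
        recs = [SequenceRecord("a", "ACGT")]
        with pytest.raises(ValueError):
            cluster_sequences(recs, 0.0, 90)
        with pytest.raises(ValueError):
            cluster_sequences(recs, 0.9, 0)
        with pytest.raises(ValueError):
            cluster_sequences(recs, 0.9, 101)

    def test_protein_clustering(self, rng):
        base = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=60)
        )
        recs = [
            SequenceRecord("p1", base, "protein"),
            SequenceRecord("p2", base[:-1] + ("A" if base[-1] != "A" else "C"), "protein"),
            SequenceRecord(
                "p3",
                "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=60)),
                "protein",
            ),
        ]
        clusters = cluster_sequences(recs, 0.9, 90)
        assert {"p1", "p2"} in clusters and {"p3"} in clusters


class TestIntersectionRate:
    def test_worked_example(self):
        assert intersection_rate({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_symmetry_bounds_equality(self, rng):
        for _ in range(20):
            a = set(rng.choice(20, size=rng.integers(1, 8), replace=False))
            b = set(rng.choice(20, size=rng.integers(1, 8), replace=False))
            r = intersection_rate(a, b)
            assert r == intersection_rate(b, a)
            assert 0 <= r <= 1
            assert (r == 1.0) == (a == b)


class TestTransformAndMatch:
    def test_identical_clusters_full_match(self):
        tf_clusters = [{"T1", "T2"}, {"T3"}]
        tfbs_clusters = [{"s1", "s2"}, {"s3"}]
        owner = {"s1": "T1", "s2": "T2", "s3": "T3"}
        report = transform_and_match(tf_clusters, tfbs_clusters, owner)
        assert report.match_rate == 1.0
        assert report.n_matching == 2

    def test_two_thirds_criterion_fails_at_half(self):
        # {A,B,C} vs rewritten {B,C,D}: intersection rate 0.5, containment 2/3
        tf_clusters = [{"A", "B", "C"}]
        tfbs_clusters = [{"sB", "sC", "sD"}]
        owner = {"sB": "B", "sC": "C", "sD": "D"}
        report = transform_and_match(tf_clusters, tfbs_clusters, owner)
        assert report.n_matching == 0

    def test_unmapped_site_error(self):
        with pytest.raises(KeyError):
            transform_and_match([{"A"}], [{"s1"}], {})


class TestAttributeFrequency:
    def _model(self, cols, used_col):
        # minimal stand-in: a depth-1 tree that can only split on used_col
        rng = np.random.default_rng(42)
        y = np.array([0, 1, 0, 1] * 15)
        X = pd.DataFrame({c: rng.normal(size=60) * 0.01 for c in cols})
        X[used_col] = y * 2.0
        from tfbslens.models import train_tree

        return train_tree(X, y, seed=0)

    def test_all_models_use_one_attribute(self):
        models = [self._model(["a", "b", "c"], "b") for _ in range(4)]
        freq = attribute_frequency(models, ["a", "b", "c"])
        assert freq["b"] == 1.0
        assert freq["a"] == 0.0 and freq["c"] == 0.0

    def test_unused_attributes_all_zero(self):
        models = [self._model(["a", "b"], "a")]
        freq = attribute_frequency(models, ["x", "y"])
        assert (freq == 0).all()


class TestBootstrapSelection:
    def test_flat_frequencies_select_nothing(self):
        freqs = pd.Series(0.4, index=[f"a{i}" for i in range(38)])
        assert bootstrap_select_attributes(freqs, seed=0) == []

    def test_five_high_attributes_selected(self):
        vals = np.full(38, 0.1)
        vals[[3, 10, 17, 25, 33]] = 0.9
        freqs = pd.Series(vals, index=[f"a{i}" for i in range(38)])
        assert bootstrap_select_attributes(freqs, seed=0) == [
            "a3",
            "a10",
            "a17",
            "a25",
            "a33",
        ]

    def test_deterministic_under_seed(self, rng):
        freqs = pd.Series(rng.random(38), index=[f"a{i}" for i in range(38)])
        assert bootstrap_select_attributes(freqs, seed=11) == bootstrap_select_attributes(
            freqs, seed=11
        )

    def test_encoding_attributes_caps_dimension(self):
        freqs = pd.Series(
            [0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.1],
            index=list("abcdefgh"),
        )
        enc = encoding_attributes(freqs, list("abcdefg"), n_dims=5)
        assert enc == ["a", "b", "c", "d", "e"]


class TestEncodeAndMap:
    def _blob_vectors(self, centers, n_per, spread, rng):
        rows, classes = {}, {}
        k = 0
        for c, center in enumerate(centers):
            for _ in range(n_per):
                tf = f"T{k:03d}"
                rows[tf] = center + rng.normal(scale=spread, size=len(center))
                classes[tf] = f"class{c + 1}"
                k += 1
        return classes, pd.DataFrame(rows).T

    def test_four_separated_blobs_recovered(self, rng):
        centers = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float
        )
        classes, vectors = self._blob_vectors(centers, 10, 0.5, rng)
        mapping = encode_and_map(classes, vectors, seed=0)
        assert mapping.k_selected == 4
        assert mapping.all_mapped()

    def test_single_blob_collapses_to_one_cluster(self, rng):
        classes, vectors = self._blob_vectors([np.zeros(3), np.zeros(3)], 8, 0.5, rng)
        mapping = encode_and_map(classes, vectors, seed=0)
        assert mapping.k_selected == 1
        assert (mapping.table.mapping_rate == 1.0).all()

    def test_mapping_threshold_is_strict(self, rng):
        # class1: 9 of 10 members in blob A, 1 stray in blob B -> rate 0.9 -> No
        classes, vectors = self._blob_vectors(
            [np.zeros(2), np.full(2, 12.0)], 10, 0.3, rng
        )
        stray = sorted(t for t, c in classes.items() if c == "class1")[0]
        vectors.loc[stray] = [12.0, 12.0]
        mapping = encode_and_map(classes, vectors, seed=0)
        t = mapping.table.set_index("tf_class")
        assert t.loc["class1", "mapping_rate"] == pytest.approx(0.9)
        assert t.loc["class1", "mapping_status"] == "No"
        assert t.loc["class2", "mapping_status"] == "Yes"

    def test_degenerate_vectors_error(self):
        classes = {"T1": "a", "T2": "b"}
        vectors = pd.DataFrame({"T1": [1.0, 1.0], "T2": [1.0, 1.0]}).T
        with pytest.raises(ValueError):
            encode_and_map(classes, vectors, seed=0)

    def test_tf_mean_vectors(self, rng):
        feats = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        vecs = tf_mean_vectors({"T1": feats}, ["a", "b"])
        assert vecs.loc["T1", "a"] == 2.0 and vecs.loc["T1", "b"] == 3.0


class TestConservation:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"tf_score": [0.1, 0.2, 0.3, 0.4], "tfbs_score": [1, 2, 3, 4.0]})
        rho, p = conservation_correspondence(df)
        assert rho == pytest.approx(1.0)

    def test_reversed_pairs(self):
        df = pd.DataFrame({"tf_score": [0.1, 0.2, 0.3, 0.4], "tfbs_score": [4, 3, 2, 1.0]})
        rho, _ = conservation_correspondence(df)
        assert rho == pytest.approx(-1.0)

    def test_constant_column_error(self):
        df = pd.DataFrame({"tf_score": [0.5, 0.5, 0.5], "tfbs_score": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            conservation_correspondence(df)

    def test_tf_conservation_score(self):
        scores = tf_conservation_score({"a": 0, "b": 49, "c": 31, "d": 96}, 96)
        assert scores["a"] == 0.0
        assert scores["d"] == 1.0
        assert scores["b"] == pytest.approx(0.510, abs=5e-4)
        assert scores["c"] == pytest.approx(0.323, abs=5e-4)
        with pytest.raises(ValueError):
            tf_conservation_score({"x": 97}, 96)

    def test_fixture_scores_near_multiples_of_96th(self):
        from tfbslens.io import load_conservation_fixture

        df = load_conservation_fixture()
        frac = df.tf_score.to_numpy() * 96
        assert np.abs(frac - np.round(frac)).max() < 0.05

    def test_tfbs_conservation_mean(self):
        # motif matching is strand-aware: pick sites whose reverse complements
        # also miss the catalog
        cat = MotifCatalog([("AAAAAAAA", 10.0), ("CCCCCCCC", 20.0)])
        assert tfbs_conservation_score(["ACACACAC", "AGAGAGAG"], cat) == 0.0
        assert tfbs_conservation_score(["AAAAAAAA", "CCCCCCCC"], cat) == 15.0

    def test_tfbs_conservation_composition_oracle(self, rng, small_catalog):
        from tfbslens.features import evolution_score

        seqs = [random_dna(12, rng) for _ in range(30)]
        expected = np.mean([evolution_score(s, small_catalog) for s in seqs])
        assert tfbs_conservation_score(seqs, small_catalog) == pytest.approx(expected)
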