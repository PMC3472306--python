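"""CFS selection, tree training, control model, metrics and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from tests.conftest import random_dna, random_pwm
from tfbslens.background import assemble_instance_sets
from tfbslens.containers import Instance, InstanceSet
from tfbslens.features import MotifCatalog
from tfbslens.models import (
    ConfusionCounts,
    cfs_merit,
    cfs_select,
    choose_control_cutoff,
    compute_auc,
    compute_metrics,
    control_predict,
    crossvalidate,
    run_model_suite,
    summarize_performance,
    train_tree,
)
from tfbslens.models import _abs_correlations
from tfbslens.simulate import sample_sites


def pair_counting_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCFS:
    def _planted(self, rng, n=200):
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {f"noise{i}": rng.normal(size=n) for i in range(39)}
        )
        X.insert(5, "signal", y * 3.0 + rng.normal(size=n))
        return X, y

    def test_informative_column_found(self, rng):
        X, y = self._planted(rng)
        assert "signal" in cfs_select(X, y)
        # merit of the signal column alone beats every other single column
        rcf, rff = _abs_correlations(X.to_numpy(), y.astype(float))
        merits = [cfs_merit((j,), rcf, rff) for j in range(X.shape[1])]
        assert X.columns[int(np.argmax(merits))] == "signal"

    def test_duplicate_informative_column_not_both_kept(self, rng):
        y = np.repeat([0, 1], 100)
        signal = y * 2.0 + np.random.default_rng(0).normal(size=200)
        X = pd.DataFrame({"a": signal, "b": signal.copy()})
        selected = cfs_select(X, y)
        assert len(selected) == 1
        # direct merit computation: a perfectly correlated duplicate cannot
        # raise the merit, so the smaller subset is preferred
        rcf, rff = _abs_correlations(X.to_numpy(), y.astype(float))
        assert cfs_merit((0,), rcf, rff) >= cfs_merit((0, 1), rcf, rff) - 1e-10

    def test_two_column_brute_force(self, rng):
        for trial in range(5):
            y = rng.integers(0, 2, size=60)
            if len(np.unique(y)) < 2:
                continue
            X = pd.DataFrame(
                {"c0": rng.normal(size=60) + y, "c1": rng.normal(size=60)}
            )
            rcf, rff = _abs_correlations(X.to_numpy(), y.astype(float))
            subsets = [(0,), (1,), (0, 1)]
            best = max(subsets, key=lambda s: cfs_merit(s, rcf, rff))
            assert cfs_select(X, y) == [X.columns[j] for j in best]

    def test_constant_labels_error(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            cfs_select(X, np.zeros(10))


class TestTrainTree:
    def test_separable_single_feature(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = train_tree(X, y, seed=0)
        pred, _ = model.predict(X)
        assert (pred == y).all()
        assert model.tree.get_depth() == 1

    def test_noise_is_pruned_to_near_stump(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=200)
        model = train_tree(X, y, seed=0)
        assert model.n_leaves <= 3
        # pooled CV accuracy near chance
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        correct = 0
        for tr, te in skf.split(X, y):
            m = train_tree(X.iloc[tr], y[tr], seed=0)
            pred, _ = m.predict(X.iloc[te])
            correct += (pred == y[te]).sum()
        assert 0.35 <= correct / len(y) <= 0.65

    def test_deterministic_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)))
        X.columns = [str(c) for c in X.columns]
        y = (X.iloc[:, 0] + rng.normal(scale=0.5, size=80) > 0).astype(int).to_numpy()
        m1 = train_tree(X, y, seed=5)
        m2 = train_tree(X, y, seed=5)
        p1, s1 = m1.predict(X)
        p2, s2 = m2.predict(X)
        assert (p1 == p2).all() and np.allclose(s1, s2)

    def test_too_few_instances(self):
        with pytest.raises(ValueError):
            train_tree(pd.DataFrame({"a": [1.0]}), np.array([1]))


class TestControl:
    def test_cutoff_zero_all_positive(self, rng):
        pwm = random_pwm(6, rng, sharpness=0.5)
        segments = [random_dna(6, rng) for _ in range(20)]
        scores, labels = control_predict(segments, pwm, cutoff=0.0)
        assert labels.sum() == 20  # specificity 0 against any negatives

    def test_cutoff_above_one_all_negative(self, rng):
        pwm = random_pwm(6, rng, sharpness=0.5)
        segments = [random_dna(6, rng) for _ in range(20)]
        _, labels = control_predict(segments, pwm, cutoff=1.01)
        assert labels.sum() == 0  # sensitivity 0 on any positives

    def test_chosen_cutoff_is_specificity_heavy(self, rng):
        pwm = random_pwm(8, rng, sharpness=0.2)
        pos = sample_sites(pwm, 50, rng)
        neg = [random_dna(8, rng) for _ in range(50)]
        scores, _ = control_predict(pos + neg, pwm, cutoff=0.5)
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        cutoff = choose_control_cutoff(scores, labels)
        pred = (scores >= cutoff).astype(int)
        sens = pred[labels == 1].mean()
        spec = 1 - pred[labels == 0].mean()
        assert spec >= sens
        assert sens > 0


class TestMetrics:
    def test_perfect_counts(self):
        assert compute_metrics(ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(3, 2, 2, 1))
        assert (sens, spec, acc) == (0.75, 0.5, 0.625)

    def test_random_counts_formula_oracle(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            sens, spec, acc = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert sens == pytest.approx(tp / (tp + fn))
            assert spec == pytest.approx(tn / (tn + fp))
            assert acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))

    def test_zero_denominator_flags_nan(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(0, 3, 2, 0))
        assert np.isnan(sens) and spec == 0.4


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert compute_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5

    def test_pair_counting_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=50)
            labels = rng.integers(0, 2, size=50)
            if len(np.unique(labels)) < 2:
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels)
            )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])


def make_planted_set(rng, n_pos=50, pwm_len=8, catalog=None):
    pwm = random_pwm(pwm_len, rng, sharpness=0.15)
    positives = sample_sites(pwm, n_pos, rng)
    pool = [random_dna(pwm_len, rng) for _ in range(n_pos * 4)]
    iset = assemble_instance_sets(positives, pool, n_sets=1, seed=rng)[0]
    return iset, pwm


class TestCrossvalidate:
    def test_planted_pwm_sequence_model(self, rng, default_table):
        iset, pwm = make_planted_set(rng)
        m = crossvalidate(iset, "sequence", default_table, MotifCatalog([]), pwm=pwm, seed=0)
        assert m.accuracy >= 0.95

    def test_label_shuffled_near_chance(self, rng, default_table):
        iset, pwm = make_planted_set(rng)
        labels = np.array(iset.labels)
        rng.shuffle(labels)
        for inst, lab in zip(iset.instances, labels):
            inst.label = int(lab)
        m = crossvalidate(iset, "sequence", default_table, MotifCatalog([]), pwm=pwm, seed=0)
        assert 0.4 <= m.accuracy <= 0.6

    def test_stratified_fold_sizes(self):
        # 23 positives + 23 negatives: fold sizes differ by at most 1 per class
        y = np.r_[np.ones(23, int), np.zeros(23, int)]
        skf = StratifiedKFold(10, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((46, 1)), y):
            classes = y[te]
            assert abs((classes == 1).sum() - (classes == 0).sum()) <= 1

    def test_too_few_instances_error(self, rng, default_table):
        iset = InstanceSet(
            "tiny",
            [Instance(f"i{k}", random_dna(8, rng), k % 2) for k in range(10)],
        )
        with pytest.raises(ValueError, match="10"):
            crossvalidate(iset, "structure", default_table, MotifCatalog([]), seed=0)

    def test_control_requires_pwm(self, rng, default_table):
        iset, _ = make_planted_set(rng)
        with pytest.raises(ValueError, match="PWM"):
            crossvalidate(iset, "control", default_table, MotifCatalog([]), pwm=None)

    def test_feature_selection_sees_only_training_folds(self, rng, default_table, monkeypatch):
        """CFS inside the fold must never receive test-fold rows."""
        iset, pwm = make_planted_set(rng, n_pos=30)
        seen = []
        import tfbslens.models as M

        real = M.cfs_select

        def spy(features, labels, **kw):
            seen.append(set(features.index))
            return real(features, labels, **kw)

        monkeypatch.setattr(M, "cfs_select", spy)
        crossvalidate(iset, "hybrid", default_table, MotifCatalog([]), pwm=pwm, seed=4)
        y = np.array(iset.labels)
        skf = StratifiedKFold(10, shuffle=True, random_state=4)
        ids = np.array([i.id for i in iset.instances])
        test_folds = [set(ids[te]) for _, te in skf.split(ids, y)]
        assert len(seen) == 10
        for train_ids, test_ids in zip(seen, test_folds):
            assert not train_ids & test_ids


class TestModelSuite:
    def _bundle(self, rng, n_sets=3):
        pwm = random_pwm(8, rng, sharpness=0.15)
        positives = sample_sites(pwm, 15, rng)
        pool = [random_dna(8, rng) for _ in range(200)]
        return assemble_instance_sets(positives, pool, n_sets=n_sets, seed=rng), pwm

    def test_row_counts_with_and_without_pwm(self, rng, default_table):
        sets, pwm = self._bundle(rng)
        cat = MotifCatalog([])
        with_pwm = run_model_suite(sets, default_table, cat, pwm=pwm, seed=0)
        assert len(with_pwm) == 5 * len(sets)
        without = run_model_suite(sets, default_table, cat, pwm=None, seed=0)
        assert len(without) == 3 * len(sets)
        assert set(without.model) == {"structure", "evolution", "hybrid"}

    def test_summary_percentiles_non_decreasing(self, rng, default_table):
        sets, pwm = self._bundle(rng)
        results = run_model_suite(sets, default_table, MotifCatalog([]), pwm=pwm, seed=0)
        summary = summarize_performance(results)
        pcols = ["p5", "p25", "p50", "p75", "p95"]
        for _, row in summary.iterrows():
            vals = row[pcols].to_numpy(dtype=float)
            assert (np.diff(vals) >= -1e-12).all()
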