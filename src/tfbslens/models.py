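"""TFBS identification models and their cross-validated evaluation.

Five models are built per instance set: a Match-style control (min-max
normalized PWM similarity with a cutoff chosen on the training folds), three
single-feature decision trees (sequence, structure, evolution) and a hybrid
tree over the full 40-column block with correlation-based feature selection
(CFS) inside each training fold. Evaluation is stratified 10-fold
cross-validation; confusion counts and scores are pooled over folds, from
which sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/N and a rank-based AUC are computed.

The decision trees follow the C4.5 recipe: information-based splits (entropy
criterion) with pessimistic post-pruning — a subtree collapses to a leaf when
the leaf's upper-confidence-bound error (CF = 0.25) does not exceed the sum of
its children's — everything deterministic under a seed.

The top-level API is statsmodels-flavored: :class:`TFBSRecognition` is built
from a TF's instance sets and ``fit()`` returns a
:class:`TFBSRecognitionResults` carrying the per-set metrics, their summary
distribution and a ``summary()`` table.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .containers import InstanceSet
from .features import (
    EVOLUTION_COLUMN,
    SEQUENCE_COLUMN,
    PWM,
    DinucleotidePropertyTable,
    MotifCatalog,
    featurize,
    match_similarity_score,
)

MODEL_KINDS = ("control", "sequence", "structure", "evolution", "hybrid")
PERCENTILES = (5, 25, 50, 75, 95)

__all__ = [
    "ConfusionCounts",
    "EvalMetrics",
    "TrainedModel",
    "cfs_merit",
    "cfs_select",
    "train_tree",
    "choose_control_cutoff",
    "control_predict",
    "compute_metrics",
    "compute_auc",
    "crossvalidate",
    "run_model_suite",
    "summarize_performance",
    "TFBSRecognition",
    "TFBSRecognitionResults",
    "MODEL_KINDS",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy from confusion counts.

    A zero denominator yields NaN (an explicit undefined-metric flag), never
    a silent 0.
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    acc = (counts.tp + counts.tn) / counts.total if counts.total else math.nan
    return sens, spec, acc


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney, ties counted half; trapezoidal ROC area)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Correlation-based feature selection (CFS)
# ---------------------------------------------------------------------------


def _abs_correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson r| feature-to-label and feature-to-feature; constant columns -> 0."""
    n, k = X.shape
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    yc = y - y.mean()
    sy = yc.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        rcf = np.abs((Xc * yc[:, None]).mean(axis=0) / (sx * sy))
        cov = (Xc.T @ Xc) / n
        rff = np.abs(cov / np.outer(sx, sx))
    rcf = np.nan_to_num(rcf)
    rff = np.nan_to_num(rff)
    np.fill_diagonal(rff, 1.0)
    return rcf, rff


def cfs_merit(subset: tuple[int, ...], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit: k * mean|r_cf| / sqrt(k + k(k-1) * mean|r_ff|)."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = np.asarray(subset)
    mean_cf = rcf[idx].mean()
    if k == 1:
        return float(mean_cf)
    sub = rff[np.ix_(idx, idx)]
    mean_ff = (sub.sum() - k) / (k * (k - 1))
    return float(k * mean_cf / math.sqrt(k + k * (k - 1) * mean_ff))


def cfs_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    max_stale: int = 5,
) -> list[str]:
    """Correlation-based filter with best-first forward search.

    Explores subsets by repeatedly expanding the best-merit open subset with
    one extra feature, stopping after ``max_stale`` expansions that fail to
    improve on the best merit seen. Never returns an empty selection (falls
    back to the single best-correlated column). Columns come back in the
    canonical order of ``features``.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; CFS undefined")
    X = features.to_numpy(dtype=float)
    rcf, rff = _abs_correlations(X, y)
    n_feat = X.shape[1]

    best_subset: tuple[int, ...] = ()
    best_merit = -np.inf
    seen: set[tuple[int, ...]] = set()
    counter = 0
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, counter, ())]
    stale = 0
    while heap and stale < max_stale:
        neg_merit, _, subset = heapq.heappop(heap)
        # strict improvement beyond float noise: a duplicated feature yields
        # an exactly tied merit and must not displace the smaller subset
        if -neg_merit > best_merit + 1e-10:
            best_merit = -neg_merit
            best_subset = subset
            stale = 0
        else:
            stale += 1
        for j in range(n_feat):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in seen:
                continue
            seen.add(child)
            counter += 1
            heapq.heappush(heap, (-cfs_merit(child, rcf, rff), counter, child))
    if not best_subset:
        best_subset = (int(np.argmax(rcf)),)
    return [features.columns[j] for j in sorted(best_subset)]


# ---------------------------------------------------------------------------
# Decision trees and the control model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted TFBS identification model.

    Tree-based kinds carry a grown sklearn tree plus the set of nodes the
    pessimistic pruning pass collapsed into leaves; the control kind carries
    a Match-score cutoff. ``feature_columns`` is the subset of the canonical
    block the model consumes; ``used_attributes`` are the columns the pruned
    tree actually splits on (the structure-level attribute-frequency
    analysis reads them).
    """

    kind: str
    feature_columns: list[str]
    tree: DecisionTreeClassifier | None = None
    effective_leaves: frozenset[int] | None = None
    cutoff: float | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def _active_nodes(self) -> set[int]:
        """Node ids still reachable after pruning."""
        t = self.tree.tree_
        active, stack = set(), [0]
        while stack:
            node = stack.pop()
            active.add(node)
            if node not in self.effective_leaves:
                stack.extend((t.children_left[node], t.children_right[node]))
        return active

    @property
    def n_leaves(self) -> int:
        if self.tree is None:
            return 0
        return sum(1 for n in self._active_nodes() if n in self.effective_leaves)

    @property
    def used_attributes(self) -> list[str]:
        if self.tree is None:
            return []
        t = self.tree.tree_
        used = sorted(
            {
                int(t.feature[n])
                for n in self._active_nodes()
                if n not in self.effective_leaves
            }
        )
        return [self.feature_columns[i] for i in used]

    def predict(self, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (predicted labels, positive-class probability scores)."""
        X = features[self.feature_columns].to_numpy(dtype=float)
        if self.kind == "control":
            scores = X[:, 0]
            return (scores >= self.cutoff).astype(int), scores
        t = self.tree.tree_
        pos_col = list(self.tree.classes_).index(1)
        # walk each sample down to the first pruned-or-real leaf
        scores = np.empty(len(X))
        for i, row in enumerate(X):
            node = 0
            while node not in self.effective_leaves:
                if row[t.feature[node]] <= t.threshold[node]:
                    node = t.children_left[node]
                else:
                    node = t.children_right[node]
            dist = t.value[node][0]
            scores[i] = dist[pos_col] / dist.sum()
        return (scores >= 0.5).astype(int), scores


def train_tree(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    kind: str = "tree",
    min_leaf: int = 2,
    prune_fraction: float = 0.1,
) -> TrainedModel:
    """Grow an entropy-criterion tree and apply reduced-error post-pruning.

    The training data is split 90/10 (stratified, seeded); the tree grows on
    the 90% part; bottom-up, a subtree is collapsed into a leaf unless it
    saves strictly more than one held-out error (the one-case margin keeps a
    single lucky holdout case from preserving a spurious split; ties prune,
    so a subtree never visited by holdout cases disappears). On
    label-independent data this reduces the tree to a near-stump; strongly
    separating splits are kept. Deterministic under the seed.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) < 2:
        raise ValueError("need at least 2 instances to train a tree")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train a tree")
    X = features.to_numpy(dtype=float)
    class_counts = np.bincount(y, minlength=2)
    n_val = int(round(len(y) * prune_fraction))
    can_holdout = prune_fraction > 0 and class_counts.min() >= 2 and n_val >= 2
    if can_holdout:
        idx_grow, idx_val = _stratified_split(y, prune_fraction, seed)
        X_grow, y_grow = X[idx_grow], y[idx_grow]
        X_val, y_val = X[idx_val], y[idx_val]
        if len(np.unique(y_grow)) < 2:
            X_grow, y_grow, X_val, y_val = X, y, None, None
    else:
        X_grow, y_grow, X_val, y_val = X, y, None, None

    tree = DecisionTreeClassifier(
        criterion="entropy", min_samples_leaf=min_leaf, random_state=seed
    )
    tree.fit(X_grow, y_grow)
    t = tree.tree_

    # holdout error count per node when the node predicts its training majority
    node_leaf_err = np.zeros(t.node_count)
    if X_val is not None and len(X_val):
        majority = t.value[:, 0, :].argmax(axis=1)
        paths = tree.decision_path(X_val)
        for i in range(len(X_val)):
            wrong = majority[paths.indices[paths.indptr[i] : paths.indptr[i + 1]]] != y_val[i]
            node_leaf_err[paths.indices[paths.indptr[i] : paths.indptr[i + 1]]] += wrong

    pruned: set[int] = set()
    subtree_err = np.zeros(t.node_count)

    def visit(node: int) -> float:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            pruned.add(node)
            subtree_err[node] = node_leaf_err[node]
            return subtree_err[node]
        below = visit(left) + visit(right)
        if X_val is not None and node_leaf_err[node] <= below + 1:
            pruned.add(node)
            subtree_err[node] = node_leaf_err[node]
        else:
            subtree_err[node] = below
        return subtree_err[node]

    visit(0)
    effective: set[int] = set()

    def collect(node: int) -> None:
        if node in pruned:
            effective.add(node)
            return
        collect(t.children_left[node])
        collect(t.children_right[node])

    collect(0)
    return TrainedModel(
        kind=kind,
        feature_columns=list(features.columns),
        tree=tree,
        effective_leaves=frozenset(effective),
        config={"min_leaf": min_leaf, "prune_fraction": prune_fraction},
        seed=seed,
    )


def _stratified_split(
    y: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified grow/holdout index split."""
    rng = np.random.default_rng(seed)
    grow, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(len(idx) * fraction)))
        val.extend(idx[:k])
        grow.extend(idx[k:])
    return np.sort(np.array(grow)), np.sort(np.array(val))


def choose_control_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Control-model cutoff: over a grid of observed scores, maximize
    specificity subject to sensitivity > 0.

    Reproduces the control model's characteristic high-specificity /
    low-sensitivity profile.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0:
        raise ValueError("no positive instances to calibrate the control cutoff")
    best_cut, best_spec, best_sens = None, -1.0, -1.0
    for cut in np.unique(scores):
        sens = float((pos >= cut).mean())
        spec = float((neg < cut).mean()) if len(neg) else 1.0
        if sens <= 0:
            continue
        if spec > best_spec or (spec == best_spec and sens > best_sens):
            best_cut, best_spec, best_sens = float(cut), spec, sens
    return best_cut


def control_predict(
    segments: list[str], pwm: PWM, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Match-style scores and thresholded labels for raw segments."""
    if pwm is None:
        raise ValueError("control model unavailable without a PWM")
    scores = np.array([_control_score(s, pwm) for s in segments])
    return scores, (scores >= cutoff).astype(int)


def _control_score(segment: str, pwm: PWM) -> float:
    n = len(pwm)
    if len(segment) == n:
        return match_similarity_score(segment, pwm)
    if len(segment) < n:
        raise ValueError("segment shorter than PWM")
    return max(
        match_similarity_score(segment[off : off + n], pwm)
        for off in range(len(segment) - n + 1)
    )


# ---------------------------------------------------------------------------
# Cross-validation and the model suite
# ---------------------------------------------------------------------------

_FOLDS = 10


def _feature_columns_for(kind: str, featured: pd.DataFrame, table_attrs: list[str]) -> list[str]:
    if kind == "sequence":
        return [SEQUENCE_COLUMN]
    if kind == "structure":
        return [a for a in table_attrs if a in featured.columns]
    if kind == "evolution":
        return [EVOLUTION_COLUMN]
    if kind == "hybrid":
        return list(featured.columns)
    raise ValueError(f"unknown model kind {kind!r}")


def crossvalidate(
    instances: InstanceSet,
    kind: str,
    table: DinucleotidePropertyTable,
    catalog: MotifCatalog,
    pwm: PWM | None = None,
    seed: int = 0,
    n_folds: int = _FOLDS,
    collect_models: list[TrainedModel] | None = None,
) -> EvalMetrics:
    """Stratified ``n_folds``-fold cross-validation of one model kind.

    Features are deterministic per-instance quantities, so the feature block
    is computed once for the whole set; the training-dependent steps (CFS for
    the hybrid model, the control cutoff) run strictly inside each training
    fold. Confusion counts and scores are pooled over the folds.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if kind in ("control", "sequence") and pwm is None:
        raise ValueError(f"{kind} model unavailable without a PWM")
    y = np.asarray(instances.labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs at least {n_folds} instances "
            f"per class (got {counts.min()})"
        )
    if instances.features is None:
        featurize(instances, table, catalog, pwm=pwm)
    feats = instances.features

    control_scores = None
    if kind == "control":
        # like the feature block, Match scores are per-instance constants;
        # only the cutoff is calibrated inside each training fold
        control_scores = np.array(
            [_control_score(s, pwm) for s in instances.sequences]
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts()
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(feats, y)):
        f_train, f_test = feats.iloc[train_idx], feats.iloc[test_idx]
        y_train, y_test = y[train_idx], y[test_idx]
        if kind == "control":
            cutoff = choose_control_cutoff(control_scores[train_idx], y_train)
            test_scores = control_scores[test_idx]
            y_pred = (test_scores >= cutoff).astype(int)
            scores = test_scores
            if collect_models is not None:
                collect_models.append(
                    TrainedModel(kind="control", feature_columns=[SEQUENCE_COLUMN], cutoff=cutoff)
                )
        else:
            cols = _feature_columns_for(kind, feats, table.attributes)
            f_train_k, f_test_k = f_train[cols], f_test[cols]
            if kind == "hybrid":
                selected = cfs_select(f_train_k, y_train)
                f_train_k, f_test_k = f_train_k[selected], f_test_k[selected]
            fold_seed = (seed * 1009 + fold) % (2**31 - 1)
            model = train_tree(f_train_k, y_train, seed=fold_seed, kind=kind)
            y_pred, scores = model.predict(f_test_k)
            if collect_models is not None:
                collect_models.append(model)
        pooled = pooled + ConfusionCounts.from_predictions(y_test, y_pred)
        pooled_scores.append(np.asarray(scores, dtype=float))
        pooled_labels.append(y_test)
    sens, spec, acc = compute_metrics(pooled)
    auc = compute_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvalMetrics(sens, spec, acc, auc)


def run_model_suite(
    instance_sets: list[InstanceSet],
    table: DinucleotidePropertyTable,
    catalog: MotifCatalog,
    pwm: PWM | None = None,
    seed: int = 0,
    tf_id: str = "TF",
    kinds: tuple[str, ...] = MODEL_KINDS,
    collect_models: dict[str, list[TrainedModel]] | None = None,
) -> pd.DataFrame:
    """Cross-validate every applicable model on every instance set of one TF.

    The control and sequence models are skipped when no PWM is available (the
    paper's "dataset 2" regime). Returns one row per (set, model) with the
    four pooled metrics.
    """
    applicable = [
        k for k in kinds if pwm is not None or k not in ("control", "sequence")
    ]
    rows = []
    ss = np.random.SeedSequence(seed)
    set_seeds = ss.generate_state(len(instance_sets))
    for iset, set_seed in zip(instance_sets, set_seeds):
        for kind in applicable:
            sink = collect_models.setdefault(kind, []) if collect_models is not None else None
            m = crossvalidate(
                iset,
                kind,
                table,
                catalog,
                pwm=pwm,
                seed=int(set_seed % (2**31 - 1)),
                collect_models=sink,
            )
            rows.append(
                {
                    "tf_id": tf_id,
                    "set_id": iset.set_id,
                    "model": kind,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                    "auc": m.auc,
                }
            )
    return pd.DataFrame(rows)


def summarize_performance(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and the 5/25/50/75/95 percentiles of each metric per model."""
    metrics = ["sensitivity", "specificity", "accuracy", "auc"]
    rows = []
    for model, group in results.groupby("model"):
        for metric in metrics:
            vals = group[metric].to_numpy(dtype=float)
            pct = np.percentile(vals, PERCENTILES)
            rows.append(
                {
                    "model": model,
                    "metric": metric,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    **{f"p{p}": v for p, v in zip(PERCENTILES, pct)},
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class TFBSRecognition:
    """TFBS recognition analysis for one TF, statsmodels-style.

    Built from the TF's balanced instance sets plus the shared property table
    and motif catalog (and the TF's PWM when one exists); ``fit`` runs the
    cross-validated model suite and returns the results object.
    """

    def __init__(
        self,
        instance_sets: list[InstanceSet],
        property_table: DinucleotidePropertyTable,
        motif_catalog: MotifCatalog,
        pwm: PWM | None = None,
        tf_id: str = "TF",
    ):
        if not instance_sets:
            raise ValueError("need at least one instance set")
        self.instance_sets = instance_sets
        self.property_table = property_table
        self.motif_catalog = motif_catalog
        self.pwm = pwm
        self.tf_id = tf_id

    def fit(self, seed: int = 0, kinds: tuple[str, ...] = MODEL_KINDS) -> "TFBSRecognitionResults":
        collected: dict[str, list[TrainedModel]] = {}
        metrics = run_model_suite(
            self.instance_sets,
            self.property_table,
            self.motif_catalog,
            pwm=self.pwm,
            seed=seed,
            tf_id=self.tf_id,
            kinds=kinds,
            collect_models=collected,
        )
        return TFBSRecognitionResults(self, metrics, collected, seed)


class TFBSRecognitionResults:
    """Cross-validated performance of the model suite for one TF."""

    def __init__(
        self,
        model: TFBSRecognition,
        metrics: pd.DataFrame,
        trained_models: dict[str, list[TrainedModel]],
        seed: int,
    ):
        self.model = model
        self.metrics = metrics
        self.trained_models = trained_models
        self.seed = seed
        self.performance = summarize_performance(metrics)

    def mean_metric(self, kind: str, metric: str) -> float:
        sel = self.metrics[self.metrics["model"] == kind]
        return float(sel[metric].mean())

    def summary(self) -> str:
        lines = [
            f"TFBS recognition results: {self.model.tf_id} "
            f"({len(self.model.instance_sets)} instance sets, seed {self.seed})",
            f"PWM available: {'yes' if self.model.pwm is not None else 'no'}",
            "",
            self.performance.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
        ]
        return "\n".join(lines)
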