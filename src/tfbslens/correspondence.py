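"""Three-level TF-TFBS correspondence analysis.

* **Sequence level** — TF proteins and TFBS segments are clustered separately
  by blastclust-style single linkage (a pair links when a local alignment
  covers at least a fraction L of both sequences with at least S% identity);
  each TFBS cluster is rewritten to the set of owning TF names and a TF
  cluster counts as matched when >90% of it is contained in some rewritten
  cluster or the intersection rate |A∩B|/|A∪B| exceeds 2/3. A one-sided
  Fisher exact test over unordered TF pairs ((same TF cluster) x (co-occur
  in a rewritten TFBS cluster)) quantifies the association.
* **Structure level** — attribute usage frequencies are collected from the
  trained trees; a 10,000-replicate bootstrap of the 75th quantile yields a
  confidence interval whose midpoint thresholds the selected attributes;
  per-TF mean vectors over the selected attributes are clustered (class
  number by Gaussian-mixture BIC, assignment by K-means) and each annotated
  TF class is mapped to its best-overlapping cluster (mapped when the
  mapping rate exceeds 0.9).
* **Evolution level** — per-TF ortholog-based conservation scores are
  correlated (Spearman, one-sided positive, t approximation) with the mean
  evolution feature of each TF's binding sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .containers import SequenceRecord
from .features import MotifCatalog, evolution_scores

__all__ = [
    "cluster_sequences",
    "sequences_link",
    "intersection_rate",
    "MatchReport",
    "transform_and_match",
    "attribute_frequency",
    "bootstrap_select_attributes",
    "ClassMapping",
    "encode_and_map",
    "conservation_correspondence",
    "tf_conservation_score",
    "tfbs_conservation_score",
    "ConservationCorrespondence",
    "ConservationCorrespondenceResults",
]


# ---------------------------------------------------------------------------
# Sequence level
# ---------------------------------------------------------------------------


def _make_aligner(moltype: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if moltype == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
    return aligner


def _ungapped_link(a: str, b: str, coverage: float, identity: float) -> bool:
    """Does some ungapped offset overlap satisfy coverage-of-both and identity?

    Sound shortcut: an ungapped overlap is itself a local alignment, so a hit
    here implies linkage without running the aligner.
    """
    na, nb = len(a), len(b)
    min_ov = max(math.ceil(coverage * na - 1e-9), math.ceil(coverage * nb - 1e-9), 1)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for off in range(-(nb - min_ov), na - min_ov + 1):
        lo_a = max(0, off)
        hi_a = min(na, off + nb)
        if hi_a - lo_a < min_ov:
            continue
        seg_a = aa[lo_a:hi_a]
        seg_b = bb[lo_a - off : hi_a - off]
        matches = int((seg_a == seg_b).sum())
        if matches / len(seg_a) >= identity:
            return True
    return False


def _alignment_link(
    aligner: Align.PairwiseAligner, a: str, b: str, coverage: float, identity: float
) -> bool:
    """Does the best affine-gap local alignment satisfy the thresholds?"""
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return False
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return False
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    if span_a < coverage * len(a) or span_b < coverage * len(b):
        return False
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return False
    return counts.identities / columns >= identity


def sequences_link(
    a: str,
    b: str,
    coverage: float,
    identity_pct: float,
    moltype: str = "protein",
    aligner: Align.PairwiseAligner | None = None,
) -> bool:
    """blastclust-style pair predicate.

    True when either an ungapped offset overlap or the best affine-gap local
    alignment (BLOSUM62 for protein; +1/-2 match/mismatch for DNA) covers at
    least ``coverage`` of BOTH sequences with at least ``identity_pct``%
    identity over the aligned columns.
    """
    identity = identity_pct / 100.0
    if _ungapped_link(a, b, coverage, identity):
        return True
    if aligner is None:
        aligner = _make_aligner(moltype)
    return _alignment_link(aligner, a, b, coverage, identity)


def cluster_sequences(
    records: list[SequenceRecord], coverage: float, identity_pct: float
) -> list[set[str]]:
    """Single-linkage clustering under the blastclust-style pair predicate.

    Returns clusters as sets of record ids, ordered by decreasing size then
    smallest member id (deterministic).
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not 0 < coverage <= 1:
        raise ValueError("coverage threshold must be in (0, 1]")
    if not 0 < identity_pct <= 100:
        raise ValueError("identity percentage must be in (0, 100]")
    moltypes = {r.moltype for r in records}
    if len(moltypes) != 1:
        raise ValueError("records must share one moltype")
    moltype = moltypes.pop()
    aligner = _make_aligner(moltype)

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if sequences_link(
                records[i].sequence,
                records[j].sequence,
                coverage,
                identity_pct,
                moltype,
                aligner,
            ):
                union(i, j)
    groups: dict[int, set[str]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), set()).add(rec.id)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


def intersection_rate(a: set, b: set) -> float:
    """|A∩B| / |A∪B| between a TF cluster and a rewritten TFBS cluster."""
    union = a | b
    if not union:
        raise ValueError("intersection rate undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass
class MatchReport:
    n_tf_clusters: int
    n_tfbs_clusters: int
    n_matching: int
    match_rate: float
    fisher_odds: float
    fisher_p: float


def transform_and_match(
    tf_clusters: list[set[str]],
    tfbs_clusters: list[set[str]],
    tf_of_tfbs: dict[str, str],
) -> MatchReport:
    """Rewrite TFBS clusters to TF-name sets and match TF clusters against them.

    A TF cluster matches when (a) more than 90% of its members fall in one
    rewritten cluster, or (b) its intersection rate with one rewritten
    cluster exceeds 2/3. The Fisher association is one-sided over unordered
    TF pairs: (same TF cluster) x (co-occurring in a rewritten cluster).
    """
    rewritten: list[set[str]] = []
    for cluster in tfbs_clusters:
        names = set()
        for item in cluster:
            try:
                names.add(tf_of_tfbs[item])
            except KeyError:
                raise KeyError(f"TFBS instance {item!r} has no owning TF") from None
        rewritten.append(names)

    n_matching = 0
    for tf_cluster in tf_clusters:
        for r in rewritten:
            containment = len(tf_cluster & r) / len(tf_cluster)
            if containment > 0.9 or intersection_rate(tf_cluster, r) > 2 / 3:
                n_matching += 1
                break
    match_rate = n_matching / len(tf_clusters) if tf_clusters else float("nan")

    cluster_of = {tf: k for k, c in enumerate(tf_clusters) for tf in c}
    tfs = sorted(cluster_of)
    co_cluster: set[tuple[str, str]] = set()
    for r in rewritten:
        for pair in itertools.combinations(sorted(r), 2):
            co_cluster.add(pair)
    table = np.zeros((2, 2), dtype=int)
    for a, b in itertools.combinations(tfs, 2):
        same_tf = cluster_of[a] == cluster_of[b]
        co = (a, b) in co_cluster
        table[0 if same_tf else 1, 0 if co else 1] += 1
    odds, p = stats.fisher_exact(table, alternative="greater")
    return MatchReport(
        n_tf_clusters=len(tf_clusters),
        n_tfbs_clusters=len(tfbs_clusters),
        n_matching=n_matching,
        match_rate=match_rate,
        fisher_odds=float(odds),
        fisher_p=float(p),
    )


# ---------------------------------------------------------------------------
# Structure level
# ---------------------------------------------------------------------------


def attribute_frequency(models, attributes: list[str]) -> pd.Series:
    """Fraction of trained models whose pruned tree splits on each attribute."""
    models = list(models)
    if not models:
        raise ValueError("no trained models")
    counts = pd.Series(0.0, index=list(attributes))
    for model in models:
        for attr in set(model.used_attributes) & set(attributes):
            counts[attr] += 1
    return counts / len(models)


def bootstrap_select_attributes(
    frequencies: pd.Series, n_boot: int = 10_000, seed: int = 0
) -> list[str]:
    """Select attributes above the midpoint of a bootstrap CI of the 75th
    quantile of the frequency vector.

    The frequency vector is resampled with replacement ``n_boot`` times; the
    2.5/97.5 percentiles of the bootstrapped 75th quantile form the interval;
    attributes with frequency strictly above the interval midpoint are
    selected (so a flat frequency profile selects nothing).
    """
    rng = np.random.default_rng(seed)
    vals = frequencies.to_numpy(dtype=float)
    n = len(vals)
    samples = rng.integers(0, n, size=(n_boot, n))
    boot_q75 = np.percentile(vals[samples], 75, axis=1)
    lo, hi = np.percentile(boot_q75, [2.5, 97.5])
    midpoint = (lo + hi) / 2
    return [name for name, v in frequencies.items() if v > midpoint]


def encoding_attributes(
    frequencies: pd.Series, selected: list[str], n_dims: int = 5
) -> list[str]:
    """The attributes used for the low-dimensional TFBS encoding.

    Takes the ``n_dims`` highest-frequency members of the bootstrap
    selection (stable order on ties), mirroring the study's 5-dimension
    encoding of binding sites.
    """
    ranked = frequencies[selected].sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_dims])


def tf_mean_vectors(
    features_by_tf: dict[str, pd.DataFrame], attributes: list[str]
) -> pd.DataFrame:
    """Per-TF encoding: mean of the selected attributes over positive sites."""
    rows = {}
    for tf_id, feats in features_by_tf.items():
        if len(feats) == 0:
            raise ValueError(f"TF {tf_id!r} has no featurized positive sites")
        rows[tf_id] = feats[attributes].mean()
    return pd.DataFrame(rows).T


@dataclass
class ClassMapping:
    table: pd.DataFrame  # per TF class: items_in_class, mapped_items, mapping_rate, mapping_status
    k_selected: int
    cluster_of_tf: dict[str, int]

    def all_mapped(self) -> bool:
        return bool((self.table["mapping_status"] == "Yes").all())


def encode_and_map(
    class_of_tf: dict[str, str],
    tf_vectors: pd.DataFrame,
    seed: int = 0,
    max_k: int = 10,
) -> ClassMapping:
    """Map annotated TF classes onto structure-based TFBS clusters.

    ``tf_vectors`` holds one row per TF: the mean of the selected structure
    attributes over the TF's positive sites. The cluster count is chosen by
    BIC over Gaussian-mixture fits for k = 1..max_k, assignment is by K-means
    with that k, and each TF class maps to the cluster holding most of its
    members; mapping status is Yes when the mapping rate exceeds 0.9.
    """
    if len(set(class_of_tf.values())) < 2:
        raise ValueError("need at least 2 annotated TF classes")
    missing = [tf for tf in class_of_tf if tf not in tf_vectors.index]
    if missing:
        raise ValueError(f"no feature vector for TF(s) {missing[:3]}")
    X = tf_vectors.loc[sorted(class_of_tf)].to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate encoding: all TF vectors identical")
    # standardize so BIC is not dominated by attribute scale
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    n = X.shape[0]
    ks = range(1, min(max_k, n - 1) + 1)
    bics = []
    for k in ks:
        # tied covariance: the structure attributes all derive from the same
        # dinucleotide counts and are strongly mutually correlated, which a
        # diagonal model would misread as extra mixture components
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="tied",
            n_init=5,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(Xs)
        bics.append(gmm.bic(Xs))
    k_best = list(ks)[int(np.argmin(bics))]

    km = KMeans(n_clusters=k_best, n_init=50, random_state=seed).fit(Xs)
    tf_ids = sorted(class_of_tf)
    cluster_of_tf = {tf: int(c) for tf, c in zip(tf_ids, km.labels_)}

    rows = []
    for cls in sorted(set(class_of_tf.values())):
        members = [tf for tf in tf_ids if class_of_tf[tf] == cls]
        counts = np.bincount([cluster_of_tf[tf] for tf in members], minlength=k_best)
        mapped = int(counts.max())
        rate = mapped / len(members)
        rows.append(
            {
                "tf_class": cls,
                "items_in_class": len(members),
                "mapped_items": mapped,
                "mapping_rate": rate,
                "mapping_status": "Yes" if rate > 0.9 else "No",
            }
        )
    return ClassMapping(pd.DataFrame(rows), k_best, cluster_of_tf)


# ---------------------------------------------------------------------------
# Evolution level
# ---------------------------------------------------------------------------


def conservation_correspondence(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between TF and TFBS conservation scores.

    Tie-corrected (average) ranks; the one-sided (positive) p-value uses the
    t approximation t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
    """
    x = pairs["tf_score"].to_numpy(dtype=float)
    y = pairs["tfbs_score"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 conservation pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("conservation scores are constant; correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return rho, 0.0 if rho > 0 else 1.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(stats.t.sf(t, n - 2))
    return rho, p


def tf_conservation_score(
    ortholog_counts: dict[str, int], n_reference: int
) -> dict[str, float]:
    """Ortholog-count-based TF conservation: count / reference-species count."""
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    scores = {}
    for tf, count in ortholog_counts.items():
        if count < 0 or count > n_reference:
            raise ValueError(
                f"TF {tf!r}: ortholog count {count} outside [0, {n_reference}]"
            )
        scores[tf] = count / n_reference
    return scores


def tfbs_conservation_score(sequences: list[str], catalog: MotifCatalog) -> float:
    """Mean evolution feature over a TF's positive instances."""
    if not sequences:
        raise ValueError("no positive instances")
    return float(evolution_scores(sequences, catalog).mean())


class ConservationCorrespondence:
    """Evolution-level correspondence, statsmodels-style.

    Built from a conservation table (tf_id, tf_score, tfbs_score); ``fit``
    computes the one-sided Spearman test.
    """

    def __init__(self, pairs: pd.DataFrame):
        self.pairs = pairs

    def fit(self) -> "ConservationCorrespondenceResults":
        rho, p = conservation_correspondence(self.pairs)
        return ConservationCorrespondenceResults(self, rho, p)


class ConservationCorrespondenceResults:
    def __init__(self, model: ConservationCorrespondence, rho: float, pvalue: float):
        self.model = model
        self.rho = rho
        self.pvalue = pvalue
        self.nobs = len(model.pairs)

    def summary(self) -> str:
        return (
            "TF-TFBS conservation correspondence (Spearman, one-sided positive)\n"
            f"n pairs: {self.nobs}\n"
            f"rho:     {self.rho:.3f}\n"
            f"p-value: {self.pvalue:.3f}"
        )
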