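"""Recursive cluster elimination SVM (RCE-SVM).

The classifier wraps a linear SVM in an iterative feature-selection
loop.  For each of ``n_splits`` stratified train/test splits:

1. **Cluster step** — k-means groups the surviving features (features
   are the clustered points, living in training-subject space).  The
   initial cluster count is the number of features, decreased until no
   cluster is empty.
2. **Scoring step** — every cluster is scored by the mean held-out
   accuracy of a linear SVM over ``n_folds`` stratified folds of the
   training subjects, repeated ``n_reps`` times with fresh partitions.
3. **Elimination step** — the lowest-scoring 10% of clusters are
   removed and the surviving features merged; the cluster count is
   reduced by 10% and the loop repeats until it reaches two clusters.

Test accuracy is recorded at every loop from an SVM trained on the full
training split with the surviving features.  Loop accuracies, averaged
over splits, get exact binomial tail p-values against chance
(``B(eta, rho)`` with ``rho = 0.5``) and a Bonferroni correction over
the number of loops.  Training and test subjects are never mixed: the
split's test subjects influence neither standardization, clustering,
scoring nor elimination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from causalbold._svm import score_feature_clusters, svm_fit, svm_predict

#: Positive class for sensitivity; the other label is the negative class.
POSITIVE_CLASS = "ASD"
NEGATIVE_CLASS = "TD"


@dataclass(frozen=True)
class BinomialNullConfig:
    """Null distribution B(eta, rho) for classification accuracy."""

    eta: int = 30
    rho: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")


@dataclass(frozen=True)
class RceConfig:
    """Settings of the RCE-SVM procedure."""

    n_splits: int = 50
    test_fraction: float = 0.2
    n_folds: int = 10
    n_reps: int = 50
    elimination_fraction: float = 0.10
    cluster_reduction_fraction: float = 0.10
    stop_at_clusters: int = 2
    svm_penalty: float = 1.0
    binomial_null: BinomialNullConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "elimination_fraction", "cluster_reduction_fraction"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("n_splits", "n_folds", "n_reps", "stop_at_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.svm_penalty <= 0:
            raise ValueError("svm_penalty must be positive")


@dataclass
class FeatureTable:
    """Subjects × named features with binary group labels."""

    matrix: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (subjects x features)")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match matrix columns")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("labels length must match matrix rows")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if np.any(~np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing/non-finite values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need exactly two classes with >= 2 subjects each")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LoopRecord:
    """Aggregated metrics of one RCE loop (mean over splits)."""

    n_clusters: int
    n_features: float
    accuracy: float
    sensitivity: float
    specificity: float
    p_value: float = float("nan")
    p_adjusted: float = float("nan")
    significant_after_bonferroni: bool = False


@dataclass
class RankedFeature:
    name: str
    rank: int
    n_splits_present: int
    mean_score: float


@dataclass
class RceResult:
    """Outcome of :func:`run_rce`."""

    loops: list[LoopRecord]
    final_features: list[RankedFeature]
    per_split: list[dict] = field(default_factory=list)

    @property
    def final_loop(self) -> LoopRecord:
        return self.loops[-1]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def classification_metrics(
    predicted: np.ndarray, actual: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); ``ASD`` is the positive class."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    if predicted.shape != actual.shape:
        raise ValueError("label vectors must have equal length")
    accuracy = float(np.mean(predicted == actual))
    pos = actual == POSITIVE_CLASS
    neg = ~pos
    sensitivity = float(np.mean(predicted[pos] == actual[pos])) if pos.any() else float("nan")
    specificity = float(np.mean(predicted[neg] == actual[neg])) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity


def binomial_significance(accuracy: float, null: BinomialNullConfig) -> float:
    """Exact tail probability P(X >= round(accuracy * eta)), X ~ B(eta, rho)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    successes = int(math.floor(accuracy * null.eta + 0.5))
    return float(stats.binom.sf(successes - 1, null.eta, null.rho))


def bonferroni_adjust(
    p_values: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Adjusted p = min(1, m * p) over m tests; flag = adjusted p < alpha."""
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p_values.size
    adjusted = np.minimum(1.0, m * p_values)
    return adjusted.tolist(), (adjusted < alpha).tolist()


def initial_cluster_count(
    training_features: np.ndarray, seed: int = 0
) -> int:
    """Largest cluster count (<= feature count) with no empty k-means cluster.

    ``training_features`` holds the feature vectors as rows (points in
    training-subject space).  Starting from one cluster per feature, the
    count is decreased by one until k-means fills every cluster; with
    duplicated feature patterns this settles at the number of distinct
    patterns.
    """
    points = np.asarray(training_features, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("training_features must be 2-D with >= 1 feature row")
    n = points.shape[0]
    if n == 1:
        return 1
    while n > 1:
        assignments = _kmeans_assign(points, n, seed)
        if np.unique(assignments).size == n:
            return n
        n -= 1
    return 1


def _kmeans_assign(points: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trigger a benign warning
        km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed % (2**32))
        return km.fit_predict(points)


def _effective_fold_count(y_signed: np.ndarray, n_folds: int, warn: bool = True) -> int:
    """Cap the fold count at the smaller class size (every fold must
    contain both classes — the stratified re-draw guarantee)."""
    min_class = min(int((y_signed > 0).sum()), int((y_signed < 0).sum()))
    if n_folds > min_class:
        if warn:
            warnings.warn(
                f"reducing folds from {n_folds} to {min_class} so every fold "
                "contains both classes",
                stacklevel=3,
            )
        return max(2, min_class)
    return n_folds


def _stratified_fold_ids(
    y_signed: np.ndarray, n_folds: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Random stratified partition; returns (fold id per subject, n_folds).

    Folds are filled round-robin per class after shuffling, so every
    fold contains both classes.
    """
    n_folds_eff = _effective_fold_count(y_signed, n_folds, warn=False)
    fold_ids = np.empty(y_signed.size, dtype=np.int64)
    for sign in (1.0, -1.0):
        idx = np.flatnonzero(y_signed == sign)
        idx = idx[rng.permutation(idx.size)]
        offset = int(rng.integers(n_folds_eff))
        for pos, i in enumerate(idx):
            fold_ids[i] = (pos + offset) % n_folds_eff
    return fold_ids, n_folds_eff


def _partition_block(
    y_signed: np.ndarray, n_folds: int, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Stack ``n_reps`` independent stratified partitions."""
    n_eff = _effective_fold_count(y_signed, n_folds)  # warn once per block
    ids = []
    for _ in range(n_reps):
        fold_ids, n_eff = _stratified_fold_ids(y_signed, n_eff, rng)
        ids.append(fold_ids)
    return np.vstack(ids), n_eff


def score_cluster(
    cluster_feature_submatrix: np.ndarray,
    labels: np.ndarray,
    config: RceConfig | None = None,
    seed: int = 0,
) -> float:
    """Cross-validated linear-SVM score of one feature cluster in [0, 1].

    Mean held-out accuracy over ``n_folds`` stratified folds repeated
    ``n_reps`` times, using only the cluster's features.  Deterministic
    given ``seed``.
    """
    config = config or RceConfig()
    sub = np.atleast_2d(np.asarray(cluster_feature_submatrix, dtype=float))
    if sub.shape[1] == 0:
        raise ValueError("cluster must contain at least one feature")
    y_signed = _signed_labels(np.asarray(labels))
    if np.all(y_signed > 0) or np.all(y_signed < 0):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 0x73636F]))
    fold_ids, n_folds = _partition_block(y_signed, config.n_folds, config.n_reps, rng)
    scores = score_feature_clusters(
        sub,
        y_signed,
        [np.arange(sub.shape[1])],
        fold_ids,
        n_folds,
        config.svm_penalty,
    )
    return float(scores[0])


def eliminate_bottom(
    cluster_scores: list[float] | np.ndarray,
    elimination_fraction: float = 0.10,
) -> list[int]:
    """Indices of clusters surviving elimination of the bottom fraction.

    Removes ``ceil(fraction * n_clusters)`` lowest-scoring clusters;
    among tied scores the cluster with the smaller index is removed
    first.  Returns the surviving cluster indices in ascending order.
    """
    scores = np.asarray(cluster_scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 clusters to eliminate from")
    n_remove = math.ceil(elimination_fraction * n)
    order = np.lexsort((np.arange(n), scores))  # score asc, then index asc
    removed = set(order[:n_remove].tolist())
    return [i for i in range(n) if i not in removed]


def _signed_labels(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if POSITIVE_CLASS in classes:
        return np.where(labels == POSITIVE_CLASS, 1.0, -1.0)
    return np.where(labels == classes[-1], 1.0, -1.0)


# ---------------------------------------------------------------------------
# Full procedure
# ---------------------------------------------------------------------------


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_test = max(1, int(round(test_fraction * idx.size)))
        test.extend(idx[:n_test].tolist())
        train.extend(idx[n_test:].tolist())
    return np.array(sorted(train)), np.array(sorted(test))


def _run_single_split(
    table: FeatureTable,
    config: RceConfig,
    split_seed_seq: np.random.SeedSequence,
) -> dict:
    rng = np.random.default_rng(split_seed_seq)
    kmeans_seed = int(rng.integers(2**31))
    train_idx, test_idx = _stratified_split(table.labels, config.test_fraction, rng)
    x_train = table.matrix[train_idx]
    x_test = table.matrix[test_idx]
    y_train = _signed_labels(table.labels[train_idx])
    y_test_lab = table.labels[test_idx]

    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    x_train = (x_train - mean) / sd
    x_test = (x_test - mean) / sd

    active = np.arange(table.n_features)
    n = initial_cluster_count(x_train.T, seed=kmeans_seed)
    loops: list[dict] = []
    final_scores: dict[int, float] = {}
    while True:
        n = min(n, active.size)
        if n > 1:
            assignments = _kmeans_assign(x_train[:, active].T, n, kmeans_seed + len(loops))
        else:
            assignments = np.zeros(active.size, dtype=int)
        clusters = [active[assignments == i] for i in range(n)]
        clusters = [c for c in clusters if c.size > 0]
        n = len(clusters)

        fold_ids, n_folds = _partition_block(
            y_train, config.n_folds, config.n_reps, rng
        )
        scores = score_feature_clusters(
            x_train, y_train, clusters, fold_ids, n_folds, config.svm_penalty
        ).tolist()

        w = svm_fit(x_train[:, active], y_train, config.svm_penalty)
        pred_signed = svm_predict(w, x_test[:, active])
        pred_labels = np.where(pred_signed > 0, POSITIVE_CLASS, NEGATIVE_CLASS)
        acc, sens, spec = classification_metrics(pred_labels, y_test_lab)
        loops.append(
            {
                "n_clusters": n,
                "n_features": int(active.size),
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": spec,
                "active_features": active.tolist(),
            }
        )

        if n <= config.stop_at_clusters:
            for cl, score in zip(clusters, scores):
                for feat in cl:
                    final_scores[int(feat)] = score
            break

        surviving = eliminate_bottom(scores, config.elimination_fraction)
        active = np.sort(np.concatenate([clusters[i] for i in surviving]))
        n_next = max(
            config.stop_at_clusters,
            int(math.floor((1.0 - config.cluster_reduction_fraction) * n)),
        )
        if n_next >= n:
            n_next = n - 1
        n = n_next
    return {
        "train_idx": train_idx,
        "test_idx": test_idx,
        "loops": loops,
        "final_feature_scores": final_scores,
    }


def run_rce(features: FeatureTable, config: RceConfig | None = None) -> RceResult:
    """Run the full RCE-SVM procedure on a feature table.

    Loop metrics are averaged over the train/test splits with loops
    aligned from the final loop backwards (every split terminates at
    ``stop_at_clusters`` clusters).  Each loop's mean accuracy receives
    an exact binomial p-value against ``B(eta, rho)`` with ``eta``
    defaulting to the number of subjects, and a Bonferroni correction
    over the number of loops.  ``final_features`` ranks the features
    surviving any split's final loop by how many splits retained them
    and by their mean final cluster score.  Fully seeded.
    """
    config = config or RceConfig()
    if features.n_features < config.stop_at_clusters:
        raise ValueError("fewer features than the stopping cluster count")
    root = np.random.SeedSequence([config.seed, 0x726365])
    split_seqs = root.spawn(config.n_splits)
    splits = [_run_single_split(features, config, seq) for seq in split_seqs]

    max_loops = max(len(s["loops"]) for s in splits)
    loops: list[LoopRecord] = []
    for back in range(max_loops - 1, -1, -1):
        rows = [
            s["loops"][len(s["loops"]) - 1 - back]
            for s in splits
            if len(s["loops"]) > back
        ]
        loops.append(
            LoopRecord(
                n_clusters=int(np.max([r["n_clusters"] for r in rows])),
                n_features=float(np.mean([r["n_features"] for r in rows])),
                accuracy=float(np.mean([r["accuracy"] for r in rows])),
                sensitivity=float(np.nanmean([r["sensitivity"] for r in rows])),
                specificity=float(np.nanmean([r["specificity"] for r in rows])),
            )
        )

    null = config.binomial_null or BinomialNullConfig(eta=features.n_subjects)
    p_values = [binomial_significance(lp.accuracy, null) for lp in loops]
    adjusted, flags = bonferroni_adjust(p_values, null.alpha)
    for lp, p, p_adj, flag in zip(loops, p_values, adjusted, flags):
        lp.p_value = p
        lp.p_adjusted = p_adj
        lp.significant_after_bonferroni = flag

    # Consensus survivors: features present in the final loop of at least
    # half the splits, ranked by presence count then mean final score.
    # (Individual splits end with very few features; the majority filter
    # suppresses single-split flukes.)
    presence: dict[int, list[float]] = {}
    for s in splits:
        for feat, score in s["final_feature_scores"].items():
            presence.setdefault(feat, []).append(score)
    min_presence = max(1, (config.n_splits + 1) // 2)
    consensus = {f: sc for f, sc in presence.items() if len(sc) >= min_presence}
    if not consensus:  # no feature reaches a majority; fall back to all
        consensus = presence
    ranked = sorted(
        consensus.items(),
        key=lambda kv: (-len(kv[1]), -float(np.mean(kv[1])), kv[0]),
    )
    final_features = [
        RankedFeature(
            name=features.feature_names[feat],
            rank=rank + 1,
            n_splits_present=len(scores),
            mean_score=float(np.mean(scores)),
        )
        for rank, (feat, scores) in enumerate(ranked)
    ]
    per_split = [
        {
            "train_idx": s["train_idx"].tolist(),
            "test_idx": s["test_idx"].tolist(),
            "loops": s["loops"],
        }
        for s in splits
    ]
    return RceResult(loops=loops, final_features=final_features, per_split=per_split)
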