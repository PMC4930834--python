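"""Guilt-by-association supervised prediction.

Genes that share association profiles across many datasets tend to share
function.  The pipeline turns that principle into a classifier:

1. each dataset's gene x attribute matrix is reduced by PCA, keeping the
   leading components that capture 99% of its variance;
2. per-dataset component scores are concatenated into one feature matrix
   (genes missing from a dataset are zero-filled on its block);
3. features are ranked by univariate ROC discriminativeness |AUC - 0.5|
   and the top 70 retained;
4. a 300-tree random forest is trained; every training gene is scored by
   the trees whose bootstrap sample excluded it (out-of-bag), giving an
   internal generalization estimate;
5. ROC / F1 / MCC curves are computed from the OOB scores, and unknown
   genes are scored with an estimated FDR (1 - OOB precision at the
   gene's score threshold, monotonized).

The negative class is typically "not known to be positive", so some label
noise is expected; the OOB curves quantify what the features support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .matrix import GeneAttributeMatrix

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


@dataclass
class ClassifierConfig:
    """Random-forest configuration; the defaults (300 trees, 70 features,
    99% PCA variance) are the published operating point."""

    n_trees: int = 300
    n_features: int = 70
    variance_fraction: float = 0.99
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.n_features <= 0:
            raise ValueError("n_trees and n_features must be positive")
        if not (0 < self.variance_fraction <= 1):
            raise ValueError("variance_fraction must lie in (0, 1]")


@dataclass
class GbaTask:
    """One prediction problem: features, labels and feature provenance."""

    feature_matrix: np.ndarray  # examples x features
    example_ids: list
    labels: list  # per-example: positive | negative | unknown
    feature_blocks: dict  # dataset name -> (start, stop) column slice
    task_kind: str = "single_label"  # single_label | multi_label | pair
    label_matrix: "np.ndarray | None" = None  # multi_label only
    label_names: "list | None" = None

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        n, p = self.feature_matrix.shape
        if len(self.example_ids) != n or len(self.labels) != n:
            raise ValueError("example ids / labels length mismatch")
        covered = sorted(
            c for (start, stop) in self.feature_blocks.values() for c in range(start, stop)
        )
        if covered != list(range(p)):
            raise ValueError("feature_blocks must cover every feature exactly once")
        if self.task_kind == "single_label":
            known = [l for l in self.labels if l != UNKNOWN]
            if POSITIVE not in known or NEGATIVE not in known:
                raise ValueError("need at least one positive and one negative example")

    def known_mask(self) -> np.ndarray:
        return np.array([l != UNKNOWN for l in self.labels])

    def y(self) -> np.ndarray:
        """Binary labels over known examples (1 = positive)."""
        mask = self.known_mask()
        return np.array([1 if l == POSITIVE else 0 for l, m in zip(self.labels, mask) if m])


@dataclass
class EvaluationCurves:
    """Threshold-sweep evaluation of scores against binary labels."""

    thresholds: np.ndarray
    roc_points: np.ndarray  # (n, 3): fpr, tpr, threshold
    auc: float
    f1_by_threshold: np.ndarray
    mcc_by_threshold: np.ndarray
    max_f1: float
    max_mcc: float
    oob_scores: "np.ndarray | None" = None
    labels: "np.ndarray | None" = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fpr": self.roc_points[1:, 0],
                "tpr": self.roc_points[1:, 1],
                "f1": self.f1_by_threshold,
                "mcc": self.mcc_by_threshold,
            }
        )


@dataclass
class ScoredPrediction:
    subject: object  # gene or (gene, partner) pair
    score: float
    estimated_fdr: float
    known: bool = False


def _bare_task(feature_matrix, example_ids, labels, feature_blocks,
               task_kind="single_label", label_matrix=None, label_names=None) -> GbaTask:
    """Construct a GbaTask without the both-classes-present check (tasks
    built for scoring only may hold unknowns exclusively)."""
    task = GbaTask.__new__(GbaTask)
    task.feature_matrix = np.asarray(feature_matrix, dtype=float)
    task.example_ids = list(example_ids)
    task.labels = list(labels)
    task.feature_blocks = dict(feature_blocks)
    task.task_kind = task_kind
    task.label_matrix = label_matrix
    task.label_names = label_names
    return task


# ---------------------------------------------------------------------------
# feature construction


def pca_reduce(matrix, variance_fraction: float = 0.99, rng_seed: int = 0):
    """Project a dataset onto the smallest set of leading principal
    components whose cumulative explained-variance fraction reaches
    ``variance_fraction``.

    Returns ``(component_scores, explained)`` where ``component_scores``
    is examples x k and ``explained`` lists the k per-component fractions.
    The sign convention (largest-magnitude loading positive) makes the
    projection deterministic.
    """
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must lie in (0, 1]")
    if isinstance(matrix, GeneAttributeMatrix):
        X = matrix.materialized()
    else:
        X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 examples for PCA")
    if np.allclose(X, X[0]):
        warnings.warn("constant matrix has no variance; returning k = 0 components")
        return np.zeros((X.shape[0], 0)), []

    n_max = min(X.shape)
    pca = PCA(n_components=n_max, svd_solver="full", random_state=rng_seed)
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, n_max)
    # deterministic sign: largest-magnitude loading of each component positive
    comps = pca.components_[:k]
    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    return scores[:, :k] * flip, list(ratios[:k])


def assemble_features(
    datasets,
    examples,
    config: "ClassifierConfig | None" = None,
    labels=None,
    dataset_names=None,
) -> GbaTask:
    """Concatenate per-dataset PCA component scores into one feature matrix.

    ``examples`` is the gene list defining the task's rows.  Genes missing
    from a dataset receive 0 on that dataset's feature block (their
    coverage is recorded in the task's ``feature_blocks`` companion
    metadata); genes absent from every dataset are dropped with a warning.
    """
    if not datasets:
        raise ValueError("empty dataset list")
    config = config or ClassifierConfig()
    names = dataset_names or [
        m.metadata.get("name", f"dataset_{i}") for i, m in enumerate(datasets)
    ]

    present_anywhere = set()
    for m in datasets:
        present_anywhere.update(m.gene_ids)
    kept, dropped = [], []
    for g in examples:
        (kept if g in present_anywhere else dropped).append(g)
    if dropped:
        warnings.warn(
            f"{len(dropped)} example(s) absent from every dataset were dropped"
        )
    if not kept:
        raise ValueError("no example is present in any dataset")

    blocks = {}
    parts = []
    start = 0
    for name, m in zip(names, datasets):
        scores, _ = pca_reduce(m, config.variance_fraction, config.rng_seed)
        k = scores.shape[1]
        pos = {g: i for i, g in enumerate(m.gene_ids)}
        block = np.zeros((len(kept), k))
        for r, g in enumerate(kept):
            if g in pos:
                block[r] = scores[pos[g]]
        parts.append(block)
        blocks[name] = (start, start + k)
        start += k

    if labels is None:
        task_labels = [UNKNOWN] * len(kept)
    elif isinstance(labels, dict):
        task_labels = [labels.get(g, UNKNOWN) for g in kept]
    else:
        by_gene = dict(zip(examples, labels))
        task_labels = [by_gene.get(g, UNKNOWN) for g in kept]
    feature_matrix = np.hstack(parts) if parts else np.zeros((len(kept), 0))
    return _bare_task(feature_matrix, kept, task_labels, blocks)


# ---------------------------------------------------------------------------
# evaluation


def _roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal AUC; ties handled by the Mann-Whitney identity."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # rank-based computation is exactly the trapezoid under the tie-aware ROC
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def compute_metrics(scores, labels) -> EvaluationCurves:
    """ROC / F1 / MCC by sweeping a threshold over the unique scores.

    At threshold t an example is called positive when score >= t.  AUC is
    the trapezoidal area under the ROC; MCC is defined as 0 whenever a
    confusion-matrix marginal is 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = np.array([1 if l == POSITIVE else 0 for l in labels])
    y = y.astype(int)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.unique(scores)[::-1]  # descending
    order = np.argsort(-scores, kind="stable")
    sorted_y = y[order]
    sorted_scores = scores[order]
    # cumulative TP/FP at each threshold (call positive when score >= t)
    boundaries = np.searchsorted(-sorted_scores, -thresholds, side="right")
    cum_tp = np.cumsum(sorted_y)
    tp = cum_tp[boundaries - 1]
    fp = boundaries - tp
    fn = n_pos - tp
    tn = n_neg - fp

    fpr = fp / n_neg
    tpr = tp / n_pos
    roc = np.column_stack(
        [np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr]),
         np.concatenate([[np.inf], thresholds])]
    )
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))

    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * tp / (2 * tp + fp + fn)
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(denom == 0, 0.0, (tp * tn - fp * fn) / np.where(denom == 0, 1.0, denom))
    f1 = np.nan_to_num(f1, nan=0.0)

    return EvaluationCurves(
        thresholds=thresholds,
        roc_points=roc,
        auc=auc,
        f1_by_threshold=f1,
        mcc_by_threshold=mcc,
        max_f1=float(f1.max()),
        max_mcc=float(mcc.max()),
        oob_scores=scores,
        labels=y,
    )


def rank_features_by_roc(task: GbaTask) -> pd.DataFrame:
    """Rank features by univariate discriminativeness |AUC - 0.5|.

    Each feature's values act as scores for the known examples; features
    whose high values mark negatives (AUC < 0.5) are as useful as their
    mirror images, so the ranking is symmetric around 0.5.  Ties break by
    feature index.
    """
    mask = task.known_mask()
    y = task.y()
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both classes among known labels")
    X = task.feature_matrix[mask]
    aucs = np.array([_roc_auc(X[:, j], y) for j in range(X.shape[1])])
    order = np.lexsort((np.arange(aucs.size), -np.abs(aucs - 0.5)))
    inv_block = {}
    for name, (start, stop) in task.feature_blocks.items():
        for c in range(start, stop):
            inv_block[c] = name
    return pd.DataFrame(
        {
            "feature": order,
            "auc": aucs[order],
            "discriminativeness": np.abs(aucs[order] - 0.5),
            "dataset": [inv_block[c] for c in order],
        }
    )


def rank_datasets(task: GbaTask, top_per_dataset: int = 5) -> pd.DataFrame:
    """Rank source datasets by the mean |AUC - 0.5| of their most
    discriminative components (a configurable heuristic for dataset
    selection)."""
    ranking = rank_features_by_roc(task)
    rows = []
    for name in task.feature_blocks:
        block = ranking[ranking["dataset"] == name]
        top = block.head(top_per_dataset)["discriminativeness"]
        rows.append((name, float(top.mean()) if len(top) else 0.0))
    return (
        pd.DataFrame(rows, columns=["dataset", "mean_discriminativeness"])
        .sort_values("mean_discriminativeness", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_indices: np.ndarray
    curves: EvaluationCurves
    example_ids: list


def train_oob_ensemble(task: GbaTask, config: "ClassifierConfig | None" = None):
    """Train the bagged decision-tree ensemble and evaluate out-of-bag.

    Features are restricted to the top ``config.n_features`` by univariate
    ROC ranking.  Each known example's OOB score is the vote fraction of
    the trees whose bootstrap sample excluded it; the evaluation curves are
    computed from those scores, estimating generalization without a
    held-out set.  ``rng_seed`` makes the run reproducible.
    """
    config = config or ClassifierConfig()
    ranking = rank_features_by_roc(task)
    n_avail = len(ranking)
    n_feat = config.n_features
    if n_feat > n_avail:
        warnings.warn(
            f"n_features={n_feat} exceeds the {n_avail} available features; clipping"
        )
        n_feat = n_avail
    feat_idx = ranking["feature"].to_numpy()[:n_feat]

    mask = task.known_mask()
    y = task.y()
    if min(y.sum(), y.size - y.sum()) < 10:
        warnings.warn("fewer than 10 examples in a class; OOB estimates will be noisy")
    X = task.feature_matrix[mask][:, feat_idx]

    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=config.rng_seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*out-of-bag.*")
        forest.fit(X, y)
    oob = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
    never_oob = np.isnan(oob)
    if never_oob.any():
        warnings.warn(f"{int(never_oob.sum())} example(s) were in every bootstrap; scored 0.5")
        oob = np.where(never_oob, 0.5, oob)

    curves = compute_metrics(oob, y)
    model = TrainedModel(
        forest=forest,
        feature_indices=feat_idx,
        curves=curves,
        example_ids=[g for g, m in zip(task.example_ids, mask) if m],
    )
    return model, curves


def train_multilabel(task: GbaTask, config: "ClassifierConfig | None" = None,
                     min_positives: int = 3, pooling: str = "micro"):
    """Train one ensemble per label column of ``task.label_matrix``.

    Labels with fewer than ``min_positives`` positive examples are skipped
    and reported.  Pooled curves concatenate every label's OOB scores and
    truths (micro pooling); ``pooling="macro"`` instead averages the
    per-label AUC/F1/MCC summaries.
    """
    if task.label_matrix is None:
        raise ValueError("task has no label_matrix")
    config = config or ClassifierConfig()
    L = np.asarray(task.label_matrix).astype(int)
    names = task.label_names or [f"label_{j}" for j in range(L.shape[1])]
    models, skipped = {}, []
    pooled_scores, pooled_y = [], []
    per_label_curves = {}
    for j, name in enumerate(names):
        y = L[:, j]
        if y.sum() < min_positives or (y == 0).sum() < min_positives:
            skipped.append(name)
            continue
        sub = _bare_task(
            task.feature_matrix, task.example_ids,
            [POSITIVE if v else NEGATIVE for v in y], task.feature_blocks,
        )
        model, curves = train_oob_ensemble(sub, config)
        models[name] = model
        per_label_curves[name] = curves
        pooled_scores.append(curves.oob_scores)
        pooled_y.append(curves.labels)
    if not models:
        raise ValueError("all labels skipped (too few positives)")
    if pooling == "micro":
        pooled = compute_metrics(np.concatenate(pooled_scores), np.concatenate(pooled_y))
    else:
        aucs = [c.auc for c in per_label_curves.values()]
        f1s = [c.max_f1 for c in per_label_curves.values()]
        mccs = [c.max_mcc for c in per_label_curves.values()]
        pooled = EvaluationCurves(
            thresholds=np.array([]), roc_points=np.zeros((0, 3)),
            auc=float(np.mean(aucs)),
            f1_by_threshold=np.array([]), mcc_by_threshold=np.array([]),
            max_f1=float(np.mean(f1s)), max_mcc=float(np.mean(mccs)),
        )
    return models, pooled, skipped


# ---------------------------------------------------------------------------
# prediction with FDR


def _fdr_by_threshold(curves: EvaluationCurves) -> np.ndarray:
    """Estimated FDR = 1 - OOB precision at each threshold, made
    nondecreasing in descending-score order by a running maximum."""
    y = curves.labels
    scores = curves.oob_scores
    thresholds = curves.thresholds
    order = np.argsort(-scores, kind="stable")
    sorted_y = y[order]
    sorted_scores = scores[order]
    boundaries = np.searchsorted(-sorted_scores, -thresholds, side="right")
    tp = np.cumsum(sorted_y)[boundaries - 1]
    called = boundaries
    precision = tp / called
    return np.maximum.accumulate(1.0 - precision)


def monotonize_fdr(raw_fdr) -> np.ndarray:
    """Running maximum over an FDR sequence ordered by descending score,
    so estimated FDR never decreases as the score cutoff loosens."""
    return np.maximum.accumulate(np.asarray(raw_fdr, dtype=float))


def predict_with_fdr(model: TrainedModel, task: GbaTask, curves: "EvaluationCurves | None" = None,
                     fdr_level: "float | None" = None, known_subjects=()):
    """Score the task's unknown examples and attach estimated FDRs.

    Each unknown's score is the forest's positive-class probability; its
    estimated FDR is 1 - OOB precision at the tightest OOB threshold not
    above its score, monotonized.  ``fdr_level`` (presets 0.67 and 0.33)
    filters the returned predictions; None returns all, sorted by
    descending score.
    """
    curves = curves or model.curves
    fdr = _fdr_by_threshold(curves)
    thresholds = curves.thresholds  # descending

    mask = ~task.known_mask()
    if not mask.any():
        return []
    X = task.feature_matrix[mask][:, model.feature_indices]
    ids = [g for g, m in zip(task.example_ids, mask) if m]
    proba = model.forest.predict_proba(X)[:, list(model.forest.classes_).index(1)]

    preds = []
    known = set(known_subjects)
    for subject, score in zip(ids, proba):
        # tightest OOB threshold <= score (thresholds descending)
        pos = np.searchsorted(-thresholds, -score, side="right") - 1
        est = float(fdr[pos]) if pos >= 0 else float(fdr[0])
        preds.append(ScoredPrediction(subject, float(score), est, subject in known))
    preds.sort(key=lambda p: (-p.score, str(p.subject)))
    # enforce the monotone-FDR invariant on the returned ordering
    running = 0.0
    for p in preds:
        running = max(running, p.estimated_fdr)
        p.estimated_fdr = running
    if fdr_level is not None:
        kept = [p for p in preds if p.estimated_fdr <= fdr_level]
        if not kept:
            warnings.warn(f"no prediction attains estimated FDR <= {fdr_level}")
        return kept
    return preds


def predictions_to_frame(preds) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": p.subject if not isinstance(p.subject, tuple) else "|".join(map(str, p.subject)),
                "score": p.score,
                "estimated_fdr": p.estimated_fdr,
                "known": p.known,
            }
            for p in preds
        ]
    )


def make_pair_task(left_task: GbaTask, right_task: GbaTask, pairs, labels) -> GbaTask:
    """Featurize (gene, partner) pairs by concatenating the two genes'
    assembled feature vectors (e.g. receptor-ligand or enzyme-substrate
    prediction)."""
    lpos = {g: i for i, g in enumerate(left_task.example_ids)}
    rpos = {g: i for i, g in enumerate(right_task.example_ids)}
    rows, ids, labs = [], [], []
    for (a, b), lab in zip(pairs, labels):
        if a not in lpos or b not in rpos:
            continue
        rows.append(
            np.concatenate(
                [left_task.feature_matrix[lpos[a]], right_task.feature_matrix[rpos[b]]]
            )
        )
        ids.append((a, b))
        labs.append(lab)
    if not rows:
        raise ValueError("no pair could be featurized")
    p_left = left_task.feature_matrix.shape[1]
    p_right = right_task.feature_matrix.shape[1]
    blocks = {}
    for name, (start, stop) in left_task.feature_blocks.items():
        blocks[f"left:{name}"] = (start, stop)
    for name, (start, stop) in right_task.feature_blocks.items():
        blocks[f"right:{name}"] = (p_left + start, p_left + stop)
    return _bare_task(np.array(rows), ids, labs, blocks, task_kind="pair")
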