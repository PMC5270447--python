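"""Evaluation protocols: power curves, feature selection, and CV AUC.

Three protocols mirror how prognostic subnetwork markers are judged in
practice:

* **Top-K power curves** — markers ranked on one dataset are re-scored
  on another (class models refitted there), and the mean absolute
  activity t of the top K = 10..50 markers measures how much
  discriminative power the ranking retains across cohorts.
* **Forward feature selection** — a greedy pass over the ranked markers
  that keeps a marker only if it strictly increases the AUC of a linear
  discriminant classifier on a held-out selection fold.
* **Cross-dataset classification** — markers and features are chosen on
  a source cohort only (3-fold split: two folds rank the markers, one
  selects the features; class-conditional densities come from the full
  source); a fresh LDA is then trained and tested on stratified 5-fold
  partitions of an independent target cohort, and the AUC is averaged
  over many random partitions.

All partitioning is stratified by class and driven by the caller's
seed, so identical seeds reproduce identical results bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_network import ExpressionDataset
from .marker_pipeline import (
    SubnetworkMarker,
    infer_activity,
    refit_marker_models,
    score_and_rank,
)

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (10, 20, 30, 40, 50)
DEFAULT_N_PARTITIONS = 100


@dataclass
class PowerCurve:
    """Mean absolute activity t of the top-K markers per K."""

    K_values: list
    mean_abs_t: list
    source_dataset: str = ""
    eval_dataset: str = ""
    n_dropped: int = 0


@dataclass
class ClassificationResult:
    """AUC summary of a repeated cross-validation experiment."""

    selected_markers: list
    auc_mean: float
    auc_sd: float
    n_partitions: int
    protocol: str
    aucs: np.ndarray = field(default=None, repr=False)


def activity_matrix(markers, dataset: ExpressionDataset) -> np.ndarray:
    """Samples x markers feature matrix of inferred activities."""
    cols = [infer_activity(m, dataset).activities for m in markers]
    return np.column_stack(cols)


def power_curve(
    ranked_markers,
    eval_dataset: ExpressionDataset,
    K_values=DEFAULT_K_VALUES,
    refit: bool = True,
    variant: str = "welch",
    source_name: str = "",
) -> PowerCurve:
    """Mean |activity t| of the top-K markers, re-evaluated on a dataset.

    The marker order is the *original* ranking; class models are
    refitted on ``eval_dataset`` (set ``refit=False`` to keep the
    models the markers carry).  Markers with genes missing from the
    evaluation dataset are dropped with a warning and counted.
    """
    if refit:
        usable = refit_marker_models(ranked_markers, eval_dataset)
    else:
        usable = [m for m in ranked_markers if all(eval_dataset.has_gene(g) for g in m.members)]
    n_dropped = len(ranked_markers) - len(usable)
    pos = eval_dataset.pos_mask
    abs_t = []
    for m in usable:
        act = infer_activity(m, eval_dataset).activities
        from .gene_statistics import t_statistic

        abs_t.append(abs(t_statistic(act[pos], act[~pos], variant)))
    means = []
    for K in K_values:
        head = abs_t[: min(K, len(abs_t))]
        means.append(float(np.mean(head)) if head else float("nan"))
    return PowerCurve(
        K_values=list(K_values),
        mean_abs_t=means,
        source_dataset=source_name,
        eval_dataset=eval_dataset.name,
        n_dropped=n_dropped,
    )


def _fit_lda(X, y):
    """Two-class LDA; the SVD solver tolerates singular scatter matrices."""
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(X, y)
    return lda


def _auc(lda, X, y) -> float:
    return float(roc_auc_score(y, lda.decision_function(X)))


def forward_select(
    markers_ranked,
    train_set: ExpressionDataset,
    select_set: ExpressionDataset,
) -> list:
    """Greedy AUC-driven forward pass over the ranked markers.

    The classifier is trained on ``train_set`` activities and judged on
    ``select_set``; a candidate is kept only if the selection-fold AUC
    strictly increases over the incumbent feature set (empty-set
    baseline 0.5).  Activities use the class models the markers carry.
    """
    selected = []
    best_auc = 0.5
    y_train = train_set.pos_mask.astype(int)
    y_select = select_set.pos_mask.astype(int)
    train_cols = {id(m): infer_activity(m, train_set).activities for m in markers_ranked}
    select_cols = {id(m): infer_activity(m, select_set).activities for m in markers_ranked}
    for cand in markers_ranked:
        feats = selected + [cand]
        X_train = np.column_stack([train_cols[id(m)] for m in feats])
        X_select = np.column_stack([select_cols[id(m)] for m in feats])
        lda = _fit_lda(X_train, y_train)
        auc = _auc(lda, X_select, y_select)
        if auc > best_auc:
            best_auc = auc
            selected = feats
    return selected


def _stratified_split(labels: np.ndarray, n_splits: int, seed: int):
    """First (train, test) split of a seeded stratified K-fold shuffle."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed) % (2**31))
    return next(iter(skf.split(np.zeros(len(labels)), labels.astype(int))))


def _three_fold_source_split(labels: np.ndarray, seed: int):
    """Source split: one fold for feature selection, two for marker ranking."""
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=int(seed) % (2**31))
    fs_idx = None
    for _, test_idx in skf.split(np.zeros(len(labels)), labels.astype(int)):
        fs_idx = test_idx
        break
    me_idx = np.setdiff1d(np.arange(len(labels)), fs_idx)
    return me_idx, fs_idx


def select_features_on_source(
    source: ExpressionDataset,
    markers,
    seed: int,
    top_k: int = 50,
    variant: str = "welch",
):
    """Rank markers and select features using the source cohort only.

    ``markers`` are the post-processed candidate markers with class
    models fitted on the *full* source (the density-estimation choice of
    the protocol).  Two of three stratified folds rank the markers by
    activity t; the third drives the greedy AUC selection.  Returns the
    selected markers (falling back to the top-ranked one if the greedy
    pass keeps nothing).
    """
    me_idx, fs_idx = _three_fold_source_split(source.labels, seed)
    marker_eval = source.subset_samples(me_idx, name=f"{source.name}[marker-eval]")
    feat_sel = source.subset_samples(fs_idx, name=f"{source.name}[feature-selection]")
    ranked = score_and_rank(list(markers), marker_eval, top_k=top_k, variant=variant)
    selected = forward_select(ranked, marker_eval, feat_sel)
    if not selected:
        logger.warning("forward selection kept no markers; falling back to top-1")
        selected = ranked[:1]
    return selected


def _evaluate_on_target(
    target: ExpressionDataset,
    selected,
    seed: int,
    n_partitions: int,
    refit_models: bool,
) -> np.ndarray:
    """AUCs over repeated stratified 5-fold partitions of the target."""
    aucs = np.empty(n_partitions)
    y = target.pos_mask.astype(int)
    for rep in range(n_partitions):
        rep_seed = (int(seed) * 100003 + rep) % (2**31)
        train_idx, test_idx = _stratified_split(target.labels, 5, rep_seed)
        if refit_models:
            train_ds = target.subset_samples(train_idx)
            feats = refit_marker_models(selected, train_ds)
            if not feats:
                raise ValueError("no selected marker is measurable on the target")
        else:
            feats = selected
        X = activity_matrix(feats, target)
        lda = _fit_lda(X[train_idx], y[train_idx])
        aucs[rep] = _auc(lda, X[test_idx], y[test_idx])
    return aucs


def cross_dataset_experiment(
    marker_source: ExpressionDataset,
    eval_target: ExpressionDataset,
    seed: int,
    markers=None,
    network=None,
    alpha: float = 0.5,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    top_k: int = 50,
    variant: str = "welch",
) -> ClassificationResult:
    """Identify markers/features on one cohort, classify an independent one.

    The marker list and feature mask are frozen before the target is
    touched; on the target side, class models for the activity features
    are refitted on each partition's training folds (expression scales
    differ across platforms), an LDA is trained on four folds and tested
    on the fifth, and the AUC is averaged over ``n_partitions`` random
    stratified partitions.
    """
    if markers is None:
        from .marker_pipeline import identify_markers

        if network is None:
            raise ValueError("pass either precomputed markers or a network")
        markers, _ = identify_markers(
            marker_source, network, alpha=alpha, top_k=None, variant=variant, seed=seed
        )
    selected = select_features_on_source(
        marker_source, markers, seed=seed, top_k=top_k, variant=variant
    )
    aucs = _evaluate_on_target(
        eval_target, selected, seed=seed, n_partitions=n_partitions, refit_models=True
    )
    return ClassificationResult(
        selected_markers=selected,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_partitions=n_partitions,
        protocol="cross_dataset",
        aucs=aucs,
    )


def within_dataset_experiment(
    dataset: ExpressionDataset,
    markers,
    seed: int,
    n_partitions: int = DEFAULT_N_PARTITIONS,
) -> ClassificationResult:
    """Repeated stratified 5-fold CV on one cohort with precomputed markers.

    Markers (and their class models) come from the full dataset — the
    protocol's stated shortcut, accepted because re-identifying markers
    per partition is prohibitively expensive — so only the LDA weights
    are refit per partition.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("within_dataset_experiment needs at least one marker")
    aucs = _evaluate_on_target(
        dataset, markers, seed=seed, n_partitions=n_partitions, refit_models=False
    )
    return ClassificationResult(
        selected_markers=markers,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_partitions=n_partitions,
        protocol="within_dataset",
        aucs=aucs,
    )
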