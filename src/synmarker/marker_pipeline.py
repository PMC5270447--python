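"""From raw clusters to ranked subnetwork markers.

A cluster found by affinity propagation may still carry genes whose
discriminative power lags behind the rest.  Post-processing clusters the
members' absolute t-scores with one-dimensional k-means, using
k = floor(log(n) + 1) groups, and removes the group with the lowest mean
score.  Marker activity for a sample is the sum of the member genes'
log-likelihood ratios; the marker's own discriminative power is the
two-sample t of that activity between classes, and markers are ranked by
its magnitude.

The one-dimensional k-means is solved exactly by dynamic programming
over contiguous partitions of the sorted scores (optimal clusters of
scalars are contiguous), so post-processing has no initialisation
randomness; a seeded Lloyd fallback covers the (unrealistically large)
k > 12 regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import MissingGeneError
from .gene_statistics import (
    GeneClassModel,
    fit_class_models,
    llr_matrix,
    t_statistic,
)
from .io_network import ExpressionDataset

logger = logging.getLogger(__name__)

EXACT_KMEANS_MAX_K = 12


@dataclass
class SubnetworkMarker:
    """An exemplar gene plus the member genes it represents."""

    exemplar: str
    members: list
    member_models: list = field(default_factory=list)
    activity_t: float | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("a marker needs at least one member gene")
        if self.member_models and len(self.member_models) != len(self.members):
            raise ValueError("member_models must align with members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ActivityProfile:
    """Per-sample activity A(x) of one marker on one dataset."""

    marker: SubnetworkMarker
    activities: np.ndarray


def kmeans_1d(values, k: int, seed: int = 0) -> np.ndarray:
    """Exact 1-D k-means labels (SSE-optimal, contiguous on sorted values).

    Dynamic programming over contiguous partitions; for k above
    ``EXACT_KMEANS_MAX_K`` falls back to a seeded Lloyd run.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k <= 1 or n <= k:
        if n <= k:
            return np.arange(n)
        return np.zeros(n, dtype=int)
    if k > EXACT_KMEANS_MAX_K:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(values.reshape(-1, 1))

    order = np.argsort(values, kind="stable")
    x = values[order]
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i, j):  # cost of segment x[i:j]
        m = j - i
        s = pref[j] - pref[i]
        return (pref2[j] - pref2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = np.inf, g - 1
            for i in range(g - 1, j):
                c = cost[g - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[g, j] = best
            back[g, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for g in range(k, 0, -1):
        i = back[g, j]
        labels_sorted[i:j] = g - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def postprocess_cluster(members, scores, seed: int = 0) -> list:
    """Drop the lowest-scoring k-means group from a cluster's members.

    ``scores`` maps gene id to absolute t.  The group count is
    k = floor(log(n) + 1) (natural log); with k = 1, n <= 2, or all
    scores tied the cluster is returned unchanged — removal must never
    empty a marker.
    """
    members = list(members)
    n = len(members)
    if n <= 2:
        return members
    abs_t = np.array([abs(float(scores[g])) for g in members])
    k = int(np.floor(np.log(n) + 1.0))
    if k <= 1 or np.allclose(abs_t, abs_t[0]):
        return members
    labels = kmeans_1d(abs_t, k, seed=seed)
    group_means = [abs_t[labels == g].mean() for g in range(labels.max() + 1)]
    lowest = int(np.argmin(group_means))
    survivors = [g for g, lab in zip(members, labels) if lab != lowest]
    if not survivors:  # k-means collapsed to one effective group
        return members
    return survivors


def clusters_to_markers(
    cluster_map: dict,
    scores,
    models,
    seed: int = 0,
) -> list:
    """Post-process every cluster and package the survivors as markers.

    ``cluster_map`` maps exemplar -> member list (from a
    ClusterSolution); ``scores`` maps gene -> absolute t; ``models``
    maps gene -> GeneClassModel.  If post-processing removes the
    exemplar, the surviving member with the highest absolute t becomes
    the marker's representative.
    """
    score_map = scores if isinstance(scores, dict) else {s.gene_id: s.abs_t for s in scores}
    model_map = models if isinstance(models, dict) else {m.gene_id: m for m in models}
    markers = []
    for exemplar, members in sorted(cluster_map.items()):
        survivors = postprocess_cluster(members, score_map, seed=seed)
        if exemplar not in survivors:
            exemplar = max(survivors, key=lambda g: (score_map[g], g))
        markers.append(
            SubnetworkMarker(
                exemplar=exemplar,
                members=sorted(survivors),
                member_models=[model_map[g] for g in sorted(survivors)],
            )
        )
    return markers


def infer_activity(marker: SubnetworkMarker, dataset: ExpressionDataset) -> ActivityProfile:
    """Marker activity per sample: the sum of member-gene LLRs."""
    absent = [g for g in marker.members if not dataset.has_gene(g)]
    if absent:
        raise MissingGeneError(f"marker member(s) absent from dataset: {absent}")
    rows = np.vstack([dataset.row(g) for g in marker.members])
    llr = llr_matrix(marker.member_models, rows)
    return ActivityProfile(marker=marker, activities=llr.sum(axis=0))


def score_and_rank(
    markers,
    dataset: ExpressionDataset,
    top_k: int | None = 50,
    variant: str = "welch",
) -> list:
    """Rank markers by the magnitude of their activity t on the dataset.

    Each marker's ``activity_t`` is set in place; ties in |t| break
    toward the smaller exemplar id, and ``top_k=None`` returns the whole
    ranking.
    """
    if not markers:
        raise ValueError("score_and_rank needs at least one marker")
    pos = dataset.pos_mask
    for m in markers:
        act = infer_activity(m, dataset).activities
        m.activity_t = t_statistic(act[pos], act[~pos], variant)
    ranked = sorted(markers, key=lambda m: (-abs(m.activity_t), m.exemplar))
    return ranked if top_k is None else ranked[:top_k]


@dataclass
class MarkerSetStats:
    """Size and gene-overlap statistics of two marker lists."""

    avg_size_a: float
    avg_size_b: float
    unique_genes_a: int
    unique_genes_b: int
    overlap: float


def marker_set_stats(list_a, list_b) -> MarkerSetStats:
    """Average sizes, unique-gene counts, and intersection/union overlap."""
    genes_a = set().union(*(m.members for m in list_a)) if list_a else set()
    genes_b = set().union(*(m.members for m in list_b)) if list_b else set()
    union = genes_a | genes_b
    overlap = len(genes_a & genes_b) / len(union) if union else 0.0
    return MarkerSetStats(
        avg_size_a=float(np.mean([m.size for m in list_a])) if list_a else 0.0,
        avg_size_b=float(np.mean([m.size for m in list_b])) if list_b else 0.0,
        unique_genes_a=len(genes_a),
        unique_genes_b=len(genes_b),
        overlap=overlap,
    )


def identify_markers(
    dataset: ExpressionDataset,
    network,
    alpha: float = 0.5,
    preference_quantile: float = 0.01,
    damping: float = 0.9,
    max_iter: int = 2000,
    stable_iters: int = 100,
    top_k: int | None = 50,
    variant: str = "welch",
    seed: int = 0,
):
    """End-to-end marker identification on one dataset.

    Runs the whole chain: induce the network onto the dataset's genes,
    fit per-gene class models, score genes and distance-<=2 pairs, build
    the asymmetric similarity, cluster by affinity propagation,
    post-process, and rank by activity t.  Returns ``(ranked_markers,
    cluster_solution)``.
    """
    from .affinity_propagation import run as ap_run
    from .gene_statistics import pair_t_values, t_array
    from .io_network import induce_common
    from .similarity import similarity_from_arrays

    net = induce_common(network, [dataset])
    gene_index = sorted(net.nodes)
    sub = dataset.subset_genes(gene_index)
    models = fit_class_models(sub)
    llr = llr_matrix(models, sub.values)
    abs_t = np.abs(t_array(llr, sub.pos_mask, variant))

    pos = {g: i for i, g in enumerate(gene_index)}
    unordered = sorted({tuple(sorted((pos[a], pos[b]))) for a, b in net.dist2_pairs})
    pair_i = np.array([p[0] for p in unordered], dtype=np.intp)
    pair_k = np.array([p[1] for p in unordered], dtype=np.intp)
    pair_abs = np.abs(pair_t_values(llr, sub.pos_mask, pair_i, pair_k, variant))

    sim = similarity_from_arrays(
        gene_index, abs_t, pair_i, pair_k, pair_abs, alpha, preference_quantile
    )
    solution = ap_run(sim, damping=damping, max_iter=max_iter, stable_iters=stable_iters)
    if not solution.converged:
        logger.warning("affinity propagation did not converge; using best solution seen")

    score_map = {g: float(abs_t[i]) for i, g in enumerate(gene_index)}
    model_map = {m.gene_id: m for m in models}
    markers = clusters_to_markers(solution.clusters(), score_map, model_map, seed=seed)
    ranked = score_and_rank(markers, dataset, top_k=top_k, variant=variant)
    return ranked, solution


def export_markers_tsv(markers, path) -> None:
    """Write the marker ranking in the interchange dialect."""
    with open(path, "w") as fh:
        fh.write("rank\texemplar\tmembers\tactivity_t\n")
        for rank, m in enumerate(markers, 1):
            t = "" if m.activity_t is None else f"{m.activity_t:.10g}"
            fh.write(f"{rank}\t{m.exemplar}\t{';'.join(m.members)}\t{t}\n")


def import_markers_tsv(path) -> list:
    """Read markers written by :func:`export_markers_tsv` (no models)."""
    markers = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("rank\t"):
            raise ValueError(f"{path}: not a marker TSV (missing header)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            _, exemplar, members, t = line.split("\t")
            markers.append(
                SubnetworkMarker(
                    exemplar=exemplar,
                    members=members.split(";"),
                    activity_t=float(t) if t else None,
                )
            )
    return markers


def refit_marker_models(markers, dataset: ExpressionDataset, sigma_floor=None) -> list:
    """New markers with member models refitted on the given dataset.

    Markers whose members are missing from the dataset are dropped (the
    count is logged); used by the cross-dataset protocols where class
    models must come from the evaluation side.
    """
    models = {m.gene_id: m for m in fit_class_models(dataset, sigma_floor=sigma_floor)}
    out, dropped = [], 0
    for m in markers:
        if all(g in models for g in m.members):
            out.append(
                SubnetworkMarker(
                    exemplar=m.exemplar,
                    members=list(m.members),
                    member_models=[models[g] for g in m.members],
                    activity_t=m.activity_t,
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d markers with genes absent from %s", dropped, dataset.name)
    return out
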