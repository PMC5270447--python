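"""Sparse asymmetric discriminative-synergy similarity between genes.

For an ordered gene pair (g_i, g_k) whose protein products are within
shortest-path distance 2 in the interaction network,

    s(i, k) = t_k + min(t_ik - t_i, t_ik - t_k) - alpha * |t_i - t_k|

where t_i, t_k are the (absolute) LLR t-scores of the two genes and
t_ik the score of their summed LLRs.  The first term rewards a
discriminative candidate exemplar g_k, the min term rewards synergy
(the pair scoring above both singles), and the last term penalises a
mismatch in discriminative power, weighted by alpha in [0, 1].  Pairs
farther than two hops apart are forbidden: their similarity is minus
infinity, represented by *absence* from the sparse structure, never by
a large negative float.

The uniform self-similarity (affinity-propagation preference) c is set
so that only a small fraction (default 1%) of the finite entries are
>= c; a higher preference yields more, smaller clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np

from .exceptions import DegenerateSimilarityError
from .io_network import InteractionNetwork


@dataclass
class SimilarityModel:
    """Sparse asymmetric similarity over ordered distance-<=2 pairs.

    ``src``/``dst``/``values`` store the finite off-diagonal entries by
    integer index into ``gene_index``; any pair not stored is -inf.
    ``preference_c`` is the shared diagonal value.
    """

    gene_index: list
    src: np.ndarray
    dst: np.ndarray
    values: np.ndarray
    alpha: float
    preference_c: float
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.src = np.asarray(self.src, dtype=np.intp)
        self.dst = np.asarray(self.dst, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=float)
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stored similarity entries must be finite")
        if np.any(self.src == self.dst):
            raise ValueError("diagonal entries are carried by preference_c, not stored")

    @property
    def n(self) -> int:
        return len(self.gene_index)

    @property
    def n_entries(self) -> int:
        return len(self.values)

    def _ensure_lookup(self):
        if not self._lookup and len(self.values):
            self._lookup = {
                (int(i), int(k)): float(v)
                for i, k, v in zip(self.src, self.dst, self.values)
            }

    def get(self, i: int, k: int) -> float:
        """s(i, k) by integer index; -inf for forbidden pairs, c on the diagonal."""
        if i == k:
            return self.preference_c
        self._ensure_lookup()
        return self._lookup.get((i, k), -inf)

    def get_by_gene(self, gene_i: str, gene_k: str) -> float:
        idx = {g: j for j, g in enumerate(self.gene_index)}
        return self.get(idx[gene_i], idx[gene_k])

    def export_tsv(self, path) -> None:
        """Dump finite entries and the chosen preference for audit."""
        with open(path, "w") as fh:
            fh.write(f"# alpha={self.alpha:.10g}\tpreference_c={self.preference_c:.10g}\n")
            fh.write("gene_i\tgene_k\ts\n")
            for i, k, v in zip(self.src, self.dst, self.values):
                fh.write(f"{self.gene_index[i]}\t{self.gene_index[k]}\t{v:.10g}\n")


def pair_similarity(
    t_i: float, t_k: float, t_ik: float, alpha: float, within_dist2: bool = True
) -> float:
    """Similarity of one ordered pair; -inf when farther than two hops."""
    if not within_dist2:
        return -inf
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return t_k + min(t_ik - t_i, t_ik - t_k) - alpha * abs(t_i - t_k)


def choose_preference(
    finite_values: np.ndarray,
    preference_quantile: float = 0.01,
    n_total_pairs: int | None = None,
) -> float:
    """Preference c such that at most the given fraction of entries is >= c.

    The fraction is taken over the finite entries by default; passing
    ``n_total_pairs`` switches the denominator to all ordered gene
    pairs.  Ties at the boundary resolve toward the larger candidate c
    (fewer entries >= c), keeping the fraction within the budget.
    """
    vals = np.asarray(finite_values, dtype=float)
    if vals.size == 0:
        raise DegenerateSimilarityError("no finite similarity entries")
    denom = n_total_pairs if n_total_pairs is not None else vals.size
    budget = max(1, int(np.floor(preference_quantile * denom)))
    desc = np.sort(vals)[::-1]
    # count(v) = entries >= v jumps only at distinct values; pick the
    # largest count <= budget, i.e. the smallest candidate value whose
    # >=-count stays within budget.
    distinct = np.unique(desc)[::-1]
    counts = np.searchsorted(-desc, -distinct, side="right")
    ok = counts <= budget
    if not ok.any():
        return float(distinct[0])
    return float(distinct[ok][-1])


def build_similarity(
    scores,
    pair_scores,
    network: InteractionNetwork,
    alpha: float,
    preference_quantile: float = 0.01,
    all_pairs_denominator: bool = False,
    gene_index: list | None = None,
) -> SimilarityModel:
    """Assemble the sparse similarity over the network's distance-<=2 pairs.

    Parameters
    ----------
    scores : mapping or iterable of GeneScore
        Per-gene absolute t-scores.
    pair_scores : mapping
        Combined absolute t per gene pair, keyed by ordered or unordered
        tuple (both orientations share one value).
    network : InteractionNetwork
        Must have ``dist2_pairs`` populated.
    alpha : float
        Penalty weight in [0, 1].
    preference_quantile : float
        Target fraction of entries at or above the preference c.
    all_pairs_denominator : bool
        Count the quantile over all ordered gene pairs (including the
        forbidden ones) instead of over finite entries only.
    """
    if not network.dist2_pairs:
        raise DegenerateSimilarityError(
            "network has no distance-<=2 pairs; call induce_common first"
        )
    abs_t = _as_abs_t_map(scores)
    if gene_index is None:
        gene_index = sorted(network.nodes)
    pos = {g: i for i, g in enumerate(gene_index)}

    src, dst, vals = [], [], []
    for gi, gk in sorted(network.dist2_pairs):
        t_i, t_k = abs_t[gi], abs_t[gk]
        t_ik = _pair_lookup(pair_scores, gi, gk)
        src.append(pos[gi])
        dst.append(pos[gk])
        vals.append(pair_similarity(t_i, t_k, t_ik, alpha))
    vals = np.asarray(vals, dtype=float)
    n = len(gene_index)
    c = choose_preference(
        vals,
        preference_quantile,
        n_total_pairs=n * (n - 1) if all_pairs_denominator else None,
    )
    return SimilarityModel(
        gene_index=list(gene_index),
        src=np.asarray(src),
        dst=np.asarray(dst),
        values=vals,
        alpha=alpha,
        preference_c=c,
    )


def _as_abs_t_map(scores) -> dict:
    if isinstance(scores, dict):
        return {g: abs(float(t)) for g, t in scores.items()}
    return {s.gene_id: s.abs_t for s in scores}


def _pair_lookup(pair_scores, gi, gk) -> float:
    for key in ((gi, gk), (gk, gi), frozenset((gi, gk))):
        if key in pair_scores:
            v = pair_scores[key]
            return abs(float(v.t_combined)) if hasattr(v, "t_combined") else abs(float(v))
    raise KeyError(f"no combined score for pair ({gi}, {gk})")


def similarity_from_arrays(
    gene_index: list,
    abs_t: np.ndarray,
    pair_i: np.ndarray,
    pair_k: np.ndarray,
    pair_abs_t: np.ndarray,
    alpha: float,
    preference_quantile: float = 0.01,
    all_pairs_denominator: bool = False,
) -> SimilarityModel:
    """Vectorised similarity assembly for unordered index pairs.

    ``pair_i``/``pair_k``/``pair_abs_t`` describe each unordered
    distance-<=2 pair once; both orientations are generated here.
    """
    t_i = abs_t[pair_i]
    t_k = abs_t[pair_k]
    synergy = pair_abs_t - np.maximum(t_i, t_k)
    penalty = alpha * np.abs(t_i - t_k)
    s_ik = t_k + synergy - penalty  # orientation i -> k
    s_ki = t_i + synergy - penalty  # orientation k -> i
    src = np.concatenate([pair_i, pair_k])
    dst = np.concatenate([pair_k, pair_i])
    vals = np.concatenate([s_ik, s_ki])
    if vals.size == 0:
        raise DegenerateSimilarityError("no finite similarity entries")
    n = len(gene_index)
    c = choose_preference(
        vals,
        preference_quantile,
        n_total_pairs=n * (n - 1) if all_pairs_denominator else None,
    )
    return SimilarityModel(
        gene_index=list(gene_index),
        src=src,
        dst=dst,
        values=vals,
        alpha=alpha,
        preference_c=c,
    )
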