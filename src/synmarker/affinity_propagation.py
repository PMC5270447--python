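"""Sparse affinity propagation over an asymmetric similarity structure.

Affinity propagation identifies exemplars by exchanging two kinds of
real-valued messages along the finite entries of the similarity:

    responsibility  r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
    availability    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
    self-availability a(k,k) <- sum_{i' != k} max(0, r(i',k))

A point k is an exemplar when a(k,k) + r(k,k) > 0; the run converges
when the exemplar set stays unchanged for a window of iterations.
Messages are damped (default 0.9) to suppress the oscillations that
undamped updates exhibit on symmetric ties; on failure to settle, the
damping is escalated and the run restarted, keeping the best solution
by net similarity.

All message storage is restricted to the sparse support (the finite
similarity entries plus the diagonal); pairs beyond two network hops
never exchange messages, so forbidden links stay forbidden regardless
of message magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import inf

import numpy as np

from .similarity import SimilarityModel

DEFAULT_DAMPING = 0.9
DEFAULT_MAX_ITER = 2000
DEFAULT_STABLE_ITERS = 100
RESTART_DAMPINGS = (0.95, 0.99)


@dataclass
class MessageState:
    """Messages and bookkeeping over the sparse support (entries + diagonal).

    Edge arrays are sorted by (row, col); ``row_start`` is the CSR-style
    index pointer over rows.  ``diag_edge`` maps each point to the index
    of its diagonal edge, and ``by_col``/``col_start`` give the same
    edges grouped by column for the availability pass.
    """

    row: np.ndarray
    col: np.ndarray
    s: np.ndarray
    r: np.ndarray
    a: np.ndarray
    damping: float
    iteration: int = 0
    stable_count: int = 0
    row_start: np.ndarray = field(default=None, repr=False)
    diag_edge: np.ndarray = field(default=None, repr=False)
    by_col: np.ndarray = field(default=None, repr=False)
    col_start: np.ndarray = field(default=None, repr=False)
    isolated: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.diag_edge)


def init_state(similarity: SimilarityModel, damping: float = DEFAULT_DAMPING) -> MessageState:
    """Build the message state: zero messages on entries plus diagonal."""
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must lie in [0.5, 1)")
    n = similarity.n
    diag = np.arange(n)
    row = np.concatenate([similarity.src, diag])
    col = np.concatenate([similarity.dst, diag])
    s = np.concatenate([similarity.values, np.full(n, similarity.preference_c)])
    order = np.lexsort((col, row))
    row, col, s = row[order], col[order], s[order]
    m = len(row)
    row_start = np.searchsorted(row, np.arange(n + 1))
    diag_edge = np.flatnonzero(row == col)
    by_col = np.lexsort((row, col))
    col_start = np.searchsorted(col[by_col], np.arange(n + 1))
    row_counts = np.diff(row_start)
    return MessageState(
        row=row,
        col=col,
        s=s,
        r=np.zeros(m),
        a=np.zeros(m),
        damping=damping,
        row_start=row_start,
        diag_edge=diag_edge,
        by_col=by_col,
        col_start=col_start,
        isolated=row_counts == 1,  # only the diagonal: no finite neighbour
    )


def update_responsibilities(state: MessageState, similarity: SimilarityModel = None) -> MessageState:
    """One damped responsibility sweep over the stored support.

    The competing maximum for edge (i,k) runs over every other finite
    candidate of row i (the diagonal included).  A row whose only
    candidate is itself has an empty competing set; by convention its
    responsibility is 0 and the point is self-exemplared at extraction.
    """
    t = state.a + state.s
    starts = state.row_start[:-1]
    max1 = np.maximum.reduceat(t, starts)
    rowmax = max1[state.row]
    # positional argmax per row: first edge attaining the row maximum
    hit = np.flatnonzero(t == rowmax)
    first_of_row = hit[np.unique(state.row[hit], return_index=True)[1]]
    t2 = t.copy()
    t2[first_of_row] = -inf
    max2 = np.maximum.reduceat(t2, starts)
    competing = rowmax.copy()
    competing[first_of_row] = max2[state.row[first_of_row]]
    with np.errstate(invalid="ignore"):
        r_new = state.s - competing
    r_new[~np.isfinite(r_new)] = 0.0  # empty competing set (isolated row)
    state.r = state.damping * state.r + (1.0 - state.damping) * r_new
    return state


def update_availabilities(state: MessageState, similarity: SimilarityModel = None) -> MessageState:
    """One damped availability sweep (off-diagonal and self) over the support."""
    rp = np.maximum(state.r, 0.0)
    rp[state.diag_edge] = 0.0  # sums exclude the candidate's own responsibility
    rp_by_col = rp[state.by_col]
    totals = np.add.reduceat(
        np.concatenate([rp_by_col, [0.0]]),  # guard: reduceat needs non-empty slices
        state.col_start[:-1],
    )
    empty = np.diff(state.col_start) == 0
    totals[empty] = 0.0
    r_diag = state.r[state.diag_edge]
    a_new = np.minimum(0.0, r_diag[state.col] + totals[state.col] - rp)
    a_new[state.diag_edge] = totals  # self-availability: plain positive-evidence sum
    state.a = state.damping * state.a + (1.0 - state.damping) * a_new
    state.iteration += 1
    return state


def _current_exemplars(state: MessageState) -> np.ndarray:
    evidence = state.a[state.diag_edge] + state.r[state.diag_edge]
    ex = evidence > 0.0
    ex |= state.isolated
    return ex


@dataclass
class ClusterSolution:
    """Exemplars and the gene partition they induce."""

    exemplars: set
    assignment: dict
    converged: bool
    iterations_run: int
    net_similarity: float

    def clusters(self) -> dict:
        """Map exemplar -> sorted member list (exemplar included)."""
        out = {e: [] for e in self.exemplars}
        for g, e in self.assignment.items():
            out[e].append(g)
        return {e: sorted(v) for e, v in out.items()}


def extract_solution(state: MessageState, similarity: SimilarityModel) -> ClusterSolution:
    """Read exemplars off the messages and assign every gene to one.

    Exemplars are the points with positive self-evidence a(k,k)+r(k,k);
    every other gene joins the reachable exemplar with the highest
    similarity (ties to the smaller gene index), or becomes a singleton
    self-exemplar if no exemplar is within reach.
    """
    genes = similarity.gene_index
    n = similarity.n
    ex_mask = _current_exemplars(state)
    if not ex_mask.any():
        evidence = state.a[state.diag_edge] + state.r[state.diag_edge]
        ex_mask = np.zeros(n, dtype=bool)
        ex_mask[int(np.argmax(evidence))] = True

    assignment_idx = np.full(n, -1, dtype=np.intp)
    assignment_idx[ex_mask] = np.flatnonzero(ex_mask)
    # assignment and net similarity use the *unperturbed* similarity
    # entries; the messages only decide who the exemplars are
    cand = ex_mask[similarity.dst] & ~ex_mask[similarity.src]
    rows, cols, sims = similarity.src[cand], similarity.dst[cand], similarity.values[cand]
    # best similarity per row, ties to the smaller column index: sort by
    # (row, -s, col) and keep the first edge of each row
    order = np.lexsort((cols, -sims, rows))
    rows_o = rows[order]
    first = np.unique(rows_o, return_index=True)[1]
    assignment_idx[rows_o[first]] = cols[order][first]
    unreached = assignment_idx == -1
    assignment_idx[unreached] = np.flatnonzero(unreached)  # singleton fallback
    ex_mask = ex_mask | unreached

    net = similarity.preference_c * int(ex_mask.sum())
    member = ~ex_mask
    if member.any():
        lut = {
            (int(i), int(k)): float(v)
            for i, k, v in zip(similarity.src, similarity.dst, similarity.values)
        }
        net += sum(
            lut[(int(i), int(assignment_idx[i]))] for i in np.flatnonzero(member)
        )
    return ClusterSolution(
        exemplars={genes[i] for i in np.flatnonzero(ex_mask)},
        assignment={genes[i]: genes[assignment_idx[i]] for i in range(n)},
        converged=False,
        iterations_run=state.iteration,
        net_similarity=float(net),
    )


def run(
    similarity: SimilarityModel,
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    stable_iters: int = DEFAULT_STABLE_ITERS,
    tie_noise: float = 1e-8,
    seed: int = 0,
) -> ClusterSolution:
    """Iterate message passing to convergence, escalating damping on failure.

    Convergence means the exemplar set is unchanged for ``stable_iters``
    consecutive iterations.  A run that fails to settle within
    ``max_iter`` (oscillation) is restarted at higher damping; after the
    escalation schedule is exhausted the best solution seen, by net
    similarity, is returned with ``converged=False``.

    Exactly symmetric inputs (identical similarities in both directions)
    leave the message equations degenerate — no damping can decide which
    of two tied points becomes the exemplar — so a deterministic, seeded
    jitter of relative magnitude ``tie_noise`` is added to the
    similarities before iterating (set ``tie_noise=0`` to disable).
    """
    schedule = [damping] + [d for d in RESTART_DAMPINGS if d > damping]
    rng = np.random.default_rng(seed)
    best = None
    for lam in schedule[:3]:
        state = init_state(similarity, damping=lam)
        if tie_noise > 0.0 and state.s.size:
            span = float(np.ptp(state.s)) or 1.0
            state.s = state.s + rng.normal(0.0, tie_noise * span, size=state.s.shape)
        prev = None
        while state.iteration < max_iter:
            update_responsibilities(state, similarity)
            update_availabilities(state, similarity)
            ex = _current_exemplars(state)
            if prev is not None and np.array_equal(ex, prev):
                state.stable_count += 1
            else:
                state.stable_count = 0
            prev = ex
            if ex.any() and state.stable_count >= stable_iters:
                sol = extract_solution(state, similarity)
                sol.converged = True
                return sol
        sol = extract_solution(state, similarity)
        if best is None or sol.net_similarity > best.net_similarity:
            best = sol
    return best


def brute_force_exemplars(similarity: SimilarityModel, max_n: int = 14):
    """Exhaustive reference: best exemplar subset and its net similarity.

    Enumerates every non-empty exemplar subset (valid when each
    non-exemplar can reach some exemplar through a finite entry) and
    scores it as ``c * |S| + sum_i max_{k in S} s(i,k)``.  Exponential;
    intended for instances of at most ~14 points in tests.
    """
    n = similarity.n
    if n > max_n:
        raise ValueError(f"brute force limited to {max_n} points, got {n}")
    s = np.full((n, n), -inf)
    s[similarity.src, similarity.dst] = similarity.values
    c = similarity.preference_c
    best_val, best_set = -inf, None
    idx = list(range(n))
    for size in range(1, n + 1):
        for subset in combinations(idx, size):
            members = np.setdiff1d(idx, subset)
            val = c * size
            if members.size:
                gains = s[np.ix_(members, list(subset))].max(axis=1)
                if not np.all(np.isfinite(gains)):
                    continue
                val += gains.sum()
            if val > best_val:
                best_val, best_set = val, set(subset)
    return best_set, float(best_val)
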