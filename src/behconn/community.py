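"""Signed Louvain community detection and consensus clustering.

Correlation networks carry negative edges, so modularity uses the symmetric
signed convention: positive and negative subnetworks each get their own
configuration-model null, and

    Q = Q+ * W+/(W+ + W-)  -  Q- * W-/(W+ + W-)

which collapses to Newman's weighted modularity when all edges are positive.
The optimiser is the two-phase Louvain heuristic (greedy node moves followed
by community aggregation) run directly on the generalised modularity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Partition",
    "ConsensusResult",
    "modularity_matrix",
    "modularity_q",
    "louvain",
    "consensus",
    "match_labels",
]


@dataclass
class Partition:
    """A hard assignment of nodes to communities with its modularity Q."""

    labels: np.ndarray  # int labels, 0..k-1
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ConsensusResult:
    partition: Partition
    agreement: np.ndarray  # co-assignment frequency over the initial runs
    n_iterations: int
    stability: float  # fraction of nodes identically assigned across all runs
    runs: list = field(default_factory=list, repr=False)


def _check_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("adjacency matrix must be symmetric")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def modularity_matrix(w: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Generalised (signed, symmetric-null) modularity matrix B.

    Q of a partition is the sum of B over co-assigned node pairs, diagonal
    included (self-terms carry the null model's -gamma*s_i^2/v contribution).
    """
    w = _check_square_symmetric(w)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp = wp.sum()
    vn = wn.sum()
    if vp + vn == 0:
        raise ValueError("all-zero network: modularity undefined")
    b = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        b += wp - gamma * np.outer(sp, sp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        b -= wn - gamma * np.outer(sn, sn) / vn
    return b / (vp + vn)


def modularity_q(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Q of a given partition under the signed symmetric convention."""
    b = modularity_matrix(w, gamma=gamma)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


def _move_phase(b: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                tol: float = 1e-12) -> bool:
    """Greedy node moves on modularity matrix ``b``; mutates ``labels``.

    Returns True if any move improved Q.
    """
    n = b.shape[0]
    improved_any = False
    improved = True
    while improved:
        improved = False
        # one spare empty slot lets a node split off into a singleton
        n_comm = labels.max() + 2
        for i in rng.permutation(n):
            a = labels[i]
            # gain of community c = sum_{j in c, j != i} B_ij
            sums = np.bincount(labels, weights=b[i], minlength=n_comm)
            sums[a] -= b[i, i]
            best = int(np.argmax(sums))
            if sums[best] > sums[a] + tol:
                labels[i] = best
                improved = True
                improved_any = True
                if best == n_comm - 1:
                    n_comm += 1
    return improved_any


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Canonical compact labels, numbered by first occurrence."""
    _, first, inv = np.unique(labels, return_index=True, return_inverse=True)
    remap = np.empty(len(first), dtype=int)
    remap[np.argsort(first)] = np.arange(len(first))
    return remap[inv]


def _aggregate(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    h = np.eye(k)[labels]  # n x k indicator
    return h.T @ b @ h


def louvain(w: np.ndarray, gamma: float = 1.0, seed: int | None = None,
            init: np.ndarray | None = None) -> Partition:
    """Louvain optimisation of signed modularity.

    Starts from singleton communities (or ``init``), alternates greedy node
    moves with community aggregation until no further Q gain. The node visiting
    order is drawn from ``seed``, which is the algorithm's only stochasticity.
    """
    b = modularity_matrix(w, gamma=gamma)
    rng = np.random.default_rng(seed)
    n = b.shape[0]
    labels = np.arange(n) if init is None else _relabel(np.asarray(init))

    node_map = labels.copy()  # original node -> current-level community
    level_b = _aggregate(b, labels) if init is not None else b
    level_labels = np.arange(level_b.shape[0])
    while True:
        improved = _move_phase(level_b, level_labels, rng)
        level_labels = _relabel(level_labels)
        node_map = level_labels[node_map]
        if not improved:
            break
        level_b = _aggregate(level_b, level_labels)
        level_labels = np.arange(level_b.shape[0])

    labels = _relabel(node_map)
    same = labels[:, None] == labels[None, :]
    return Partition(labels=labels, q=float(b[same].sum()))


def _kl_round(b: np.ndarray, labels: np.ndarray, tol: float = 1e-12
              ) -> tuple[np.ndarray, bool]:
    """One Kernighan-Lin pass: chain of locked single moves, best prefix kept.

    Unlike plain greedy moves, intermediate moves may lower Q, letting the
    pass cross small barriers between local optima.
    """
    n = b.shape[0]
    cur = labels.copy()
    best_labels = labels.copy()
    locked = np.zeros(n, dtype=bool)
    cum = 0.0
    best_cum = 0.0
    for _ in range(n):
        n_comm = cur.max() + 2  # spare empty slot allows singleton split-off
        move, move_gain = None, -np.inf
        for i in np.flatnonzero(~locked):
            sums = np.bincount(cur, weights=b[i], minlength=n_comm)
            sums[cur[i]] -= b[i, i]
            order = np.argsort(-sums, kind="stable")
            c = order[0] if order[0] != cur[i] else order[1]
            gain = 2.0 * (sums[c] - sums[cur[i]])
            if gain > move_gain:
                move, move_gain = (i, int(c)), gain
        i, c = move
        cur[i] = c
        locked[i] = True
        cum += move_gain
        if cum > best_cum + tol:
            best_cum = cum
            best_labels = cur.copy()
    return best_labels, best_cum > tol


def refine(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0,
           max_rounds: int = 20) -> Partition:
    """Deterministic refinement of a partition on the original network.

    A greedy local-move hill-climb followed by Kernighan-Lin passes until no
    further modularity gain; Q can only increase relative to the input
    partition. Used to polish the consensus partition.
    """
    b = modularity_matrix(w, gamma=gamma)
    work = _relabel(np.asarray(labels).copy())
    rng = np.random.default_rng(0)  # permutation fixed -> deterministic
    for _ in range(max_rounds):
        _move_phase(b, work, rng)
        work = _relabel(work)
        work, improved = _kl_round(b, work)
        work = _relabel(work)
        if not improved:
            break
    same = work[:, None] == work[None, :]
    return Partition(labels=work, q=float(b[same].sum()))


def agreement_matrix(runs: list[np.ndarray]) -> np.ndarray:
    """Fraction of runs co-assigning each node pair."""
    n = len(runs[0])
    d = np.zeros((n, n))
    for lab in runs:
        lab = np.asarray(lab)
        d += (lab[:, None] == lab[None, :]).astype(float)
    d /= len(runs)
    np.fill_diagonal(d, 0.0)
    return d


def match_labels(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to best overlap ``reference`` (Hungarian matching)."""
    labels = _relabel(np.asarray(labels))
    reference = _relabel(np.asarray(reference))
    k1 = labels.max() + 1
    k2 = reference.max() + 1
    k = max(k1, k2)
    cont = np.zeros((k, k))
    for a, b_ in zip(labels, reference):
        cont[a, b_] += 1
    row, col = linear_sum_assignment(-cont)
    mapping = np.empty(k, dtype=int)
    mapping[row] = col
    return mapping[labels]


def consensus(w: np.ndarray, n_iter: int = 100, tau: float = 0.5,
              gamma: float = 1.0, seed: int | None = None,
              max_outer: int = 50) -> ConsensusResult:
    """Consensus community detection over ``n_iter`` seeded Louvain runs.

    The agreement (co-assignment) matrix of the runs is thresholded at ``tau``
    and re-clustered, iterating until all runs agree; the stable partition is
    then refined by deterministic local moves on the original network and its
    Q reported on that network.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    w = _check_square_symmetric(w)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_iter)
    runs = [louvain(w, gamma=gamma, seed=int(s)).labels for s in sub]
    agreement = agreement_matrix(runs)

    current = [r.copy() for r in runs]
    n_outer = 0
    while not all(np.array_equal(_relabel(current[0]), _relabel(r)) for r in current[1:]):
        n_outer += 1
        if n_outer > max_outer:
            raise RuntimeError(
                f"consensus did not converge in {max_outer} iterations; "
                f"agreement range [{agreement.min():.3f}, {agreement.max():.3f}]"
            )
        d = agreement_matrix(current)
        d_thr = np.where(d >= tau, d, 0.0)
        if not d_thr.any():
            raise RuntimeError("thresholded agreement matrix is empty; lower tau")
        sub = rng.integers(0, 2**31 - 1, size=n_iter)
        current = [louvain(d_thr, gamma=gamma, seed=int(s)).labels for s in sub]

    part = refine(w, current[0], gamma=gamma)

    aligned = np.stack([match_labels(r, part.labels) for r in runs])
    stability = float((aligned == aligned[0]).all(axis=0).mean())
    return ConsensusResult(partition=part, agreement=agreement,
                           n_iterations=n_iter, stability=stability, runs=runs)
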