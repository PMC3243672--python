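"""Signed-modularity community detection.

Modularity is generalised to signed weights by computing the standard
Newman weighted modularity separately on the positive and the negative
sub-graph and combining them,

    Q = w⁺/(w⁺+w⁻) · Q⁺  −  w⁻/(w⁺+w⁻) · Q⁻ ,

so that within-community positive weight is rewarded and within-community
negative weight penalised beyond their null expectations.  Equivalently,
Q is the sum over same-community vertex pairs (i, j), i = j included, of

    B_ij = [ (w⁺_ij − k⁺_i k⁺_j / 2w⁺) − (w⁻_ij − k⁻_i k⁻_j / 2w⁻) ]
           / (2(w⁺ + w⁻)) ,

which is the representation all optimisers here work on: any partition's
quality is a sum of within-community entries of the fixed matrix B.

Optimisation follows the classical protocol: repeated tabu searches and a
greedy agglomerative (Newman fast) pass, each refined by a fine-tuning
sweep of best single-vertex moves, with the trivial all-singleton and
one-community partitions as floors.  An exact optimiser enumerating all
set partitions is provided for small graphs as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import CorrelationNetwork

__all__ = [
    "CommunityPartition",
    "signed_modularity",
    "detect_communities",
    "exact_partition",
]

_EPS = 1e-12


@dataclass
class CommunityPartition:
    """Assignment of every vertex to a community.

    Community indices are contiguous and 1-based, ordered by descending
    community size, ties broken by the smallest member label.  Isolated
    vertices form one-member communities.
    """

    assignment: dict[str, int]
    modularity: float

    def communities(self) -> list[list[str]]:
        k = max(self.assignment.values(), default=0)
        groups: list[list[str]] = [[] for _ in range(k)]
        for label in sorted(self.assignment):
            groups[self.assignment[label] - 1].append(label)
        return groups

    @property
    def n_communities(self) -> int:
        return max(self.assignment.values(), default=0)


def _as_graph(net: CorrelationNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CorrelationNetwork) else net


def _modularity_matrix(g: nx.Graph) -> tuple[list[str], np.ndarray]:
    labels = sorted(g.nodes)
    n = len(labels)
    if n == 0:
        return labels, np.zeros((0, 0))
    W = nx.to_numpy_array(g, nodelist=labels, weight="weight")
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    two_wp = Wp.sum()
    two_wn = Wn.sum()
    total = 0.5 * (two_wp + two_wn)
    B = np.zeros((n, n))
    if two_wp > 0:
        kp = Wp.sum(axis=1)
        B += Wp - np.outer(kp, kp) / two_wp
    if two_wn > 0:
        kn = Wn.sum(axis=1)
        B -= Wn - np.outer(kn, kn) / two_wn
    if total > 0:
        B /= 2.0 * total
    return labels, B


def _partition_quality(B: np.ndarray, comm: np.ndarray) -> float:
    q = 0.0
    for c in np.unique(comm):
        idx = np.flatnonzero(comm == c)
        q += B[np.ix_(idx, idx)].sum()
    return float(q)


def _canonical(labels: list[str], comm: np.ndarray) -> dict[str, int]:
    groups: dict[int, list[str]] = {}
    for lab, c in zip(labels, comm):
        groups.setdefault(int(c), []).append(lab)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    assignment: dict[str, int] = {}
    for i, members in enumerate(ordered, start=1):
        for m in members:
            assignment[m] = i
    return assignment


def _canonical_key(labels: list[str], comm: np.ndarray) -> tuple[int, ...]:
    assignment = _canonical(labels, comm)
    return tuple(assignment[lab] for lab in sorted(labels))


def signed_modularity(
    net: CorrelationNetwork | nx.Graph, partition: CommunityPartition | dict[str, int]
) -> float:
    """Signed weighted modularity of a partition of the network."""
    g = _as_graph(net)
    assignment = (
        partition.assignment
        if isinstance(partition, CommunityPartition)
        else partition
    )
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"vertices without community assignment: {sorted(missing)}")
    labels, B = _modularity_matrix(g)
    comm = np.array([assignment[lab] for lab in labels])
    return _partition_quality(B, comm)


# ---------------------------------------------------------------------------
# heuristics
# ---------------------------------------------------------------------------

def _community_sums(B: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """R[v, c] = sum of B[v, j] over vertices j currently in community c."""
    k = int(comm.max()) + 1
    n = len(comm)
    M = np.zeros((n, k))
    M[np.arange(n), comm] = 1.0
    return B @ M


def _fine_tune(B: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """Best single-vertex reassignments and community merges until neither
    improves Q."""
    comm = _compact(comm)
    n = len(comm)
    while True:
        k = int(comm.max()) + 1
        R = _community_sums(B, comm)
        own = R[np.arange(n), comm] - np.diag(B)
        # gain of moving v to community c (including an empty community k)
        gains = np.zeros((n, k + 1))
        gains[:, :k] = 2.0 * (R - own[:, None])
        gains[:, k] = 2.0 * (0.0 - own)
        gains[np.arange(n), comm] = -np.inf
        v, c = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[v, c] > _EPS:
            comm[v] = c
            comm = _compact(comm)
            continue
        if k > 1:
            # aggregated between-community sums; merging (a, b) gains 2*agg
            M = np.zeros((n, k))
            M[np.arange(n), comm] = 1.0
            agg = M.T @ B @ M
            merge_gains = 2.0 * agg
            np.fill_diagonal(merge_gains, -np.inf)
            a, b = np.unravel_index(np.argmax(merge_gains), merge_gains.shape)
            if merge_gains[a, b] > _EPS:
                comm[comm == b] = a
                comm = _compact(comm)
                continue
        return comm


def _compact(comm: np.ndarray) -> np.ndarray:
    _, out = np.unique(comm, return_inverse=True)
    return out.astype(int)


def _tabu_search(
    B: np.ndarray,
    rng: np.random.Generator,
    tenure: int,
    max_non_improving: int = 100,
) -> np.ndarray:
    """Single-vertex-move tabu search over partitions.

    Each iteration applies the best admissible move (possibly worsening);
    the moved vertex becomes tabu for ``tenure`` iterations unless moving
    it would beat the best quality seen (aspiration).  Stops after
    ``max_non_improving`` consecutive iterations without a new best.
    """
    n = len(B)
    comm = _compact(rng.integers(0, max(1, n // 2 + 1), size=n))
    best = comm.copy()
    best_q = _partition_quality(B, comm)
    q = best_q
    tabu_until = np.zeros(n, dtype=int)
    it = 0
    non_improving = 0
    diag = np.diag(B)
    while non_improving < max_non_improving:
        it += 1
        k = int(comm.max()) + 1
        R = _community_sums(B, comm)
        own = R[np.arange(n), comm] - diag
        gains = np.empty((n, k + 1))
        gains[:, :k] = 2.0 * (R - own[:, None])
        gains[:, k] = -2.0 * own
        gains[np.arange(n), comm] = -np.inf
        tabu = tabu_until > it
        if tabu.any():
            aspire = q + gains[tabu] > best_q + _EPS
            masked = np.where(aspire, gains[tabu], -np.inf)
            gains[tabu] = masked
        if not np.isfinite(gains).any():
            break
        v, c = np.unravel_index(np.argmax(gains), gains.shape)
        q += gains[v, c]
        comm[v] = c
        comm = _compact(comm)
        tabu_until[v] = it + tenure
        if q > best_q + _EPS:
            best_q = q
            best = comm.copy()
            non_improving = 0
        else:
            non_improving += 1
    return best


def _newman_fast(B: np.ndarray) -> np.ndarray:
    """Greedy agglomerative merging from singletons, tracking the best
    partition along the merge path."""
    n = len(B)
    comm = np.arange(n)
    agg = B.copy()  # aggregated between-community sums
    alive = list(range(n))
    best = comm.copy()
    best_q = _partition_quality(B, comm)
    q = best_q
    while len(alive) > 1:
        sub = agg[np.ix_(alive, alive)]
        gains = 2.0 * sub
        np.fill_diagonal(gains, -np.inf)
        i, j = np.unravel_index(np.argmax(gains), gains.shape)
        a, b = alive[i], alive[j]
        q += gains[i, j]
        comm[comm == b] = a
        agg[a, :] += agg[b, :]
        agg[:, a] += agg[:, b]
        alive.remove(b)
        if q > best_q + _EPS:
            best_q = q
            best = comm.copy()
    return _compact(best)


def detect_communities(
    net: CorrelationNetwork | nx.Graph, seed: int = 0, n_restarts: int = 10
) -> CommunityPartition:
    """Maximise signed modularity by tabu search plus greedy agglomeration.

    Runs ``n_restarts`` tabu searches from random partitions and one
    greedy agglomerative pass, each followed by a fine-tuning sweep, and
    returns the best partition found (never below the all-singleton or
    one-community baselines).  Deterministic for a given ``seed``; ties in
    quality resolve to the lexicographically smallest canonical assignment.
    """
    g = _as_graph(net)
    labels, B = _modularity_matrix(g)
    n = len(labels)
    if n == 0:
        return CommunityPartition(assignment={}, modularity=0.0)
    rng = np.random.default_rng(seed)
    tenure = max(1, n // 4)

    candidates: list[np.ndarray] = [
        np.arange(n),            # all singletons
        np.zeros(n, dtype=int),  # one community
        _fine_tune(B, np.arange(n)),
        _fine_tune(B, _newman_fast(B)),
    ]
    for _ in range(n_restarts):
        candidates.append(_fine_tune(B, _tabu_search(B, rng, tenure)))

    best_comm = None
    best_q = -np.inf
    best_key = None
    for comm in candidates:
        qq = _partition_quality(B, comm)
        key = _canonical_key(labels, comm)
        if qq > best_q + _EPS or (
            qq > best_q - _EPS and (best_key is None or key < best_key)
        ):
            best_comm, best_q, best_key = comm, qq, key
    assignment = _canonical(labels, best_comm)
    return CommunityPartition(assignment=assignment, modularity=best_q)


def exact_partition(net: CorrelationNetwork | nx.Graph) -> CommunityPartition:
    """Globally optimal partition by enumeration of all set partitions.

    Vertices are placed one at a time into existing or new blocks
    (Bell-number search); a branch is abandoned when even the optimistic
    bound on the remaining placements cannot beat the incumbent.  Limited
    to 13 vertices.
    """
    g = _as_graph(net)
    labels, B = _modularity_matrix(g)
    n = len(labels)
    if n > 13:
        raise ValueError("exact_partition is limited to 13 vertices")
    if n == 0:
        return CommunityPartition(assignment={}, modularity=0.0)
    diag = np.diag(B).copy()
    # optimistic per-vertex placement bound: pairs (u, v), u < v, count at v
    bound = np.empty(n)
    for v in range(n):
        bound[v] = diag[v] + 2.0 * np.clip(B[:v, v], 0.0, None).sum()
    suffix = np.concatenate([np.cumsum(bound[::-1])[::-1], [0.0]])

    comm = np.zeros(n, dtype=int)
    best: dict[str, object] = {"q": -np.inf, "comm": None, "key": None}
    block_sums: list[np.ndarray] = []

    def record(q: float) -> None:
        key = _canonical_key(labels, comm)
        if q > best["q"] + _EPS or (
            q > best["q"] - _EPS and (best["key"] is None or key < best["key"])
        ):
            best["q"], best["comm"], best["key"] = q, comm.copy(), key

    def rec(v: int, q: float) -> None:
        if v == n:
            record(q)
            return
        if q + suffix[v] < best["q"] - _EPS:
            return
        for b, sums in enumerate(block_sums):
            dq = diag[v] + 2.0 * sums[v]
            comm[v] = b
            block_sums[b] = sums + B[v]
            rec(v + 1, q + dq)
            block_sums[b] = sums
        comm[v] = len(block_sums)
        block_sums.append(B[v].copy())
        rec(v + 1, q + diag[v])
        block_sums.pop()

    rec(0, 0.0)
    assignment = _canonical(labels, np.asarray(best["comm"]))
    return CommunityPartition(assignment=assignment, modularity=float(best["q"]))
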