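"""Residue-specific correlation scores from cumulative binomial tails.

The central statistic: for an alignment of N sequences, let n_A be the
number of sequences carrying amino acid x at column i and n_B the number
carrying y at column j.  Under independence, restricting to the n_A
sequences with x at i ("perturbing" the alignment) leaves the frequency of
y at j at its marginal value n_B/N, so the joint count n_{B|A} is Binomial
(n_A, n_B/N).  The correlation score is the signed log tail probability

* +(−log10 P[X ≥ n_{B|A}])  when the joint count exceeds its expectation
  n_A·n_B/N (correlation), and
* −(−log10 P[X ≤ n_{B|A}])  when it falls below (anti-correlation).

Scores of 100+ correspond to p-values around 1e-100, far below float
underflow, so the tails are evaluated in log space throughout.

Scores are computed in both directions (A perturbing B, B perturbing A)
and averaged downstream when the network is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .alignment import AMINO_ACIDS, Alignment, _GAP_CODE

__all__ = [
    "ResidueNode",
    "DirectionalScore",
    "CorrelationEdge",
    "binomial_tail_log10",
    "directional_score",
    "score_all_pairs",
    "edges_from_table",
    "score_table",
    "eligible_nodes",
    "min_perturbation_fraction",
    "node_label",
    "reference_numbering",
]

_LN10 = np.log(10.0)
_LOG_HALF = float(np.log(0.5))

SCORE_COLUMNS = [
    "col_a", "res_a", "col_b", "res_b", "n_a", "n_b",
    "joint_ab", "joint_ba", "score_ab", "score_ba", "mean_score",
    "f_b_given_a", "f_a_given_b", "label_a", "label_b",
]


@dataclass(frozen=True)
class ResidueNode:
    """A (column, residue) pair: one vertex of the correlation network.

    ``column`` is 1-based; ``count`` is the number of sequences carrying
    ``residue`` there; ``frequency`` is count/N over all N sequences
    (gapped sequences included in the denominator).
    """

    column: int
    residue: str
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"not a canonical amino acid: {self.residue!r}")
        if self.count <= 0:
            raise ValueError("node count must be positive")


@dataclass(frozen=True)
class DirectionalScore:
    """Score of perturbing by ``source`` and observing ``target``."""

    source: ResidueNode
    target: ResidueNode
    joint_count: int
    conditional_frequency: float
    signed_log_p: float


@dataclass(frozen=True)
class CorrelationEdge:
    """Both directional scores for an unordered residue-node pair."""

    node_a: ResidueNode
    node_b: ResidueNode
    score_ab: float
    score_ba: float
    freq_b_given_a: float
    freq_a_given_b: float
    joint_count: int
    label_a: str
    label_b: str

    @property
    def mean_score(self) -> float:
        return 0.5 * (self.score_ab + self.score_ba)


# ---------------------------------------------------------------------------
# binomial tails in log space
# ---------------------------------------------------------------------------

def _exact_tail_log10(n: int, s: int, p: float, tail: str) -> float:
    # log-space summation of the exact tail; used when the scipy path
    # underflows (p-values far below 1e-308)
    if tail == "upper":
        k = np.arange(s, n + 1)
    else:
        k = np.arange(0, s + 1)
    log_terms = (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    return float(-logsumexp(log_terms) / _LN10)


def _upper_tail_log10_vec(n: np.ndarray, s: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised −log10 P[X ≥ s] for X ~ Binomial(n, p)."""
    out = np.zeros(len(p), dtype=float)
    m = s > 0
    if not m.any():
        return out
    n_m, s_m, p_m = n[m], s[m], p[m]
    with np.errstate(divide="ignore"):
        z = binom.logsf(s_m - 1, n_m, p_m)
    res = -z / _LN10
    # p-value near 1: log(sf) loses all precision; use the complement cdf
    near_one = z > _LOG_HALF
    if near_one.any():
        c = binom.cdf(s_m[near_one] - 1, n_m[near_one], p_m[near_one])
        res[near_one] = -np.log1p(-c) / _LN10
    # underflow: exact log-space summation
    bad = ~np.isfinite(res)
    for idx in np.flatnonzero(bad):
        res[idx] = _exact_tail_log10(int(n_m[idx]), int(s_m[idx]), float(p_m[idx]), "upper")
    out[m] = res
    return out


def _lower_tail_log10_vec(n: np.ndarray, s: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised −log10 P[X ≤ s] for X ~ Binomial(n, p)."""
    out = np.zeros(len(p), dtype=float)
    m = s < n
    if not m.any():
        return out
    n_m, s_m, p_m = n[m], s[m], p[m]
    with np.errstate(divide="ignore"):
        z = binom.logcdf(s_m, n_m, p_m)
    res = -z / _LN10
    near_one = z > _LOG_HALF
    if near_one.any():
        c = binom.sf(s_m[near_one], n_m[near_one], p_m[near_one])
        res[near_one] = -np.log1p(-c) / _LN10
    bad = ~np.isfinite(res)
    for idx in np.flatnonzero(bad):
        res[idx] = _exact_tail_log10(int(n_m[idx]), int(s_m[idx]), float(p_m[idx]), "lower")
    out[m] = res
    return out


def binomial_tail_log10(
    trials: int, successes: int, prob: float, tail: str = "upper"
) -> float:
    """−log10 of a cumulative binomial tail, computed in log space.

    Parameters
    ----------
    trials, successes
        Binomial sample size n and the tail boundary s (inclusive).
    prob
        Success probability, strictly inside (0, 1).
    tail
        ``"upper"`` for P[X ≥ s], ``"lower"`` for P[X ≤ s].

    Returns a non-negative finite value; exactly 0.0 for the degenerate
    whole-distribution tails (upper with s=0, lower with s=n).
    """
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be strictly inside (0, 1)")
    if tail not in ("upper", "lower"):
        raise ValueError(f"unknown tail: {tail!r}")
    n = np.array([trials])
    s = np.array([successes])
    p = np.array([prob], dtype=float)
    if tail == "upper":
        return float(_upper_tail_log10_vec(n, s, p)[0])
    return float(_lower_tail_log10_vec(n, s, p)[0])


def _signed_scores_vec(
    trials: np.ndarray, joint: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Signed −log10 tail score for each (trials, joint, p) triple.

    Positive (upper tail) when the joint count is at or above the
    expectation trials·p, negative (lower tail) below.  The exact-boundary
    case takes the upper tail, whose value is small by construction.
    """
    expected = trials * p
    upper_mask = joint >= expected
    out = np.empty(len(p), dtype=float)
    if upper_mask.any():
        out[upper_mask] = _upper_tail_log10_vec(
            trials[upper_mask], joint[upper_mask], p[upper_mask]
        )
    lower_mask = ~upper_mask
    if lower_mask.any():
        out[lower_mask] = -_lower_tail_log10_vec(
            trials[lower_mask], joint[lower_mask], p[lower_mask]
        )
    return out


def directional_score(
    N: int, node_a: ResidueNode, node_b: ResidueNode, joint_count: int
) -> DirectionalScore:
    """Score the perturbation "node_a present" on the frequency of node_b.

    The trials are the node_a carriers (n_A), the success probability is
    node_b's marginal frequency, and the observation is the joint count.
    """
    if not (0 <= joint_count <= min(node_a.count, node_b.count)):
        raise ValueError("joint count inconsistent with node counts")
    if not (0.0 < node_b.frequency < 1.0):
        raise ValueError(
            "target frequency must be strictly inside (0, 1); "
            "invariant columns carry no correlation signal"
        )
    score = float(
        _signed_scores_vec(
            np.array([node_a.count], dtype=float),
            np.array([joint_count], dtype=float),
            np.array([node_b.frequency], dtype=float),
        )[0]
    )
    return DirectionalScore(
        source=node_a,
        target=node_b,
        joint_count=joint_count,
        conditional_frequency=joint_count / node_a.count,
        signed_log_p=score,
    )


# ---------------------------------------------------------------------------
# node eligibility and all-pairs scoring
# ---------------------------------------------------------------------------

def eligible_nodes(
    aln: Alignment, min_fraction: float, max_fraction: float | None = None
) -> list[ResidueNode]:
    """Residue nodes whose marginal frequency lies in the admitted band.

    ``max_fraction`` defaults to ``1 − min_fraction``, excluding
    quasi-invariant columns whose apparent correlations reflect
    conservation rather than sub-family structure.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    if max_fraction is None:
        max_fraction = 1.0 - min_fraction
    if not (min_fraction <= max_fraction < 1.0):
        raise ValueError("need min_fraction <= max_fraction < 1")
    mat = aln.matrix
    N = aln.N
    nodes: list[ResidueNode] = []
    for j in range(aln.L):
        col = mat[:, j]
        counts = np.bincount(col[col >= 0], minlength=20)
        for code in np.flatnonzero(counts):
            freq = counts[code] / N
            if min_fraction <= freq <= max_fraction:
                nodes.append(
                    ResidueNode(
                        column=j + 1,
                        residue=AMINO_ACIDS[code],
                        count=int(counts[code]),
                        frequency=float(freq),
                    )
                )
    return nodes


def reference_numbering(aln: Alignment, reference_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based residue numbers of a
    reference sequence; columns gapped in the reference are absent."""
    if reference_id not in aln.sequence_ids:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    row = aln.row(reference_id)
    mapping: dict[int, int] = {}
    pos = 0
    for j, c in enumerate(row, start=1):
        if c != "-":
            pos += 1
            mapping[j] = pos
    return mapping


def node_label(node: ResidueNode, refmap: dict[int, int] | None = None) -> str:
    """Vertex label for a residue node.

    With a reference numbering, ``G71`` style; for columns the reference
    does not cover, ``GX(483)`` style (residue, X, alignment column in
    parentheses).  Without a reference, residue + alignment column.
    """
    if refmap is None:
        return f"{node.residue}{node.column}"
    if node.column in refmap:
        return f"{node.residue}{refmap[node.column]}"
    return f"{node.residue}X({node.column})"


def score_table(
    aln: Alignment,
    min_fraction: float,
    max_fraction: float | None = None,
    reference_id: str | None = None,
) -> tuple[list[ResidueNode], pd.DataFrame]:
    """Score every eligible residue-node pair on distinct columns.

    Returns the eligible nodes and a DataFrame with one row per unordered
    pair, holding both directional scores, their signed mean and the
    conditional frequencies.  Sequences gapped at either column of a pair
    are excluded from both the trials and the joint count of that pair's
    binomial tests; marginal frequencies always use the full N.
    """
    nodes = eligible_nodes(aln, min_fraction, max_fraction)
    refmap = reference_numbering(aln, reference_id) if reference_id else None
    labels = [node_label(nd, refmap) for nd in nodes]
    k = len(nodes)
    if k == 0:
        return nodes, pd.DataFrame(columns=SCORE_COLUMNS)
    mat = aln.matrix
    code = {a: i for i, a in enumerate(AMINO_ACIDS)}
    masks = np.zeros((k, aln.N), dtype=np.float64)
    obs = np.zeros((k, aln.N), dtype=np.float64)  # non-gap at the node's column
    for idx, nd in enumerate(nodes):
        col = mat[:, nd.column - 1]
        masks[idx] = col == code[nd.residue]
        obs[idx] = col != _GAP_CODE
    joint = masks @ masks.T                # sequences carrying both residues
    trials = masks @ obs.T                 # trials[i, j]: i-carriers observed at j's column

    cols = np.array([nd.column for nd in nodes])
    counts = np.array([nd.count for nd in nodes], dtype=float)
    freqs = np.array([nd.frequency for nd in nodes])

    ia, ib = np.triu_indices(k, 1)
    distinct = cols[ia] != cols[ib]
    ia, ib = ia[distinct], ib[distinct]
    if len(ia) == 0:
        return nodes, pd.DataFrame(columns=SCORE_COLUMNS)

    score_ab = _signed_scores_vec(trials[ia, ib], joint[ia, ib], freqs[ib])
    score_ba = _signed_scores_vec(trials[ib, ia], joint[ib, ia], freqs[ia])

    df = pd.DataFrame(
        {
            "col_a": cols[ia],
            "res_a": [nodes[i].residue for i in ia],
            "col_b": cols[ib],
            "res_b": [nodes[i].residue for i in ib],
            "n_a": counts[ia].astype(int),
            "n_b": counts[ib].astype(int),
            "joint_ab": joint[ia, ib].astype(int),
            "joint_ba": joint[ib, ia].astype(int),
            "score_ab": score_ab,
            "score_ba": score_ba,
            "mean_score": 0.5 * (score_ab + score_ba),
            "f_b_given_a": joint[ia, ib] / counts[ia],
            "f_a_given_b": joint[ib, ia] / counts[ib],
            "label_a": [labels[i] for i in ia],
            "label_b": [labels[i] for i in ib],
        }
    )
    return nodes, df


def score_all_pairs(
    aln: Alignment,
    min_fraction: float,
    max_fraction: float | None = None,
    reference_id: str | None = None,
) -> list[CorrelationEdge]:
    """All-pairs scoring returning :class:`CorrelationEdge` objects."""
    nodes, df = score_table(aln, min_fraction, max_fraction, reference_id)
    return edges_from_table(nodes, df)


def edges_from_table(
    nodes: Sequence[ResidueNode], df: pd.DataFrame
) -> list[CorrelationEdge]:
    """Materialise :class:`CorrelationEdge` objects from a score table."""
    index = {(nd.column, nd.residue): nd for nd in nodes}
    edges = []
    for row in df.itertuples(index=False):
        edges.append(
            CorrelationEdge(
                node_a=index[(row.col_a, row.res_a)],
                node_b=index[(row.col_b, row.res_b)],
                score_ab=row.score_ab,
                score_ba=row.score_ba,
                freq_b_given_a=row.f_b_given_a,
                freq_a_given_b=row.f_a_given_b,
                joint_count=int(row.joint_ab),
                label_a=row.label_a,
                label_b=row.label_b,
            )
        )
    return edges


def min_perturbation_fraction(
    aln: Alignment | int, clt_constant: float = 10.0
) -> float:
    """Smallest admissible perturbation size as a fraction of the alignment.

    A perturbation restricted to f·N sequences supports a binomial test on a
    frequency q only if the count variance f·N·q(1−q) is large enough for
    the normal regime (a central-limit criterion).  The most extreme
    admitted marginal frequency equals the threshold itself, so we return
    the smallest f on a 0.05 grid with (f·N)·f·(1−f) ≥ ``clt_constant``.
    """
    if clt_constant <= 0:
        raise ValueError("clt_constant must be positive")
    N = aln if isinstance(aln, int) else aln.N
    for step in range(1, 20):
        f = step * 0.05
        if f * N * f * (1.0 - f) >= clt_constant:
            return round(f, 2)
    raise ValueError(
        f"no perturbation fraction below 1 satisfies the central-limit "
        f"criterion for N={N}; more sequences are needed"
    )
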