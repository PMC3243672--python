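"""Community-level statistics: self-correlation, Δ_AB, ranking, adherence.

These are the interpretation layer of the pipeline.  Given the communities
found in the signed correlation network they quantify (i) why a community's
members hang together (self-correlation matrices of conditional residue
frequencies), (ii) how two communities relate — mutually exclusive, or
independent (the Δ_AB statistic, the mean signed raw score between member
pairs), (iii) which members matter most (iterative elimination ranking),
and (iv) how well an individual sequence fits a community (adherence, a
weight-normalised fraction of the community's residue pairs the sequence
carries, between 0 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment
from .network import CorrelationNetwork
from .scoring import ResidueNode

__all__ = [
    "SelfCorrelationMatrix",
    "MemberRanking",
    "self_correlation_matrix",
    "delta_ab",
    "delta_matrix",
    "rank_members",
    "adherence",
    "adherence_table",
    "ScoreLookup",
]


class ScoreLookup:
    """Directional score lookup keyed by vertex labels.

    Built from the unfiltered all-pairs score table; pairs absent from the
    table (same-column pairs, or nodes outside the eligibility band) have
    no score and are skipped or treated as zero depending on the caller.
    """

    def __init__(self, table: pd.DataFrame):
        self._dir: dict[tuple[str, str], float] = {}
        self._mean: dict[tuple[str, str], float] = {}
        for row in table.itertuples(index=False):
            a, b = row.label_a, row.label_b
            self._dir[(a, b)] = row.score_ab
            self._dir[(b, a)] = row.score_ba
            key = (a, b) if a <= b else (b, a)
            self._mean[key] = row.mean_score

    def directional(self, source: str, target: str) -> float | None:
        return self._dir.get((source, target))

    def mean(self, a: str, b: str) -> float | None:
        return self._mean.get((a, b) if a <= b else (b, a))


@dataclass
class SelfCorrelationMatrix:
    """Overall and pairwise conditional frequencies for one community."""

    members: list[str]
    overall_freq: list[float]           # percentages
    conditional_freq: np.ndarray        # (r, c): % of c-carriers that carry r

    def to_dataframe(self) -> pd.DataFrame:
        data = {"ALL": [round(v, 1) for v in self.overall_freq]}
        for c, lab in enumerate(self.members):
            col = []
            for r in range(len(self.members)):
                col.append("X" if r == c else round(self.conditional_freq[r, c], 1))
            data[lab] = col
        return pd.DataFrame(data, index=self.members)


@dataclass
class MemberRanking:
    """Elimination order (ascending importance) and the final member pair."""

    elimination_order: list[tuple[str, float]]
    final_pair: tuple[str, str, float] | None


def _member_nodes(members: list) -> list[tuple[str, int, str]]:
    """Normalise members to (label, column, residue) and sanity-check them."""
    out = []
    for m in members:
        if isinstance(m, ResidueNode):
            out.append((f"{m.residue}{m.column}", m.column, m.residue))
        else:
            label, column, residue = m
            out.append((label, column, residue))
    return out


def self_correlation_matrix(
    aln: Alignment, members: list, labels: list[str] | None = None
) -> SelfCorrelationMatrix:
    """Frequencies of each member residue overall and conditioned on every
    other member, as percentages (full precision; round when reporting).

    ``members`` may be :class:`ResidueNode` objects or
    ``(label, column, residue)`` triples; members must lie on distinct
    columns and be present in the alignment.
    """
    if not members:
        raise ValueError("members must be non-empty")
    norm = _member_nodes(members)
    cols = [c for _, c, _ in norm]
    if len(set(cols)) != len(cols):
        raise ValueError("members must lie on distinct columns")
    from .alignment import _AA_CODE

    mat = aln.matrix
    masks = []
    for label, column, residue in norm:
        mask = mat[:, column - 1] == _AA_CODE[residue]
        if not mask.any():
            raise ValueError(f"member {label} absent from the alignment")
        masks.append(mask)
    masks = np.array(masks, dtype=float)
    counts = masks.sum(axis=1)
    overall = (100.0 * counts / aln.N).tolist()
    joint = masks @ masks.T
    conditional = 100.0 * joint / counts[None, :]
    np.fill_diagonal(conditional, np.nan)
    member_labels = labels if labels is not None else [lab for lab, _, _ in norm]
    return SelfCorrelationMatrix(
        members=list(member_labels),
        overall_freq=overall,
        conditional_freq=conditional,
    )


def delta_ab(
    scores: ScoreLookup | pd.DataFrame,
    A: list[str],
    B: list[str],
    direction_resolved: bool = True,
) -> float:
    """Δ_AB: mean signed raw correlation score between two communities.

    Off-diagonal (A ≠ B): the mean over member pairs (a ∈ A, b ∈ B) of the
    unfiltered score — sub-threshold pairs contribute their raw score, not
    zero.  In the default direction-resolved mode the score of a→b
    (community A perturbing) is used, which makes Δ_AB ≠ Δ_BA in general;
    with ``direction_resolved=False`` the two-direction mean is used and
    Δ is symmetric.  Diagonal (A = B, the same member set): mean over
    unordered within-community pairs; 0 for singletons.

    Pairs with no defined score (members sharing a column) are excluded
    from the average.  Large negative values flag mutually exclusive
    traits; values near zero flag independent traits.
    """
    if not A or not B:
        raise ValueError("communities must be non-empty")
    lookup = scores if isinstance(scores, ScoreLookup) else ScoreLookup(scores)
    same = set(A) == set(B)
    values: list[float] = []
    if same:
        if len(A) == 1:
            return 0.0
        for i, a in enumerate(A):
            for b in A[i + 1:]:
                v = lookup.mean(a, b)
                if v is not None:
                    values.append(v)
    else:
        for a in A:
            for b in B:
                if a == b:
                    continue
                v = (
                    lookup.directional(a, b)
                    if direction_resolved
                    else lookup.mean(a, b)
                )
                if v is not None:
                    values.append(v)
    if not values:
        return 0.0
    return float(np.mean(values))


def delta_matrix(
    scores: ScoreLookup | pd.DataFrame,
    communities: list[list[str]],
    direction_resolved: bool = True,
) -> pd.DataFrame:
    """Square Δ matrix over all communities of a partition (1-based index)."""
    lookup = scores if isinstance(scores, ScoreLookup) else ScoreLookup(scores)
    k = len(communities)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            out[i, j] = delta_ab(
                lookup, communities[i], communities[j], direction_resolved
            )
    idx = [str(i + 1) for i in range(k)]
    return pd.DataFrame(out, index=idx, columns=idx)


def rank_members(
    scores: ScoreLookup | pd.DataFrame, members: list[str]
) -> MemberRanking:
    """Iterative elimination ranking of community members.

    Repeatedly removes the member whose mean raw score against the
    *remaining* members is lowest (mean and sum order members identically
    within a round; the mean is reported), until two members are left.
    Missing pairwise scores count as 0; ties break by label order.
    Communities of fewer than three members yield a trivial ranking.
    """
    if len(members) < 2:
        raise ValueError("ranking needs at least two members")
    lookup = scores if isinstance(scores, ScoreLookup) else ScoreLookup(scores)

    def pair_score(a: str, b: str) -> float:
        v = lookup.mean(a, b)
        return 0.0 if v is None else v

    remaining = sorted(members)
    order: list[tuple[str, float]] = []
    while len(remaining) > 2:
        means = {
            m: float(
                np.mean([pair_score(m, o) for o in remaining if o != m])
            )
            for m in remaining
        }
        worst = min(remaining, key=lambda m: (means[m], m))
        order.append((worst, means[worst]))
        remaining.remove(worst)
    a, b = remaining
    return MemberRanking(
        elimination_order=order, final_pair=(a, b, pair_score(a, b))
    )


def adherence(
    row: str,
    members: list[tuple[str, int, str]],
    weights: dict[tuple[str, str], float],
) -> float:
    """Adh(S, A): weighted fraction of community A's residue pairs that
    sequence S carries.

    ``weights`` maps unordered member-label pairs to the positive
    intra-community edge weights; pairs without a stored edge contribute 0
    to numerator and denominator alike.  A sequence carrying every member
    residue scores exactly 1, one carrying none scores 0.
    """
    if len(members) < 2:
        raise ValueError("adherence needs a community of at least two members")
    present = {
        label: (row[column - 1] == residue) for label, column, residue in members
    }
    total = 0.0
    got = 0.0
    for i, (la, _, _) in enumerate(members):
        for lb, _, _ in members[i + 1:]:
            key = (la, lb) if la <= lb else (lb, la)
            w = weights.get(key, 0.0)
            if w <= 0:
                continue
            total += w
            if present[la] and present[lb]:
                got += w
    if total == 0:
        raise ValueError("community has zero positive intra-community weight")
    return got / total


def adherence_table(
    aln: Alignment, net: CorrelationNetwork, partition
) -> pd.DataFrame:
    """Adherence of every sequence to every multi-member community.

    Long format: (sequence_id, community, adherence).  Communities of
    fewer than two members, or with no positive internal edge, are skipped
    (adherence is undefined for them).
    """
    g = net.graph
    weights = {
        ((u, v) if u <= v else (v, u)): d["weight"]
        for u, v, d in g.edges(data=True)
        if d["weight"] > 0
    }
    rows = []
    for idx, members in enumerate(partition.communities(), start=1):
        if len(members) < 2:
            continue
        triples = [
            (lab, g.nodes[lab]["column"], g.nodes[lab]["residue"])
            for lab in members
        ]
        intra = {
            (a, b): w
            for (a, b), w in weights.items()
            if a in members and b in members
        }
        if not intra:
            continue
        for sid, row in zip(aln.sequence_ids, aln.rows):
            rows.append(
                {
                    "sequence_id": sid,
                    "community": idx,
                    "adherence": adherence(row, triples, intra),
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "community", "adherence"])
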