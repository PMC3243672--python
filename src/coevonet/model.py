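"""Model/Results interface over the full correlation-network analysis.

`ResidueCorrelationModel` holds an alignment plus the analysis settings;
`fit()` runs identity culling, all-pairs binomial-tail scoring, network
filtering and signed-modularity community detection, and returns a
`ResidueCorrelationResults` carrying the score table, the network, the
partition and accessors for every community statistic, plus a `summary()`
table in the style of classical statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics
from .alignment import Alignment, cull_by_identity, read_alignment
from .community import CommunityPartition, detect_communities
from .network import CorrelationNetwork, build_network
from .scoring import (
    ResidueNode,
    edges_from_table,
    min_perturbation_fraction,
    score_table,
)

__all__ = ["ResidueCorrelationModel", "ResidueCorrelationResults"]


class ResidueCorrelationModel:
    """Residue-specific correlation analysis of a protein family alignment.

    Parameters
    ----------
    alignment
        The input multiple sequence alignment.
    min_fraction
        Minimum marginal frequency for a (column, residue) node to enter
        the analysis; ``"auto"`` derives it from the central-limit
        criterion on the alignment size.
    max_fraction
        Upper frequency bound (default ``1 − min_fraction``), excluding
        quasi-invariant columns.
    minlogp
        Minimum |signed score| for a pair to become a network edge.
    delta_f
        Frequency-shift threshold: positive edges need both conditional
        frequencies above ``1 − delta_f``, negative edges below ``delta_f``.
    identity_cutoff
        If given, sequences are culled so that no surviving pair exceeds
        this pairwise identity.
    reference_id
        Optional sequence whose residue numbering labels the vertices.
    """

    def __init__(
        self,
        alignment: Alignment,
        min_fraction: float | str = "auto",
        max_fraction: float | None = None,
        minlogp: float = 10.0,
        delta_f: float = 0.2,
        identity_cutoff: float | None = None,
        reference_id: str | None = None,
        clt_constant: float = 10.0,
    ):
        self.input_alignment = alignment
        self.minlogp = minlogp
        self.delta_f = delta_f
        self.identity_cutoff = identity_cutoff
        self.reference_id = reference_id
        self.clt_constant = clt_constant
        self.culling_log: list[tuple[str, str, float]] = []
        if identity_cutoff is not None:
            self.alignment, self.culling_log = cull_by_identity(
                alignment, identity_cutoff
            )
        else:
            self.alignment = alignment
        if min_fraction == "auto":
            self.min_fraction = min_perturbation_fraction(
                self.alignment, clt_constant
            )
        else:
            self.min_fraction = float(min_fraction)
        self.max_fraction = (
            1.0 - self.min_fraction if max_fraction is None else max_fraction
        )

    @classmethod
    def from_file(cls, path: str | Path, format: str = "fasta", **kwargs):
        return cls(read_alignment(path, format), **kwargs)

    def fit(self, seed: int = 0, n_restarts: int = 10) -> "ResidueCorrelationResults":
        """Run scoring, filtering and community detection."""
        nodes, table = score_table(
            self.alignment,
            self.min_fraction,
            self.max_fraction,
            self.reference_id,
        )
        edges = edges_from_table(nodes, table)
        net = build_network(edges, self.minlogp, self.delta_f)
        partition = detect_communities(net, seed=seed, n_restarts=n_restarts)
        return ResidueCorrelationResults(
            model=self,
            nodes=nodes,
            scores=table,
            network=net,
            partition=partition,
        )


@dataclass
class ResidueCorrelationResults:
    """Fitted results: scores, network, communities and their statistics."""

    model: ResidueCorrelationModel
    nodes: list[ResidueNode]
    scores: pd.DataFrame
    network: CorrelationNetwork
    partition: CommunityPartition
    _lookup: analytics.ScoreLookup | None = field(default=None, repr=False)

    @property
    def score_lookup(self) -> analytics.ScoreLookup:
        if self._lookup is None:
            self._lookup = analytics.ScoreLookup(self.scores)
        return self._lookup

    @property
    def communities(self) -> list[list[str]]:
        return self.partition.communities()

    def community_members(self, index: int) -> list[tuple[str, int, str]]:
        g = self.network.graph
        return [
            (lab, g.nodes[lab]["column"], g.nodes[lab]["residue"])
            for lab in self.communities[index - 1]
        ]

    def self_correlation(self, index: int) -> analytics.SelfCorrelationMatrix:
        members = self.community_members(index)
        return analytics.self_correlation_matrix(
            self.model.alignment,
            [(lab, col, res) for lab, col, res in members],
        )

    def delta_matrix(self, direction_resolved: bool = True) -> pd.DataFrame:
        return analytics.delta_matrix(
            self.score_lookup, self.communities, direction_resolved
        )

    def delta(self, a: int, b: int, direction_resolved: bool = True) -> float:
        return analytics.delta_ab(
            self.score_lookup,
            self.communities[a - 1],
            self.communities[b - 1],
            direction_resolved,
        )

    def rank_members(self, index: int) -> analytics.MemberRanking:
        return analytics.rank_members(self.score_lookup, self.communities[index - 1])

    def adherence(self) -> pd.DataFrame:
        return analytics.adherence_table(
            self.model.alignment, self.network, self.partition
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Residue Correlation Network Analysis",
            "=" * 60,
            f"Sequences (analysed)        {m.alignment.N}",
            f"  removed by culling        {len(m.culling_log)}",
            f"Alignment columns           {m.alignment.L}",
            f"Eligible residue nodes      {len(self.nodes)}",
            f"Frequency band              [{m.min_fraction:.2f}, {m.max_fraction:.2f}]",
            f"Scored pairs                {len(self.scores)}",
            f"Network edges (|score|>{m.minlogp:g}, Δf={m.delta_f:g})"
            f"   {self.network.n_edges}",
            f"Network vertices            {len(self.network.vertices)}",
            f"Communities                 {self.partition.n_communities}",
            f"Signed modularity Q         {self.partition.modularity:.4f}",
            "-" * 60,
        ]
        if self.partition.n_communities:
            lines.append("Community  Size  Δ_AA     Members")
            for i, members in enumerate(self.communities, start=1):
                d = analytics.delta_ab(self.score_lookup, members, members)
                shown = " ".join(members[:8]) + (" …" if len(members) > 8 else "")
                lines.append(f"{i:<10d}{len(members):<6d}{d:<9.2f}{shown}")
        lines.append("=" * 60)
        return "\n".join(lines)
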