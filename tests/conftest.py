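"""Shared fixtures: tiny hand-built alignments and the planted fixture."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from coevonet.alignment import Alignment
from coevonet.synthetic import generate_alignment, sod_like_classes

PLANTED_EXCLUSIVE_A = {f"{r}{c}" for c, r in zip([5, 6, 7, 8, 9, 10], "HDWGKQ")}
PLANTED_EXCLUSIVE_B = {f"{r}{c}" for c, r in zip([5, 6, 7, 8, 9, 10], "ANYERT")}
PLANTED_INDEPENDENT = {f"{r}{c}" for c, r in zip([20, 21, 22, 23, 24, 25], "CFLMPS")}


@pytest.fixture
def covarying_alignment() -> Alignment:
    """40 sequences, two perfectly co-varying two-state columns (3 and 7).

    All other columns are invariant and therefore ineligible.
    """
    rows = []
    for i in range(40):
        a, d = ("A", "D") if i < 20 else ("C", "E")
        row = list("GGGGGGGG")
        row[2] = a
        row[6] = d
        rows.append("".join(row))
    return Alignment([f"s{i}" for i in range(40)], rows)


@pytest.fixture
def planted_fixture():
    """The standard planted alignment: two exclusive classes + one
    independent class, N=800, fidelity 0.95."""
    aln, truth = generate_alignment(800, 50, sod_like_classes(), seed=3)
    return aln, truth


def random_signed_graph(rng: np.random.Generator, n: int, neg_prob: float = 0.4) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(f"v{i:02d}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                sign = -1.0 if rng.random() < neg_prob else 1.0
                g.add_edge(
                    f"v{i:02d}", f"v{j:02d}", weight=sign * rng.uniform(1, 10)
                )
    return g
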