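"""Synthetic alignments with planted sub-family structure.

The generator emulates the statistical situation the correlation pipeline
assumes: a protein family containing sub-families ("classes"), each
defined by a set of class-specific residues that co-occur at high
frequency within the class.  Two layouts matter:

* mutually exclusive classes share the same columns but use different
  residues there (metal-selectivity style: the same positions carry one
  residue set in one sub-family and another in the other);
* independent classes occupy disjoint columns and membership is assigned
  independently of the other classes (oligomeric-state style).

All remaining columns are background: i.i.d. draws from a per-column
categorical distribution with Dirichlet-sampled composition, so marginal
frequencies routinely fall inside the eligibility band and the null is
non-trivial.  No phylogenetic correlation between sequences is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AMINO_ACIDS, Alignment

__all__ = ["PlantedClassSpec", "generate_alignment", "sod_like_classes"]


@dataclass
class PlantedClassSpec:
    """One planted sub-family.

    ``columns`` are 1-based alignment columns; ``residues`` gives the
    class-specific residue for each of them.  ``fidelity`` is the
    probability a class member actually carries the class residue at a
    class column (the rest is background noise).  Exclusive classes name
    each other via ``exclusive_with`` and must share an identical column
    list with disjoint residues; ``independent`` marks classes whose
    membership is drawn independently of all others.
    """

    name: str
    columns: list[int]
    residues: list[str]
    class_fraction: float
    fidelity: float = 0.9
    exclusive_with: str | None = None
    independent: bool = False


def _validate(classes: list[PlantedClassSpec], n_columns: int) -> None:
    names = [c.name for c in classes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    by_name = {c.name: c for c in classes}
    for c in classes:
        if len(c.columns) != len(c.residues):
            raise ValueError(f"class {c.name}: columns and residues differ in length")
        if any(not (1 <= j <= n_columns) for j in c.columns):
            raise ValueError(f"class {c.name}: column out of range")
        if len(set(c.columns)) != len(c.columns):
            raise ValueError(f"class {c.name}: repeated columns")
        if any(r not in AMINO_ACIDS for r in c.residues):
            raise ValueError(f"class {c.name}: non-canonical residue")
        if not (0 < c.class_fraction <= 1) or not (0 < c.fidelity <= 1):
            raise ValueError(f"class {c.name}: fractions must be in (0, 1]")
        if c.exclusive_with is not None:
            other = by_name.get(c.exclusive_with)
            if other is None:
                raise ValueError(f"class {c.name}: unknown partner {c.exclusive_with}")
            if other.exclusive_with != c.name:
                raise ValueError(
                    f"exclusivity must be mutual: {c.name}/{other.name}"
                )
            if sorted(other.columns) != sorted(c.columns):
                raise ValueError(
                    f"exclusive classes {c.name}/{other.name} must share columns"
                )
            res_c = {j: r for j, r in zip(c.columns, c.residues)}
            res_o = {j: r for j, r in zip(other.columns, other.residues)}
            if any(res_c[j] == res_o[j] for j in res_c):
                raise ValueError(
                    f"exclusive classes {c.name}/{other.name} share a residue"
                )
    # exclusive groups partition sequences: fractions must sum to <= 1
    seen = set()
    for c in classes:
        if c.exclusive_with and c.name not in seen:
            other = by_name[c.exclusive_with]
            seen.update({c.name, other.name})
            if c.class_fraction + other.class_fraction > 1 + 1e-9:
                raise ValueError(
                    f"exclusive fractions of {c.name}+{other.name} exceed 1"
                )
    # independent traits must not share columns with anything else
    col_owner: dict[int, str] = {}
    for c in classes:
        for j in c.columns:
            owner = col_owner.get(j)
            if owner is not None and by_name[owner].exclusive_with != c.name:
                raise ValueError(
                    f"column {j} used by both {owner} and {c.name} "
                    "without exclusivity"
                )
            col_owner[j] = c.name


def generate_alignment(
    n_sequences: int,
    n_columns: int,
    classes: list[PlantedClassSpec],
    background_alphabet_size: int = 6,
    seed: int = 0,
) -> tuple[Alignment, dict[str, list[bool]]]:
    """Sample an alignment with planted classes and its ground truth.

    Returns the alignment and per-class boolean membership labels (one
    entry per sequence).  Background compositions are symmetric
    Dirichlet(1) over a per-column random subset of
    ``background_alphabet_size`` residues; at class columns the background
    alphabet excludes every class residue, so non-members never carry a
    class marker by chance.  Fully reproducible for a given ``seed``.
    """
    _validate(classes, n_columns)
    rng = np.random.default_rng(seed)
    by_name = {c.name: c for c in classes}

    # membership assignment
    labels: dict[str, np.ndarray] = {}
    done = set()
    for c in classes:
        if c.name in done:
            continue
        if c.exclusive_with:
            other = by_name[c.exclusive_with]
            u = rng.random(n_sequences)
            labels[c.name] = u < c.class_fraction
            labels[other.name] = (u >= c.class_fraction) & (
                u < c.class_fraction + other.class_fraction
            )
            done.update({c.name, other.name})
        else:
            labels[c.name] = rng.random(n_sequences) < c.class_fraction
            done.add(c.name)

    class_residues_at: dict[int, set[str]] = {}
    for c in classes:
        for j, r in zip(c.columns, c.residues):
            class_residues_at.setdefault(j, set()).add(r)

    mat = np.empty((n_sequences, n_columns), dtype="U1")
    for j in range(1, n_columns + 1):
        excluded = class_residues_at.get(j, set())
        pool = np.array([a for a in AMINO_ACIDS if a not in excluded])
        # class columns: residues outside the sub-family are heterogeneous,
        # as at real determinant positions, so draw from the full remaining
        # alphabet; plain background columns use a narrow alphabet so their
        # marginals land inside the eligibility band and the null is tested
        size = len(pool) if excluded else min(background_alphabet_size, len(pool))
        letters = rng.choice(pool, size=size, replace=False)
        probs = rng.dirichlet(np.ones(size))
        mat[:, j - 1] = rng.choice(letters, size=n_sequences, p=probs)

    for c in classes:
        members = labels[c.name]
        for j, r in zip(c.columns, c.residues):
            carry = members & (rng.random(n_sequences) < c.fidelity)
            mat[carry, j - 1] = r

    ids = [f"seq{i+1:05d}" for i in range(n_sequences)]
    aln = Alignment(ids, ["".join(row) for row in mat])
    truth = {name: mask.tolist() for name, mask in labels.items()}
    return aln, truth


def sod_like_classes(
    fidelity: float = 0.95,
    exclusive_fractions: tuple[float, float] = (0.5, 0.45),
    independent_fraction: float = 0.5,
) -> list[PlantedClassSpec]:
    """The standard planted layout used throughout the test suite.

    Two mutually exclusive six-residue classes sharing columns 5–10
    (emulating metal-selectivity sub-families whose determinants sit at
    the same positions with different residue types) plus one independent
    six-residue class on columns 20–25 (emulating an unrelated trait such
    as oligomeric state).
    """
    cols = [5, 6, 7, 8, 9, 10]
    return [
        PlantedClassSpec(
            name="classA",
            columns=cols,
            residues=list("HDWGKQ"),
            class_fraction=exclusive_fractions[0],
            fidelity=fidelity,
            exclusive_with="classB",
        ),
        PlantedClassSpec(
            name="classB",
            columns=cols,
            residues=list("ANYERT"),
            class_fraction=exclusive_fractions[1],
            fidelity=fidelity,
            exclusive_with="classA",
        ),
        PlantedClassSpec(
            name="classC",
            columns=[20, 21, 22, 23, 24, 25],
            residues=list("CFLMPS"),
            class_fraction=independent_fraction,
            fidelity=fidelity,
            independent=True,
        ),
    ]


def write_ground_truth(truth: dict, classes: list[PlantedClassSpec], path: str | Path) -> None:
    """Dump per-sequence labels and the class column/residue map as JSON."""
    payload = {
        "classes": [
            {
                "name": c.name,
                "columns": c.columns,
                "residues": c.residues,
                "class_fraction": c.class_fraction,
                "fidelity": c.fidelity,
                "exclusive_with": c.exclusive_with,
                "independent": c.independent,
            }
            for c in classes
        ],
        "labels": truth,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
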