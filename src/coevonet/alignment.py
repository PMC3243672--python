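"""Multiple sequence alignment container and redundancy handling.

The alignment is the sole data input of the correlation pipeline: a
rectangular block of aligned protein sequences over the 20 amino-acid
letters plus the gap character ``-``.  Ambiguity codes (X, B, Z, U, O) are
retained on input but are treated everywhere downstream as non-matching
observations: they never form residue nodes and never count as identities.

Besides parsing (FASTA and Stockholm, via Biopython), this module provides
the two alignment-level preprocessing steps of the pipeline:

* identity culling — removal of one sequence of every pair above a pairwise
  identity cutoff, to damp phylogenetic redundancy that would otherwise
  masquerade as correlation;
* column shuffling — the permutation null model in which every column is
  independently permuted across sequences, destroying inter-column
  dependence while preserving each column's residue composition exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "Alignment",
    "AlignmentFormatError",
    "read_alignment",
    "write_fasta",
    "pairwise_identity",
    "cull_by_identity",
    "shuffle_columns",
    "AMINO_ACIDS",
    "GAP",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# integer codes used by the cached matrix representation
_GAP_CODE = -1
_OTHER_CODE = -2
_AA_CODE = {a: i for i, a in enumerate(AMINO_ACIDS)}


class AlignmentFormatError(ValueError):
    """Raised when an input file cannot be interpreted as an alignment."""


@dataclass
class Alignment:
    """A rectangular protein multiple sequence alignment.

    Parameters
    ----------
    sequence_ids
        Unique identifiers, one per row.
    rows
        Aligned sequences (equal length, upper case, ``-`` gaps).
    """

    sequence_ids: list[str]
    rows: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("sequence_ids and rows differ in length")
        if len(self.rows) < 1:
            raise AlignmentFormatError("alignment is empty")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            offender = next(
                sid
                for sid, r in zip(self.sequence_ids, self.rows)
                if len(r) != len(self.rows[0])
            )
            raise AlignmentFormatError(
                f"ragged alignment: sequence {offender!r} has a different length"
            )
        if self.L < 1:
            raise AlignmentFormatError("alignment has zero columns")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentFormatError("duplicate sequence identifiers")

    @property
    def N(self) -> int:
        """Number of sequences."""
        return len(self.rows)

    @property
    def L(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    @property
    def matrix(self) -> np.ndarray:
        """Integer-coded (N, L) residue matrix.

        Codes: 0–19 for the canonical amino acids (order of
        :data:`AMINO_ACIDS`), −1 for gaps, −2 for any other letter.
        """
        if self._matrix is None:
            lookup = np.full(128, _OTHER_CODE, dtype=np.int8)
            for aa, code in _AA_CODE.items():
                lookup[ord(aa)] = code
            lookup[ord(GAP)] = _GAP_CODE
            flat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            )
            self._matrix = lookup[flat].reshape(self.N, self.L)
        return self._matrix

    def row(self, sequence_id: str) -> str:
        return self.rows[self.sequence_ids.index(sequence_id)]

    def __len__(self) -> int:
        return self.N


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from ``path`` in FASTA or Stockholm format.

    Rows are upper-cased and ``.`` gaps (the Stockholm/PFAM convention for
    insert states) are normalised to ``-``.  Ragged FASTA input raises
    :class:`AlignmentFormatError` naming the offending sequence.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [_normalise(str(r.seq)) for r in records]
    return Alignment(ids, rows)


def read_alignment_string(text: str, format: str = "fasta") -> Alignment:
    """Parse an alignment from an in-memory string (mainly for tests)."""
    handle = io.StringIO(text)
    if format == "fasta":
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(AlignIO.read(handle, "stockholm"))
    if not records:
        raise AlignmentFormatError("no sequences found")
    return Alignment([r.id for r in records], [_normalise(str(r.seq)) for r in records])


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def _char_array(row: str) -> np.ndarray:
    return np.frombuffer(row.encode("ascii"), dtype=np.uint8)


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over columns where neither row is a gap.

    Ambiguity codes compare by letter equality only in the sense that they
    are never equal to a canonical amino acid; two identical ambiguity codes
    are not counted as a match either (they are not observations).
    Returns 0.0 when no gap-free column exists.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned sequences differ in length")
    a = _char_array(row_a)
    b = _char_array(row_b)
    gap = ord(GAP)
    comparable = (a != gap) & (b != gap)
    n = int(comparable.sum())
    if n == 0:
        return 0.0
    canonical = np.zeros(128, dtype=bool)
    for aa in AMINO_ACIDS:
        canonical[ord(aa)] = True
    matches = comparable & (a == b) & canonical[a]
    return float(matches.sum()) / n


def _residue_count(row: str) -> int:
    return sum(1 for c in row if c != GAP)


def cull_by_identity(
    aln: Alignment, cutoff: float
) -> tuple[Alignment, list[tuple[str, str, float]]]:
    """Remove redundant sequences above a pairwise identity cutoff.

    A single greedy pass in input order compares each sequence to every
    retained predecessor.  Whenever a pair exceeds ``cutoff``, the sequence
    with fewer non-gap residues ("the smallest sequence") is removed; on a
    tie the later sequence in input order is removed.  Survivors keep their
    original order, so the procedure is deterministic and idempotent.

    Returns the culled alignment and a removal log of
    ``(removed_id, kept_id, identity)`` tuples.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    kept: list[int] = []
    sizes = [_residue_count(r) for r in aln.rows]
    log: list[tuple[str, str, float]] = []
    for i in range(aln.N):
        drop_candidate = False
        displaced: list[tuple[int, float]] = []
        for j in kept:
            ident = pairwise_identity(aln.rows[i], aln.rows[j])
            if ident > cutoff:
                # remove the smaller of the pair; tie -> the later (i)
                if sizes[i] <= sizes[j]:
                    log.append((aln.sequence_ids[i], aln.sequence_ids[j], ident))
                    drop_candidate = True
                    break
                displaced.append((j, ident))
        if drop_candidate:
            continue
        for j, ident in displaced:
            kept.remove(j)
            log.append((aln.sequence_ids[j], aln.sequence_ids[i], ident))
        kept.append(i)
    culled = Alignment(
        [aln.sequence_ids[i] for i in kept], [aln.rows[i] for i in kept]
    )
    return culled, log


def shuffle_columns(aln: Alignment, seed: int) -> Alignment:
    """Independently permute every column across sequences.

    The permutation null model: per-column residue compositions (including
    gaps) are preserved exactly, while any dependence between columns is
    destroyed.  Reproducible for a given ``seed``.
    """
    rng = np.random.default_rng(seed)
    mat = np.array([list(r) for r in aln.rows])
    for j in range(aln.L):
        mat[:, j] = mat[rng.permutation(aln.N), j]
    rows = ["".join(row) for row in mat]
    return Alignment(list(aln.sequence_ids), rows)
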