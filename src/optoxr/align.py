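"""Global pairwise alignment and star-topology multiple alignment.

The pairwise aligner is a three-state affine-gap Needleman–Wunsch with a
fixed traceback tie-break (diagonal > up > left) so outputs are
bit-reproducible. A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
Ends are penalized (no terminal-gap discount): domain boundaries near the
termini matter for loop transfer, so terminal gaps must compete on cost.

The multiple alignment is reference-centric (star topology): every homolog is
aligned pairwise to the reference and the pairwise gap structures are merged
into reference coordinates ("once a gap, always a gap"). This makes
homolog -> reference coordinate transfer exact, which is all the topology
consensus needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import BoundsError, ParameterError
from .seqio import PROTEIN_ALPHABET, ProteinSequence

NEG = -(10**9)

DEFAULT_GAP_OPEN = 10
DEFAULT_GAP_EXTEND = 1


class SubstitutionMatrix:
    """Symmetric residue-pair score lookup (default BLOSUM62)."""

    def __init__(self, scores: dict[tuple[str, str], int], name: str = "custom"):
        self.name = name
        self._scores = {}
        for (a, b), s in scores.items():
            self._scores[(a, b)] = int(s)
            self._scores[(b, a)] = int(s)

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"pair ({a!r}, {b!r}) not defined in matrix {self.name}")

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        m = substitution_matrices.load("BLOSUM62")
        letters = sorted(PROTEIN_ALPHABET)
        scores = {
            (a, b): int(m[a, b]) for a in letters for b in letters
        }
        return cls(scores, name="BLOSUM62")

    @classmethod
    def from_file(cls, path, name: Optional[str] = None) -> "SubstitutionMatrix":
        """Load a square-matrix text file (header row of symbols, one row per
        symbol)."""
        path = Path(path)
        lines = [l.split() for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
        header = lines[0]
        scores = {}
        for row in lines[1:]:
            a = row[0]
            for b, s in zip(header, row[1:]):
                scores[(a, b)] = int(s)
        return cls(scores, name=name or path.stem)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of a global alignment of A against B.

    ``column_map[i]`` is the alignment column holding position ``i`` of A.
    """

    aligned_a: str
    aligned_b: str
    score: int
    column_map: tuple[int, ...]

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def ungapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    def ungapped_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def recompute_score(self, matrix: SubstitutionMatrix, gap_open: int, gap_extend: int) -> int:
        """Re-score the emitted alignment column by column (audit helper)."""
        total = 0
        in_gap_a = in_gap_b = False
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("double-gap column")
            if ca == "-":
                total -= gap_extend if in_gap_a else gap_open
                in_gap_a, in_gap_b = True, False
            elif cb == "-":
                total -= gap_extend if in_gap_b else gap_open
                in_gap_a, in_gap_b = False, True
            else:
                total += matrix.score(ca, cb)
                in_gap_a = in_gap_b = False
        return total


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap costs.

    Three DP states per cell: M (a_i aligned to b_j), X (gap in B, consuming
    A, "up"), Y (gap in A, consuming B, "left"). Traceback prefers
    diagonal > up > left at every tie, making the emitted alignment unique.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("global_align requires non-empty sequences")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)

    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in B (up)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in A (left)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        ca = sa[i - 1]
        row_scores = [matrix.score(ca, cb) for cb in sb]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = row_scores[j - 1]
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open, Yi[j - 1] - gap_extend)

    # traceback: state priority M > X > Y (diagonal > up > left)
    i, j = n, m
    final = max(M[i, j], X[i, j], Y[i, j])
    if M[i, j] == final:
        state = "M"
    elif X[i, j] == final:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = matrix.score(sa[i - 1], sb[j - 1])
            prev = M[i, j] - s
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif X[i, j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cur = X[i, j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            if M[i - 1, j] - gap_open == cur:
                state = "M"
            elif X[i - 1, j] - gap_extend == cur:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            cur = Y[i, j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            if M[i, j - 1] - gap_open == cur:
                state = "M"
            elif X[i, j - 1] - gap_open == cur:
                state = "X"
            else:
                state = "Y"
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    column_map = tuple(c for c, ch in enumerate(aligned_a) if ch != "-")
    aln = PairwiseAlignment(aligned_a, aligned_b, int(final), column_map)
    assert aln.ungapped_a() == sa and aln.ungapped_b() == sb
    return aln


@dataclass(frozen=True)
class MultipleAlignment:
    """Reference-centric multiple alignment; row 0 is the reference."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for k in range(0, len(row), 60):
                    fh.write(row[k : k + 60] + "\n")


def star_msa(
    reference: ProteinSequence,
    others: Sequence[ProteinSequence],
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Star multiple alignment around ``reference``.

    Each other sequence is aligned pairwise to the reference; the reference
    gap structures are merged by taking, in every inter-residue slot, the
    maximum number of inserted columns over all pairwise alignments.
    """
    if not others:
        raise ParameterError("star_msa requires at least one other sequence")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    n = len(reference)
    pairwise = [global_align(reference, o, matrix, gap_open, gap_extend) for o in others]

    # chunks[k] for slot k in 0..n: characters of the other row aligned to
    # reference-gap columns in that slot; slot k precedes reference residue k.
    def split_chunks(aln: PairwiseAlignment) -> list[str]:
        chunks: list[list[str]] = [[] for _ in range(n + 1)]
        ref_pos = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == "-":
                chunks[ref_pos].append(cb)
            else:
                ref_pos += 1
        return ["".join(c) for c in chunks]

    def residue_cols(aln: PairwiseAlignment) -> list[str]:
        """Other-row character aligned to each reference residue."""
        out = []
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                out.append(cb)
        return out

    all_chunks = [split_chunks(p) for p in pairwise]
    slot_width = [max(len(c[k]) for c in all_chunks) for k in range(n + 1)]

    ref_row = "".join(
        "-" * slot_width[k] + (reference.residues[k] if k < n else "")
        for k in range(n + 1)
    )
    rows = [ref_row]
    for aln, chunks in zip(pairwise, all_chunks):
        res = residue_cols(aln)
        row = "".join(
            chunks[k].ljust(slot_width[k], "-") + (res[k] if k < n else "")
            for k in range(n + 1)
        )
        rows.append(row)
    ids = (reference.id,) + tuple(o.id for o in others)
    return MultipleAlignment(ids=ids, rows=tuple(rows))


def map_position(msa: MultipleAlignment, row: int, pos: int) -> Optional[int]:
    """Reference coordinate of position ``pos`` in ``row``.

    Returns ``None`` (gap flag) when the column holding that position is a
    gap in the reference row.
    """
    if not (0 <= row < len(msa.rows)):
        raise BoundsError(f"row {row} out of range")
    row_str = msa.rows[row]
    seen = -1
    col = None
    for c, ch in enumerate(row_str):
        if ch != "-":
            seen += 1
            if seen == pos:
                col = c
                break
    if col is None:
        raise BoundsError(f"position {pos} out of range for row {row}")
    ref = msa.rows[0]
    if ref[col] == "-":
        return None
    return sum(1 for ch in ref[:col] if ch != "-")
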