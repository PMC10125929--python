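"""Case-encoded identity consensus of short C-terminal peptides.

Sets of lamin C-termini are compared right-anchored (column -1 is the very
last residue of each peptide). A shift-only aligner assigns each peptide a
small integer offset; gaps are never inserted — for peptides of at most a
dozen residues, letter-level consensus reproduction does not need them and a
shift-only objective can be optimized exactly.

The consensus string follows the usual identity-threshold case encoding:
uppercase for columns where the modal residue reaches the high identity
threshold (default 90%), lowercase for the low threshold (default 50%) and
``.`` below that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


@dataclass
class AnchoredSet:
    """Peptides with per-sequence shift offsets in a shared column space.

    Offset 0 means right-anchored: the last residue of the peptide sits in
    column -1. Offset ``o`` moves the peptide ``o`` columns to the left (its
    last residue sits in column ``-1 - o``), so the residue of sequence ``s``
    in column ``c`` (negative, counted from the right edge) is
    ``s[len(s) + c + o]`` when that index is in range.
    """

    sequences: list[str]
    offsets: list[int]
    objective: int = 0

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.offsets):
            raise ValueError("one offset per sequence required")

    @property
    def column_range(self) -> tuple[int, int]:
        """(leftmost, rightmost) occupied column, e.g. ``(-12, -1)``."""
        lo = min(-len(s) - o for s, o in zip(self.sequences, self.offsets))
        hi = max(-1 - o for s, o in zip(self.sequences, self.offsets))
        return lo, hi

    def residues_in_column(self, c: int) -> list[str]:
        out = []
        for s, o in zip(self.sequences, self.offsets):
            i = len(s) + c + o
            if 0 <= i < len(s):
                out.append(s[i])
        return out


@dataclass
class ColumnStats:
    column: int
    depth: int  # sequences covering the column
    modal_residue: str
    modal_count: int
    tie: bool  # another residue reached the modal count
    frequencies: dict[str, int] = field(default_factory=dict)


@dataclass
class ConsensusResult:
    """Case-encoded consensus plus per-column residue frequency tables."""

    consensus: str
    columns: list[ColumnStats]
    high: float
    low: float

    def letters(self) -> str:
        """Consensus without case or gap encoding (``.`` columns dropped)."""
        return self.consensus.replace(".", "").upper()


def _objective(sequences: list[str], offsets: list[int]) -> int:
    """Sum over columns of the count of the modal residue."""
    anchored = AnchoredSet(list(sequences), list(offsets))
    lo, hi = anchored.column_range
    total = 0
    for c in range(lo, hi + 1):
        col = anchored.residues_in_column(c)
        if col:
            total += max(col.count(r) for r in set(col))
    return total


def _tie_key(offsets: tuple[int, ...]) -> tuple:
    # ties broken toward offset 0, then deterministically
    return (sum(abs(o) for o in offsets), offsets)


def anchor_align(
    peptides: list[str],
    max_shift: int = 3,
    exhaustive_limit: int = 5,
) -> AnchoredSet:
    """Assign shift offsets maximizing the summed modal-residue count.

    Up to ``exhaustive_limit`` peptides the search enumerates every offset
    vector in ``[-max_shift, max_shift]^k`` and is exactly optimal. Larger
    sets use iterative refinement from the right-anchored start: sequences
    are swept in turn, each moved to its best offset given the others, until
    no move improves the objective. Ties are broken toward offset 0.
    """
    peptides = [str(p).upper() for p in peptides]
    if not peptides:
        raise ValueError("at least one peptide required")
    k = len(peptides)
    if k == 1:
        return AnchoredSet(peptides, [0], objective=_objective(peptides, [0]))
    shifts = range(-max_shift, max_shift + 1)
    if k <= exhaustive_limit:
        best = None
        for offsets in itertools.product(shifts, repeat=k):
            score = _objective(peptides, list(offsets))
            key = (-score, _tie_key(offsets))
            if best is None or key < best[0]:
                best = (key, offsets, score)
        return AnchoredSet(peptides, list(best[1]), objective=best[2])
    # iterative refinement
    offsets = [0] * k
    for _ in range(20):  # sweeps; converges long before this in practice
        changed = False
        for i in range(k):
            best_o, best_key = None, None
            for o in shifts:
                trial = offsets[:i] + [o] + offsets[i + 1 :]
                s = _objective(peptides, trial)
                key = (-s, _tie_key(tuple(trial)))
                if best_key is None or key < best_key:
                    best_key, best_o = key, o
            if best_o != offsets[i]:
                offsets[i] = best_o
                changed = True
        if not changed:
            break
    return AnchoredSet(peptides, offsets, objective=_objective(peptides, offsets))


def consensus_string(
    anchored: AnchoredSet, high: float = 0.90, low: float = 0.50
) -> ConsensusResult:
    """Column-wise identity consensus of an anchored peptide set.

    Unoccupied positions (sequence not covering a column) are excluded from
    both numerator and denominator. A column frequency exactly equal to a
    threshold takes the stronger case. Modal ties are broken alphabetically
    and recorded in the column table.
    """
    if not 0 < low <= high <= 1:
        raise ValueError("thresholds must satisfy 0 < low <= high <= 1")
    if not anchored.sequences:
        raise ValueError("empty anchored set")
    lo, hi = anchored.column_range
    letters = []
    columns = []
    for c in range(lo, hi + 1):
        col = anchored.residues_in_column(c)
        if not col:
            letters.append(".")
            columns.append(ColumnStats(c, 0, "", 0, False, {}))
            continue
        freq = {r: col.count(r) for r in sorted(set(col))}
        modal_count = max(freq.values())
        modal = min(r for r, n in freq.items() if n == modal_count)
        tie = sum(1 for n in freq.values() if n == modal_count) > 1
        f = modal_count / len(col)
        if f >= high:
            letters.append(modal.upper())
        elif f >= low:
            letters.append(modal.lower())
        else:
            letters.append(".")
        columns.append(ColumnStats(c, len(col), modal, modal_count, tie, freq))
    return ConsensusResult(
        consensus="".join(letters), columns=columns, high=high, low=low
    )


def consensus_of(
    peptides: list[str],
    high: float = 0.90,
    low: float = 0.50,
    max_shift: int = 0,
) -> ConsensusResult:
    """Convenience wrapper: anchor (``max_shift=0`` keeps the set strictly
    right-anchored) and derive the consensus in one call."""
    return consensus_string(anchor_align(peptides, max_shift=max_shift), high, low)
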