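"""Global pairwise protein alignment helpers.

Alignment is delegated to Biopython's :class:`~Bio.Align.PairwiseAligner`
(global, BLOSUM62, gap open 10, extend 0.5). On top of the raw alignment
this module derives the two quantities the rest of the package needs: a
percent-identity value (identical residues over aligned columns, internal
gap columns included, terminal gap columns excluded) and a 1-based
coordinate map from one sequence onto the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._aminoacids import validate_sequence

__all__ = ["PairwiseAlignment", "align_global", "identity_fraction"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # End gaps are penalized like internal ones (true global alignment):
    # with free ends the optimizer collapses unrelated pairs onto short
    # high-identity cores and overstates their percent identity.
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of ``seq_a`` (target) against ``seq_b`` (query)."""

    seq_a: str
    seq_b: str
    score: float
    #: aligned coordinate blocks as returned by Biopython: pairs of
    #: half-open (start, end) ranges on seq_a and seq_b.
    blocks_a: tuple[tuple[int, int], ...]
    blocks_b: tuple[tuple[int, int], ...]
    _a_to_b: dict[int, int] = field(repr=False, default_factory=dict)

    @property
    def n_aligned(self) -> int:
        return sum(e - s for s, e in self.blocks_a)

    @property
    def n_matches(self) -> int:
        m = 0
        for (as_, ae), (bs, _) in zip(self.blocks_a, self.blocks_b):
            for k in range(ae - as_):
                if self.seq_a[as_ + k] == self.seq_b[bs + k]:
                    m += 1
        return m

    @property
    def n_columns(self) -> int:
        """Aligned columns between the first and last aligned pair.

        Internal gaps count as columns; unaligned terminal overhangs do not.
        """
        if not self.blocks_a:
            return 0
        a_span = self.blocks_a[-1][1] - self.blocks_a[0][0]
        b_span = self.blocks_b[-1][1] - self.blocks_b[0][0]
        return a_span + b_span - self.n_aligned

    @property
    def identity(self) -> float:
        cols = self.n_columns
        return self.n_matches / cols if cols else 0.0

    def map_a_to_b(self, pos: int) -> int | None:
        """Map a 1-based position on seq_a to seq_b (``None`` if gapped)."""
        return self._a_to_b.get(pos)

    def project(self, pos: int) -> int:
        """Best-effort 1-based projection of a seq_a position onto seq_b.

        Positions falling in a gap are extrapolated from the nearest aligned
        column, preserving the offset.
        """
        hit = self._a_to_b.get(pos)
        if hit is not None:
            return hit
        if not self._a_to_b:
            return pos
        nearest = min(self._a_to_b, key=lambda p: (abs(p - pos), p))
        return self._a_to_b[nearest] + (pos - nearest)


def align_global(seq_a: str, seq_b: str) -> PairwiseAlignment:
    """Globally align two protein sequences and return the column bookkeeping."""
    validate_sequence(seq_a, name="seq_a")
    validate_sequence(seq_b, name="seq_b")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = (
        tuple(tuple(int(x) for x in pair) for pair in part) for part in aln.aligned
    )
    a_to_b: dict[int, int] = {}
    for (as_, ae), (bs, _) in zip(blocks_a, blocks_b):
        for k in range(ae - as_):
            a_to_b[as_ + k + 1] = bs + k + 1
    return PairwiseAlignment(seq_a, seq_b, float(aln.score), blocks_a, blocks_b, a_to_b)


def identity_fraction(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over aligned columns (terminal overhangs excluded)."""
    if seq_a == seq_b:
        validate_sequence(seq_a, name="seq_a")
        return 1.0
    return align_global(seq_a, seq_b).identity
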