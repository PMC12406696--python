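"""Catalytic-motif screening of homology-search candidates.

A candidate retained by the profile search is only *qualified* if the
conserved catalytic and substrate-binding motifs of its clade can be located
in its sequence. Each motif anchor (a 1-based position range on the clade
representative) is projected onto the candidate through a global pairwise
alignment, and a token-wise pattern match is attempted within a tolerance
window around the projected position. Patterns support fixed residues, the
``X`` wildcard (any standard residue, never a gap), bracketed residue sets
(``[D/E]``) and whole-motif alternates (``HD/HAE``); a clade's screening
pattern is its family consensus with the representative's own concrete motif
accepted as an additional alternate. Unqualified sequences are excluded from
the homolog set.

For clades lacking validated structures, an advisory neighbor-joining tree
screen flags sequences falling outside the subtree spanned by validated
members (strict mode excludes them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from skbio import DistanceMatrix
from skbio.tree import nj

from ._aminoacids import ALPHABET
from ._pairwise import PairwiseAlignment, identity_fraction
from .catalog import FAMILY_MOTIF_PATTERNS, ReferenceEnzyme
from .profiles import Hit, align_to_representative

logger = logging.getLogger(__name__)

__all__ = [
    "MotifPattern",
    "MotifCheck",
    "ScreenResult",
    "parse_motif_pattern",
    "motif_for_clade",
    "locate_motifs",
    "screen_candidates",
    "build_nj_tree",
    "tree_screen",
    "DEFAULT_TOLERANCE_WINDOW",
]

DEFAULT_TOLERANCE_WINDOW = 10

Token = frozenset  # a token is the set of residues it accepts ('X' = all 20)

_ANY = frozenset(ALPHABET)


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif: one or more whole-motif alternates of residue tokens."""

    source: str
    alternates: tuple[tuple[Token, ...], ...]
    anchor: tuple[int, int] = (0, 0)  # 1-based inclusive positions on the representative
    tolerance_window: int = DEFAULT_TOLERANCE_WINDOW

    def __post_init__(self) -> None:
        if not self.alternates or any(len(a) == 0 for a in self.alternates):
            raise ValueError(f"motif pattern {self.source!r} has an empty alternate")

    def __str__(self) -> str:
        return self.source

    def matches_at(self, seq: str, start0: int) -> str | None:
        """Matched text if any alternate matches at 0-based ``start0``, else None."""
        for alt in self.alternates:
            end = start0 + len(alt)
            if start0 < 0 or end > len(seq):
                continue
            window = seq[start0:end]
            if all(res in tok for res, tok in zip(window, alt)):
                return window
        return None


def _tokenize(chunk: str, source: str) -> tuple[Token, ...]:
    tokens: list[Token] = []
    i = 0
    while i < len(chunk):
        c = chunk[i]
        if c == "[":
            j = chunk.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced bracket in motif pattern {source!r}")
            residues = [r for r in chunk[i + 1 : j] if r != "/"]
            if not residues or any(r not in ALPHABET for r in residues):
                raise ValueError(f"invalid residue set in motif pattern {source!r}")
            tokens.append(frozenset(residues))
            i = j + 1
        elif c == "X":
            tokens.append(_ANY)
            i += 1
        elif c in ALPHABET:
            tokens.append(frozenset(c))
            i += 1
        else:
            raise ValueError(f"invalid character {c!r} in motif pattern {source!r}")
    return tuple(tokens)


def _split_alternates(pattern: str) -> list[str]:
    """Split on '/' outside brackets ('GNH[D/E]' is one alternate)."""
    parts, depth, cur = [], 0, []
    for c in pattern:
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced bracket in motif pattern {pattern!r}")
        if c == "/" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(c)
    if depth != 0:
        raise ValueError(f"unbalanced bracket in motif pattern {pattern!r}")
    parts.append("".join(cur))
    return parts


def parse_motif_pattern(
    pattern: str,
    anchor: tuple[int, int] = (0, 0),
    tolerance_window: int = DEFAULT_TOLERANCE_WINDOW,
) -> MotifPattern:
    """Parse a motif string such as ``"EGXXXD"``, ``"GNH[D/E]"`` or ``"HD/HAE"``."""
    if not pattern:
        raise ValueError("empty motif pattern")
    alternates = tuple(
        _tokenize(chunk, pattern) for chunk in _split_alternates(pattern)
    )
    return MotifPattern(
        source=pattern, alternates=alternates, anchor=anchor,
        tolerance_window=tolerance_window,
    )


def motif_for_clade(
    enzyme: ReferenceEnzyme,
    tolerance_window: int = DEFAULT_TOLERANCE_WINDOW,
) -> list[MotifPattern]:
    """Screening patterns for one clade representative.

    Family consensus patterns are paired positionally with the
    representative's concrete motifs; the concrete motif is appended as an
    accepted alternate wherever it deviates from the consensus (several
    catalogued representatives carry clade-specific variants of the family
    motif).
    """
    generics = FAMILY_MOTIF_PATTERNS.get(enzyme.family)
    if generics is None or not enzyme.motifs:
        raise ValueError(f"{enzyme.accession}: no motif definitions for screening")
    if len(generics) != len(enzyme.motifs):
        raise ValueError(
            f"{enzyme.accession}: {len(enzyme.motifs)} concrete motifs vs "
            f"{len(generics)} family patterns"
        )
    patterns = []
    for generic, (concrete, start, end) in zip(generics, enzyme.motifs):
        base = parse_motif_pattern(generic, (start, end), tolerance_window)
        concrete_tokens = _tokenize(concrete, concrete)
        alternates = base.alternates
        if not base.matches_at(concrete, 0):
            alternates = alternates + (concrete_tokens,)
        patterns.append(
            MotifPattern(
                source=f"{generic}|{concrete}" if alternates is not base.alternates else generic,
                alternates=alternates,
                anchor=(start, end),
                tolerance_window=tolerance_window,
            )
        )
    return patterns


@dataclass(frozen=True)
class MotifCheck:
    pattern: str
    found: bool
    candidate_start: int | None  # 1-based
    matched_text: str = ""


@dataclass(frozen=True)
class ScreenResult:
    query_id: str
    clade_label: str
    motif_checks: tuple[MotifCheck, ...]
    qualified: bool
    reason: str = ""


def locate_motifs(
    candidate: str,
    representative: str,
    patterns: Sequence[MotifPattern],
    column_map: PairwiseAlignment | None = None,
) -> list[MotifCheck]:
    """Locate each motif in the candidate near its projected anchor.

    The representative anchor is projected through the alignment column map
    and the candidate is searched nearest-first within ±tolerance_window
    residues of the projected start.
    """
    if column_map is None:
        column_map = align_to_representative(candidate, representative)
    checks: list[MotifCheck] = []
    for pat in patterns:
        start, _end = pat.anchor
        if start < 1 or start > len(representative):
            raise ValueError(
                f"motif {pat.source!r} anchor {start} outside representative "
                f"(length {len(representative)})"
            )
        projected = column_map.project(start)  # 1-based on candidate
        found = None
        for delta in sorted(range(-pat.tolerance_window, pat.tolerance_window + 1), key=abs):
            pos0 = projected - 1 + delta
            text = pat.matches_at(candidate, pos0)
            if text is not None:
                found = (pos0 + 1, text)
                break
        if found:
            checks.append(MotifCheck(pat.source, True, found[0], found[1]))
        else:
            checks.append(MotifCheck(pat.source, False, None))
    return checks


def screen_candidates(
    hits: Sequence[Hit],
    candidates: Mapping[str, str],
    clade_representatives: Mapping[str, ReferenceEnzyme],
    tolerance_window: int = DEFAULT_TOLERANCE_WINDOW,
    min_motifs: int | None = None,
) -> list[ScreenResult]:
    """Screen search hits for conserved-motif qualification.

    ``clade_representatives`` maps a hit's clade label to the representative
    enzyme (sequence attached). By default all family motifs must be found
    (any alternate accepted); ``min_motifs`` relaxes this to a quorum.
    """
    results: list[ScreenResult] = []
    per_clade: dict[str, list[bool]] = {}
    for hit in hits:
        if hit.clade_label not in clade_representatives:
            raise KeyError(f"hit references unknown clade {hit.clade_label!r}")
        if hit.query_id not in candidates:
            raise KeyError(f"hit query {hit.query_id!r} missing from candidate set")
        rep = clade_representatives[hit.clade_label]
        if not rep.sequence:
            raise ValueError(f"representative {rep.accession} has no sequence")
        patterns = motif_for_clade(rep, tolerance_window)
        seq = candidates[hit.query_id]
        earliest = min(p.anchor[0] for p in patterns)
        if len(seq) < max(1, earliest - tolerance_window):
            result = ScreenResult(
                hit.query_id, hit.clade_label,
                tuple(MotifCheck(p.source, False, None) for p in patterns),
                qualified=False, reason="sequence too short",
            )
        else:
            checks = tuple(locate_motifs(seq, rep.sequence, patterns))
            needed = len(patterns) if min_motifs is None else min_motifs
            n_found = sum(c.found for c in checks)
            qualified = n_found >= needed
            missing = [c.pattern for c in checks if not c.found]
            reason = "" if qualified else "missing motifs: " + ", ".join(missing)
            result = ScreenResult(hit.query_id, hit.clade_label, checks, qualified, reason)
        results.append(result)
        per_clade.setdefault(hit.clade_label, []).append(result.qualified)
    for clade_label, flags in sorted(per_clade.items()):
        logger.info(
            "clade %s: %d/%d candidates qualified", clade_label, sum(flags), len(flags)
        )
    return results


def build_nj_tree(
    sequences: Mapping[str, str] | DistanceMatrix,
    distance: str = "p",
):
    """Neighbor-joining tree over sequences (or a precomputed distance matrix).

    ``distance="p"`` uses 1 − pairwise identity from global alignments.
    Negative branch lengths are clamped to zero. Returns a skbio TreeNode;
    ``str(tree)`` yields newick.
    """
    if isinstance(sequences, DistanceMatrix):
        dm = sequences
    else:
        ids = list(sequences)
        if len(ids) < 3:
            raise ValueError("neighbor joining requires at least 3 sequences")
        if distance != "p":
            raise ValueError(f"unknown distance choice {distance!r}")
        import numpy as np

        n = len(ids)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - identity_fraction(sequences[ids[i]], sequences[ids[j]])
                mat[i, j] = mat[j, i] = d
        dm = DistanceMatrix(mat, ids=ids)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 sequences")
    return nj(dm, neg_as_zero=True)


def tree_screen(
    tree,
    validated_ids: Sequence[str],
    strict: bool = False,
) -> dict[str, str]:
    """Advisory tree-based screen for clades lacking validated structures.

    Tips outside the smallest subtree containing all validated members are
    flagged (``"flagged"``); in strict mode they are marked ``"excluded"``.
    Validated members and co-clustering tips are ``"ok"``.
    """
    tips = {t.name for t in tree.tips()}
    validated = [v for v in validated_ids if v in tips]
    if not validated:
        raise ValueError("no validated members present in the tree")
    if len(validated) == 1:
        anchor = tree.find(validated[0])
        lca = anchor.parent if anchor.parent is not None else tree
    else:
        lca = tree.lca(validated)
    inside = {t.name for t in lca.tips()} | set(validated)
    verdict = "excluded" if strict else "flagged"
    return {name: ("ok" if name in inside else verdict) for name in tips}
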