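"""Amino-acid alphabet and background composition shared across the package."""

from __future__ import annotations

import numpy as np

#: The 20 standard residues, in a fixed order used by all profile matrices.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Swiss-Prot-like average composition; renormalized over the 20 standard residues.
_RAW_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

BACKGROUND = np.array([_RAW_BACKGROUND[aa] for aa in ALPHABET], dtype=float)
BACKGROUND /= BACKGROUND.sum()


def validate_sequence(seq: str, *, allow_gaps: bool = False, name: str = "sequence") -> None:
    """Raise ``ValueError`` for empty input or residues outside the standard alphabet."""
    if not seq:
        raise ValueError(f"{name} is empty")
    allowed = set(ALPHABET) | ({"-"} if allow_gaps else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters: {bad}")


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as integer indices into :data:`ALPHABET`."""
    try:
        return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded by validate_sequence
        raise ValueError(f"invalid residue {exc} in sequence") from exc
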