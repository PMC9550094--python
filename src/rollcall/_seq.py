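"""Shared sequence primitives: alphabet checks, complementation, bundled oligos."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")

#: 21 nt synthetic oligo carrying the human miRNA hsa-let-7a-5p sequence
#: (cDNA alphabet). Used as the accuracy-control insert.
LET7A = "TGAGGTAGTAGGTTGTATAGT"

#: Default 21 nt 3' ligation adapter (cDNA alphabet).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and transliterate RNA (U) into cDNA space (T)."""
    return seq.upper().replace("U", "T")


def validate_seq(seq: str, name: str = "sequence", allow_empty: bool = False) -> str:
    """Normalise to DNA and reject empty or non-ACGT input."""
    if not isinstance(seq, str):
        raise TypeError(f"{name} must be a string, got {type(seq).__name__}")
    seq = to_dna(seq)
    if not seq and not allow_empty:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq
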