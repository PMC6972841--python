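"""Tiny nucleotide-string helpers used by every stage.

All internal comparisons are DNA-space and uppercase; U is treated as T at
every entry point.
"""

from __future__ import annotations

VALID_CHARS = frozenset("ACGTUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def as_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U accepted on input)."""
    return as_dna(seq).translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq.upper()) - VALID_CHARS
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return seq
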