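"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and map U->T so everything downstream is DNA-alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet for human-facing report output."""
    return seq.upper().replace("T", "U")
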