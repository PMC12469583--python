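"""Low-level DNA string helpers shared across modules.

Sequences are handled as uppercase ASCII ``str`` at module boundaries and as
``numpy`` uint8 arrays internally where scanning speed matters.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

VALID_BASES = frozenset("ACGTN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True) -> None:
    """Reject anything outside A/C/G/T (and optionally N).

    Downstream codon and repeat arithmetic assumes an unambiguous alphabet;
    IUPAC ambiguity codes other than N are refused with a clear error rather
    than silently miscounted.
    """
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        alphabet = "A/C/G/T/N" if allow_n else "A/C/G/T"
        raise ValueError(
            f"sequence contains unsupported characters {sorted(bad)}; "
            f"only {alphabet} are accepted"
        )


def as_bytes(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array (no copy of semantics, one of data)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T; N excluded from the denominator.

    Returns ``nan`` when no unambiguous base is present.
    """
    a = as_bytes(seq)
    g = int(np.count_nonzero(a == ord("G")))
    c = int(np.count_nonzero(a == ord("C")))
    t = int(np.count_nonzero(a == ord("T")))
    aa = int(np.count_nonzero(a == ord("A")))
    denom = aa + c + g + t
    if denom == 0:
        return float("nan")
    return (g + c) / denom


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that position ``offset`` becomes 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
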