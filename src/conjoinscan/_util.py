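"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_leq(a: str, b: str, max_mismatches: int) -> bool:
    """True if equal-length strings differ in at most ``max_mismatches`` positions.

    Early-exits as soon as the budget is exceeded.
    """
    if len(a) != len(b):
        raise ValueError("hamming_leq requires equal-length strings")
    budget = max_mismatches
    for x, y in zip(a, b):
        if x != y:
            budget -= 1
            if budget < 0:
                return False
    return True
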