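"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away", "canonical_deletion", "canonical_insertion"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; percentage tables
    in this package follow the half-away-from-zero convention instead.
    """
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def canonical_deletion(template: str, start: int, length: int) -> int:
    """Leftmost equivalent start of deleting ``template[start:start+length]``.

    Deleting at any equivalent start yields the same molecule; reporting the
    leftmost makes indel tallies well-defined in repeats.
    """
    while start > 0 and template[start - 1] == template[start + length - 1]:
        start -= 1
    return start


def canonical_insertion(template: str, anchor: int, ins: str) -> tuple[int, str]:
    """Leftmost equivalent (anchor, content) of inserting ``ins`` before ``anchor``."""
    while anchor > 0 and ins[-1] == template[anchor - 1]:
        ins = template[anchor - 1] + ins[:-1]
        anchor -= 1
    return anchor, ins
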