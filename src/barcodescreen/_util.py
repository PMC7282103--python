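"""Small shared helpers: rounding, complements, sequence validation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

#: bases the statistics are defined over
CANONICAL = frozenset("ACGT")
ALPHABET = frozenset("ACGTN-")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N/- alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def round_half_up(x: float, ndigits: int = 0) -> float | int:
    """Decimal half-up rounding (7/9 -> 78 at ndigits=0, never banker's).

    Returns an int when ndigits == 0.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(v) if ndigits == 0 else float(v)
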