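"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value, ndigits: int = 2) -> Decimal:
    """Round half-up to ``ndigits`` decimals (the convention of all reported
    means and percentage ratios in this package; bankers' rounding would
    differ on exact halves)."""
    if not isinstance(value, Decimal):
        value = Decimal(str(value))
    return value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)


def pct(numerator, denominator, ndigits: int = 2) -> float:
    """Exact-decimal percentage with half-up rounding."""
    return float(round_half_up(Decimal(int(numerator)) * 100 / Decimal(int(denominator)), ndigits))
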