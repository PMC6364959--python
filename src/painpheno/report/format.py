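"""Number formatting for rendered tables: "n (%)" with half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct_half_up(count: int | float, total: int | float, decimals: int = 1) -> float:
    """Percentage rounded half-up (not banker's) to ``decimals`` places.

    Computed in exact decimal arithmetic so 14.05 rounds to 14.1, never
    14.0.
    """
    if total == 0:
        raise ZeroDivisionError("cannot take a percentage of a zero total")
    ratio = Decimal(100) * Decimal(str(count)) / Decimal(str(total))
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def fmt_count_pct(count: int, total: int, decimals: int = 1) -> str:
    """Render "count (pct)" in the conventional n (%) style."""
    pct = pct_half_up(count, total, decimals)
    return f"{count} ({pct:.{decimals}f})"
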