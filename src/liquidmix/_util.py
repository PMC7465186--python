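"""Small shared helpers: rounding conventions and seeded RNG streams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_up", "percent", "stream"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero at positive values (half-up).

    Python's built-in ``round`` is banker's rounding; the reporting
    convention here is half-up (37.5% -> 38%), so route through Decimal.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(k: int, n: int) -> int:
    """Integer percentage k/n with half-up rounding (10/19 -> 53)."""
    if n <= 0:
        raise ValueError("percentage denominator must be positive")
    return int(round_half_up(100.0 * k / n))


def stream(seed: int, *offsets: int) -> np.random.Generator:
    """Independent RNG stream derived from a base seed and stable offsets.

    Each generator in the cohort simulator draws from its own stream so that
    adding or reordering generators never perturbs the others.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *offsets])
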