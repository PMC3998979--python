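"""Small shared helpers: report rounding and seed derivation."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in printed report tables.

    Python's built-in ``round`` is banker's rounding; QC percentages are
    reported with conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded to `ndigits` decimals."""
    if denominator == 0:
        raise ValueError("percentage denominator must be nonzero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Per-stream RNG derived from one master seed and a string label.

    The label is folded in through CRC32 so every library/stage gets an
    independent, reproducible stream documented by (seed, label).
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(zlib.crc32(label.encode("utf-8")),))
    )
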