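"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported percentages).

    Python's built-in ``round`` rounds half to even, which turns 88.95 -> 88.9
    style ties the wrong way for reporting. Reported integer percentages in
    this package always use half-away-from-zero.
    """
    scale = 10.0 ** ndigits
    v = math.floor(abs(x) * scale + 0.5) / scale
    out = math.copysign(v, x)
    return out if ndigits > 0 else int(out)


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


Z95 = 1.959963984540054  # two-sided 95% normal quantile
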