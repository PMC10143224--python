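"""Shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for every split / reduction size in the package so that sizes do
    not depend on the host language's banker's rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def derive_seed(master: int, *path: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and an index path."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))
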