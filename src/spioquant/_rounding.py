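"""Deterministic rounding helpers shared across modules.

All particle-count arithmetic in this package uses round-half-up (0.5 always
rounds away from zero for the non-negative quantities handled here), not
banker's rounding, so results are reproducible across platforms and match the
hand-computable reporting convention.
"""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round a non-negative scalar half-up to the nearest integer."""
    return int(math.floor(float(x) + 0.5))


def round_half_up_array(x: np.ndarray) -> np.ndarray:
    """Element-wise round-half-up, returned as int64."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def round_half_up_decimals(x: float, decimals: int) -> float:
    """Round half-up at a fixed number of decimal places (reporting only)."""
    scale = 10.0 ** decimals
    # tiny epsilon guards against binary representation of exact halves
    return math.floor(float(x) * scale + 0.5 + 1e-12) / scale
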