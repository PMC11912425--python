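"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    return np.where(
        np.asarray(x) >= 0,
        1.0 / (1.0 + np.exp(-np.clip(x, -700, None))),
        np.exp(np.clip(x, None, 700)) / (1.0 + np.exp(np.clip(x, None, 700))),
    )


def spawn_seed(master_seed: int, offset: int) -> int:
    """Derive a child seed from a master seed by a fixed offset.

    Deterministic and collision-free for offsets < 10_000; stays below 2**31.
    """
    return int((int(master_seed) * 10_007 + offset) % (2**31 - 1))


def check_random_state(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def format_pct(numerator: float, denominator: float, digits: int = 2) -> str:
    """Percentage string such as '9.19%' used in exclusion reports."""
    if denominator == 0:
        return "n/a"
    return f"{100.0 * numerator / denominator:.{digits}f}%"
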