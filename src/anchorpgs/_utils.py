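"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def as_rng(seed=None, rng=None) -> np.random.Generator:
    """Return a Generator from either an explicit rng or a seed."""
    if rng is not None:
        if not isinstance(rng, np.random.Generator):
            raise TypeError("rng must be a numpy.random.Generator")
        return rng
    return np.random.default_rng(seed)


def check_probability(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x
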