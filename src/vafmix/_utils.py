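"""Small shared helpers: reproducible seed derivation and logging."""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("vafmix")

_SEED_CAP = 2**31


def norm_seed(seed: int | None) -> int:
    """Map an optional user seed to a non-negative int usable as entropy."""
    if seed is None:
        # Draw once from OS entropy; callers that need determinism pass a seed.
        return int(np.random.SeedSequence().generate_state(1)[0] % _SEED_CAP)
    return int(seed) % _SEED_CAP


def derive_seed(*keys) -> int:
    """Derive a child seed < 2**31 from a tuple of integer keys.

    Independent of execution order: the same keys always give the same
    child seed, which is what makes parallel restarts / bootstrap
    resamples order-independent.
    """
    entropy = [int(k) if k is not None else 0 for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % _SEED_CAP)
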