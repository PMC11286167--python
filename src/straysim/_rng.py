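"""Counter-based random streams.

Every replicate / deme / generation gets its own child stream keyed off the
base seed, so scenario sweeps are order-independent, parallelizable and
resumable: the stream consumed at (replicate r, deme d, generation g) does
not depend on how much randomness any other generation consumed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_seed_sequence", "child_seed", "child_rng"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int / SeedSequence / None into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError(
            "pass an integer seed or SeedSequence (not a Generator) so that "
            "child streams can be derived deterministically"
        )
    return np.random.SeedSequence(seed)


def child_seed(ss: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """Derive a child SeedSequence by extending the spawn key."""
    return np.random.SeedSequence(ss.entropy, spawn_key=ss.spawn_key + tuple(key))


def child_rng(ss: np.random.SeedSequence, *key: int) -> np.random.Generator:
    """A fresh Generator for the child stream identified by ``key``."""
    return np.random.default_rng(child_seed(ss, *key))
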