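"""Named, reproducible random substreams.

Every stochastic component draws from its own named substream of a single
master seed, so adding or removing one simulated channel never perturbs the
draws of any other channel, and the same (seed, name) pair always yields the
same stream across runs and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_key(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode("utf-8")).digest()[:4], "little")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``."""
    key = tuple(_name_key(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def derive_seed(seed: int, *names: str) -> int:
    """A small (< 2^31) integer seed derived from a named substream."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
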