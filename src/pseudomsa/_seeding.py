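"""Named random substreams derived from one top-level seed.

Every stochastic stage of the pipeline draws from its own substream so
that adding or reordering stages never perturbs the randomness of the
others, and the whole run is reproducible from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``names`` under ``seed``."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def subseed(seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, *[zlib.crc32(n.encode()) for n in names]]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
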