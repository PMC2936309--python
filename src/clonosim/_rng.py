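"""Deterministic named sub-streams derived from a single master seed.

Every stochastic operation takes a master seed and a stream name; the pair is
hashed into a ``numpy.random.SeedSequence`` so that stages of a pipeline can
be re-run in isolation without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) sub-stream.

    The stream name is folded in through a CRC32 so the mapping is stable
    across platforms and sessions.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
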