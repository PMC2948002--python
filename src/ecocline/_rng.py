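"""Seed handling: one global integer seed, named substreams per stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of a global seed.

    The same (seed, name) pair always yields an identical stream, and
    distinct names yield statistically independent streams, so pipeline
    stages can be regenerated in isolation.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])
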