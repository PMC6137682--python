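"""Deterministic seed management.

A single root seed deterministically spawns named substreams so that the
permutation loop, the PPC loop, the Gibbs sampler and the simulator each
draw from independent streams regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_rng"]


def _tag_to_int(tag: str | int) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, *tags: str | int) -> np.random.SeedSequence:
    """Return the SeedSequence for a named substream of ``seed``.

    The same (seed, tags) pair always maps to the same stream; distinct
    tags map to streams that are independent for all practical purposes.
    """
    return np.random.SeedSequence(entropy=int(seed),
                                  spawn_key=tuple(_tag_to_int(t) for t in tags))


def spawn_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Generator drawing from the named substream of the root seed."""
    return np.random.default_rng(substream(seed, *tags))
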