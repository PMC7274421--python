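"""Named, reproducible random sub-streams.

A single user-facing seed fans out into independent generators keyed by a
stage name ("meiosis", "partition", "gibbs", ...), so any stage can be rerun
in isolation and still produce the same draws it produced inside the full
pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the global `seed`.

    The stage name is folded in through a CRC so the mapping is stable across
    sessions and platforms (Python's `hash` is salted and would not be).
    """
    if seed is None:
        raise ValueError("seed must be set explicitly for reproducibility")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
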