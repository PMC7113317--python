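"""Seed plumbing: one global seed, deterministic named substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for a named substream of a global seed.

    The substream is keyed by a CRC32 of ``label`` so that adding a new
    consumer never perturbs existing streams, and the same (seed, label)
    pair always yields the same stream.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
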