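"""Seed plumbing: one master seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of a master seed.

    Derivation is a SeedSequence over ``(seed, crc32(label))`` so that the
    cross / reads / phenotypes / permutation stages draw from independent,
    individually reproducible streams.
    """
    if seed is None:
        raise ValueError("a seed is required for stochastic operations")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
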