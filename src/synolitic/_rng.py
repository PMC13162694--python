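"""Seed fan-out.

A single experiment seed expands into named, independent substreams so that
adding one randomized stage (e.g. replicate noise) never perturbs another
(e.g. the cohort draw).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def subseed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
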