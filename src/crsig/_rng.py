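"""Seed fan-out.

A single global seed is fanned out to per-stage generators keyed by stable
string labels, so every stage is reproducible on its own regardless of
execution order.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a stable stage label.

    The label is hashed with CRC-32 (stable across processes and Python
    versions, unlike ``hash``) and mixed with the seed through a
    ``SeedSequence``.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
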