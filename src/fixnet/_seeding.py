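"""Deterministic fan-out of one global seed into per-stage substreams.

Every stochastic stage draws from ``substream(seed, label)`` with a fixed
string label, so stages are reproducible independently of each other and of
the order in which they run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, label: str) -> int:
    """Derive a stable 31-bit child seed from a global seed and a stage label."""
    key = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    mixed = np.random.SeedSequence([int(seed), key]).generate_state(1)[0]
    return int(mixed & 0x7FFFFFFF)


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage ``label`` derived from the global ``seed``."""
    key = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
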