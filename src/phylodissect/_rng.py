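"""Labeled random streams.

Every stochastic operation in the package draws from its own
`numpy` Generator, derived from a master seed and a stable string
label. Adding a new operation therefore never perturbs the stream
of an existing one, and identical (seed, label) pairs always yield
bitwise-identical draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, label: str) -> np.random.Generator:
    """Return the Generator for ``label`` under master ``seed``.

    The label is folded into the seed sequence through its CRC-32,
    which is stable across platforms and Python versions.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
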