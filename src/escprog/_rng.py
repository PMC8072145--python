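"""Named random substreams derived from one master seed.

Every stochastic component draws from a child generator keyed by
(master seed, component name, optional per-item keys), so regenerating a
single patient's image or survival time never perturbs any other stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"substream keys must be non-negative, got {key}")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``."""
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
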