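"""Deterministic random-stream derivation.

Every source of randomness in the package descends from a single root seed.
Named substreams are derived from the root seed plus a key path (feature name,
class label, participant, repetition index, ...), so any unit of work — one
noisy evaluation of one feature of one recording — can be regenerated in
isolation without replaying the whole run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    String keys are hashed with CRC-32 (stable across processes, unlike
    ``hash``); integer keys are used directly. The same ``(seed, keys)`` pair
    always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
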