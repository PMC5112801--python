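"""Deterministic random-stream derivation.

Every stochastic operation in the package takes either an explicit
``numpy.random.Generator`` or an integer seed.  When an operation needs
several independent sub-streams (per condition, per subject, per
replication) it derives them with :func:`child_rng`, which hashes string
keys into a :class:`numpy.random.SeedSequence` spawn key.  The same
(seed, keys) pair therefore always yields the same stream, regardless of
call order elsewhere in the program.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf8"))


def child_seed(seed: int, *keys: object) -> np.random.SeedSequence:
    """A seed sequence deterministically derived from ``seed`` and ``keys``."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(_key_to_int, keys)])


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """A generator deterministically derived from ``seed`` and ``keys``."""
    return np.random.default_rng(child_seed(seed, *keys))
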