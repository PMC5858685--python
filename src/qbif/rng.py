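"""Deterministic random-stream management.

One root seed spawns named child streams (training shuffle, tie-breaks,
listener parameters, listener responses, masker offset, ...) so that each
component of a session is independently reproducible: changing how often one
component draws never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(name.encode("utf-8"))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named stream derived from ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str) -> int:
    """Derive a 31-bit integer sub-seed for the named stream."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
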