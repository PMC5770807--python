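"""Deterministic random-stream derivation.

One top-level seed fans out to independent child streams keyed by stable
string/int labels (subject index, stage name, ...), so results do not depend
on execution order or parallelism.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_sequence(seed: int, *keys) -> np.random.SeedSequence:
    spawn_key = tuple(zlib.crc32(str(k).encode("utf8")) for k in keys)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)


def child_rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_sequence(seed, *keys))


def child_seed(seed: int, *keys) -> int:
    """A plain integer seed (< 2**31) derived from the keyed stream."""
    return int(child_sequence(seed, *keys).generate_state(1)[0] % (2**31))
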