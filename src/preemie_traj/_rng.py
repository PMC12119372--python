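"""Deterministic per-stage random-number streams.

A single top-level seed is combined with a stable per-stage key so that
adding or reordering pipeline stages never perturbs the random draws of
other stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from the global ``seed``.

    The stage name is hashed with CRC-32 (stable across processes and
    Python versions, unlike ``hash``) and used as a spawn key, so each
    stage gets an independent, reproducible substream.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
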