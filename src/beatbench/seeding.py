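"""Deterministic seed fan-out.

One master seed is expanded into named substreams (data, init, train,
sampling, eval, ...) so each pipeline stage can be re-seeded independently
while the whole run stays a pure function of the master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "rng_for"]

_MOD = 2**31 - 1


def substream_seed(master_seed: int, name: str, index: int = 0) -> int:
    """Derive a reproducible child seed from ``(master_seed, name, index)``.

    Uses a CRC of the stream name so substreams are decoupled from call
    order; the result is kept below 2**31.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return int((int(master_seed) * 1_000_003 + tag * 7919 + index) % _MOD)


def rng_for(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, name, index))
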