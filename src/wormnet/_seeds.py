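"""Deterministic derivation of per-stage child seeds from one pipeline seed."""

from __future__ import annotations

import zlib

import numpy as np

_MAX_SEED = 2**31 - 1


def child_seed(seed: int, stage: str) -> int:
    """Derive a reproducible child seed for a named pipeline stage.

    The stage name is hashed (CRC32) and mixed with the parent seed through a
    ``SeedSequence`` so that stages draw from independent streams and each
    stage can be rerun in isolation from the recorded (seed, stage) pair.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % _MAX_SEED)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded for one stage of the pipeline."""
    return np.random.default_rng(child_seed(seed, stage))
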