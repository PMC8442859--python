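"""Deterministic per-stage random streams.

All randomness in the package flows from a single integer master seed. Each
named stage (or sub-experiment) derives an independent substream by combining
the master seed with a CRC32 hash of the stage name inside a
``numpy.random.SeedSequence``. Adding a new stage therefore never perturbs the
streams of existing stages, and identical ``(master_seed, stage)`` pairs always
reproduce identical draws.
"""

from __future__ import annotations

import random
import zlib

import numpy as np


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage under a master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence([int(master_seed), key])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """numpy Generator for a named stage."""
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))


def stage_pyrandom(master_seed: int, stage: str) -> random.Random:
    """Stdlib ``random.Random`` for tight scalar loops (genealogy simulation)."""
    state = stage_seed_sequence(master_seed, stage).generate_state(2)
    return random.Random(int(state[0]) << 32 | int(state[1]))
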