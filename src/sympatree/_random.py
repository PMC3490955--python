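"""Seed plumbing: every stochastic stage derives its generator from one run seed.

A stage generator is seeded with ``SeedSequence((seed, crc32(stage_name)))`` so
stages are statistically independent and a run is reproducible from the single
integer recorded in its outputs.
"""
from __future__ import annotations

from zlib import crc32

import numpy as np


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive the seed sequence for a named pipeline stage."""
    return np.random.SeedSequence((int(seed), crc32(stage.encode("utf-8"))))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A fresh generator for one named stage of a run."""
    return np.random.default_rng(stage_seed(seed, stage))
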