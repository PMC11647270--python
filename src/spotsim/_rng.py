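"""Deterministic per-stage random substreams.

A single integer seed drives the whole pipeline; each stage derives an
independent stream from (seed, stage name) so stages can be re-run in
isolation without perturbing one another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a reproducible SeedSequence for a named pipeline stage."""
    # crc32 is stable across platforms/sessions, unlike hash().
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage of a run identified by ``seed``."""
    return np.random.default_rng(stage_seed(seed, stage))
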