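"""Named random substreams.

All stochastic stages draw from one top-level seed. Each stage derives its
own generator from (seed, stage-name), so adding or reordering stages never
perturbs the stream another stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the run seed.

    The stage name is folded in through a CRC so the mapping is stable
    across sessions and platforms.
    """
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))
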