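"""Named random substreams derived from one master seed.

Every stochastic operation in the package takes a seed and derives its own
generator through :func:`substream`, so stages can be re-run in isolation and
still reproduce exactly what a full pipeline run produced.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of ``master_seed``.

    The stream key is a CRC-32 of the name, so distinct stage names yield
    statistically independent streams while remaining stable across runs
    and platforms.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))
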