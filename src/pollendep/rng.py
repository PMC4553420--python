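"""Named random-number substreams.

Every stochastic step of the pipeline (field generation, pilot scan, each
design, each spot draw, image rendering) consumes its own substream derived
from a single master seed and a stable name.  Re-running any single step with
the same master seed therefore reproduces it exactly, independent of the
order in which other steps ran.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _tag(token: str | int) -> int:
    if isinstance(token, (int, np.integer)):
        if token < 0:
            raise ValueError("substream integer tokens must be non-negative")
        return int(token)
    return zlib.crc32(token.encode("utf-8"))


def substream_seed(master_seed: int, *tokens: str | int) -> np.random.SeedSequence:
    """Seed sequence for the substream named by ``tokens``.

    Tokens may be strings (hashed with CRC-32, stable across sessions and
    platforms) or non-negative integers (e.g. a replicate index).
    """
    return np.random.SeedSequence([int(master_seed)] + [_tag(t) for t in tokens])


def substream(master_seed: int, *tokens: str | int) -> np.random.Generator:
    """A ``numpy`` Generator on the named substream."""
    return np.random.default_rng(substream_seed(master_seed, *tokens))
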