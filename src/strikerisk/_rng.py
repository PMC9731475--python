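"""Named, order-independent random substreams.

Every stochastic component draws from a substream keyed by a stable name
(e.g. ``("Cattle Egret", "counts")``) so that adding or reordering species
in a generator config never shifts the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]

_MOD = 2**31 - 1


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream depends only on (seed, names), not on how many other
    substreams have been created.
    """
    keys = [int(seed) % _MOD] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def derive_seed(seed: int, *names: str) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    return int(substream(seed, *names).integers(0, _MOD))
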