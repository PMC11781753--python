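"""Deterministic seed substreams.

Every stochastic stage (simulation, splitting, bagging, cross-validation)
derives its own named substream from one top-level integer seed, so changing
one stage's randomness never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream_seed(seed: int, *names: str) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a path of stage names."""
    ss = np.random.SeedSequence([int(seed)] + [_name_key(n) for n in names])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def substream(seed: int, *names: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named substream."""
    ss = np.random.SeedSequence([int(seed)] + [_name_key(n) for n in names])
    return np.random.default_rng(ss)
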