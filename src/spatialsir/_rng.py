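"""Deterministic seed fan-out.

Every stochastic operation in the package derives its generator from a
(master seed, tag, index) triple through :func:`child_sequence`.  The
scheme is counter-based: adding replicates or re-ordering experiments
never shifts the stream another operation sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_sequence", "child_seed", "child_rng"]


def _tag_hash(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8")) & 0x7FFFFFFF


def child_sequence(master: int, tag: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence keyed on (master seed, operation tag, replicate index)."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, _tag_hash(tag), int(index)])


def child_seed(master: int, tag: str, index: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from the triple."""
    return int(child_sequence(master, tag, index).generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def child_rng(master: int, tag: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(child_sequence(master, tag, index))
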