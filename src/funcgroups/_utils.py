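"""Shared helpers: seeded RNG fan-out, error types, small numerics."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "DegenerateInputError",
    "EmptySubsetError",
    "stage_rng",
    "stage_seed",
]


class DegenerateInputError(ValueError):
    """A series or matrix required by an operation has no usable variance."""


class EmptySubsetError(ValueError):
    """A frame subset requested for evaluation contains no frames."""


def stage_seed(root_seed: int, name: str) -> int:
    """Derive a per-stage 31-bit seed from a root seed and a stage name.

    Uses CRC32 of the stage name so the mapping is stable across sessions
    and platforms (unlike ``hash``).
    """
    return int((int(root_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1))


def stage_rng(root_seed: int, name: str) -> np.random.Generator:
    """Seeded generator for a named pipeline stage."""
    return np.random.default_rng(stage_seed(root_seed, name))
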