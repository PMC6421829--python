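"""Seed derivation and small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "derive_rng", "as_int_key"]


def as_int_key(key: int | str) -> int:
    """Map a stage name or integer to a stable 32-bit integer key."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed_sequence(seed: int | None, *keys: int | str) -> np.random.SeedSequence:
    """Deterministic child seed for a (seed, key path) combination.

    Every stochastic stage (each rarefaction iteration, each simulated
    library, each permutation block) derives its own stream from the single
    global seed, so runs are reproducible and order-independent.
    """
    spawn_key = tuple(as_int_key(k) for k in keys)
    return np.random.SeedSequence(entropy=seed, spawn_key=spawn_key)


def derive_rng(seed: int | None, *keys: int | str) -> np.random.Generator:
    """A numpy Generator seeded from ``child_seed_sequence(seed, *keys)``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))
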