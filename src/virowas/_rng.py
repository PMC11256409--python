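"""Deterministic child-seed derivation.

A single study-level seed fans out to independent per-entity generators by
stable hashing of string tokens (e.g. sample ids), so the stream an entity
receives does not depend on the order entities are visited.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *tokens: object) -> int:
    """Derive a 63-bit child seed from a root seed and hashable tokens."""
    payload = "\x1f".join(str(t) for t in tokens).encode("utf-8")
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return (int(seed) ^ int.from_bytes(digest, "big")) & 0x7FFFFFFFFFFFFFFF


def child_rng(seed: int, *tokens: object) -> np.random.Generator:
    """A generator keyed to (seed, tokens); independent of visiting order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, child_seed(seed, *tokens)])
    )
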