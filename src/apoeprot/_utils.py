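"""Seed-stream derivation and small numeric helpers shared across modules."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, *path) -> int:
    """Derive a stable 31-bit child seed from a master seed and a name path.

    The derivation hashes the master seed together with the path components
    (e.g. ``("analyte", "A0003")``), so each named stream is independent of
    every other and of the order in which streams are requested: adding an
    analyte never perturbs the draws of existing ones.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master_seed)).encode())
    for part in path:
        h.update(b"\x1f")
        h.update(str(part).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def child_rng(master_seed: int, *path) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *path))
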