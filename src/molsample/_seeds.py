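"""Deterministic seed derivation so one global seed drives every RNG."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, label: str) -> int:
    """Derive a 32-bit child seed from ``seed`` and an operation label.

    Stable across processes and Python versions (uses BLAKE2b, not ``hash``).
    """
    digest = hashlib.blake2b(
        f"{int(seed)}:{label}".encode("utf-8"), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big")
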