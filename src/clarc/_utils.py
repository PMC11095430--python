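"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *names: str) -> int:
    """Deterministic sub-seed from a master seed and stage names.

    Hashes ``"<seed>:<name>:<name>..."`` with SHA-256 and folds to < 2^31 so
    one top-level ``--seed`` governs every stage RNG reproducibly.
    """
    key = ":".join([str(int(seed)), *names]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)
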