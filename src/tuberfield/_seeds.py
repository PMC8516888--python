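"""Stable per-item seed derivation.

Seeds are derived by hashing the master seed together with string labels
(condition id, replicate, stage), so adding conditions to an experiment
never perturbs the randomness of existing items, and every derived seed
fits in a signed 32-bit integer.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *parts: object) -> int:
    """Derive a deterministic child seed < 2**31 from a master seed and labels."""
    key = ":".join([str(int(master_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
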