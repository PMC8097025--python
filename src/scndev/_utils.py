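"""Small internal helpers: deterministic seed derivation and rounding."""

from __future__ import annotations

import hashlib
import math

_SEED_MOD = 2**31


def derive_seed(root_seed: int, *tags) -> int:
    """Derive a child seed from a root seed and a sequence of string-able tags.

    The derivation is a SHA-256 hash of ``"root:tag1:tag2:..."`` reduced
    modulo 2**31, so each (stage, configuration, bin) combination gets an
    independent, reproducible stream regardless of execution order.
    """
    key = ":".join([str(int(root_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _SEED_MOD


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))
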