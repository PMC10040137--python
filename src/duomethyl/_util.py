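"""Small shared helpers: rounding, seeding, checksums."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    Python's built-in round() is banker's rounding; percentages such as
    20.85 -> 20.9 need half-up behaviour to match printed values.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed, stable across runs.

    Hash-based so stages can be re-run in isolation while remaining
    reproducible; result is kept below 2**31.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
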