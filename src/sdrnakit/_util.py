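"""Small shared helpers (rounding, hashing)."""
from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, at ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; printed summary tables
    here use the half-away convention (e.g. 92.925 -> 92.93).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
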