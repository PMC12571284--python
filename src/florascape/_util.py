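"""Small shared helpers: report rounding and config hashing."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed report tables do.

    Python's built-in round() is banker's rounding; report columns
    (integer percents, densities) use commercial half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v) if ndigits > 0 else float(int(v))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
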