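"""Small shared helpers: config hashing and deterministic seed derivation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

_SEED_MOD = 2**31 - 1


def config_hash(obj: Any) -> str:
    """Stable short hash of a (dataclass) configuration.

    Used to stamp model files so that train- and predict-time configurations
    cannot silently diverge.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = dataclasses.asdict(obj)
    else:
        payload = obj
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(*parts: int) -> int:
    """Derive a child seed from a master seed plus index parts.

    Deterministic, order-sensitive, and always within [0, 2**31 - 1) so the
    result is safe to hand to any RNG API.
    """
    blob = ",".join(str(int(p)) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:8], "big") % _SEED_MOD
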