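"""Small shared helpers: rounding conventions, seed fan-out, nested-dict access."""

from __future__ import annotations

import copy
import hashlib
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Mapping


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - int(math.floor(math.log10(abs(x))))
    return round_half_up(x, ndigits)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage child seed from one global seed.

    The scheme is a SHA-256 hash of ``"<seed>:<stage>"`` reduced modulo 2**31,
    so partial re-runs of any stage reproduce exactly without consuming
    random state from other stages.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def get_path(cfg: Mapping[str, Any], dotted: str) -> Any:
    """Fetch a value from a nested mapping by dotted path."""
    node: Any = cfg
    for key in dotted.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError) as exc:
            raise KeyError(f"config path not found: {dotted!r} (at {key!r})") from exc
    return node


def set_path(cfg: dict, dotted: str, value: Any) -> None:
    """Set a value in a nested dict by dotted path (intermediate keys must exist)."""
    keys = dotted.split(".")
    node = cfg
    for key in keys[:-1]:
        try:
            node = node[key]
        except (KeyError, TypeError) as exc:
            raise KeyError(f"config path not found: {dotted!r} (at {key!r})") from exc
    if keys[-1] not in node:
        raise KeyError(f"config path not found: {dotted!r} (at {keys[-1]!r})")
    node[keys[-1]] = value


def with_overrides(cfg: Mapping[str, Any], overrides: Mapping[str, Any]) -> dict:
    """Deep-copy ``cfg`` and apply ``{dotted_path: value}`` overrides."""
    out = copy.deepcopy(dict(cfg))
    for path, value in overrides.items():
        set_path(out, path, value)
    return out


def config_digest(cfg: Mapping[str, Any]) -> str:
    """Stable short digest of a configuration mapping, for output provenance."""
    canon = repr(_canonical(cfg)).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _canonical(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return tuple(sorted((k, _canonical(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_canonical(v) for v in obj)
    return obj
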