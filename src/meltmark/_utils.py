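"""Shared helpers: table-style percent rounding and reproducible seed fan-out."""

from __future__ import annotations

import decimal
from typing import Sequence

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in printed summary tables.

    Python's built-in ``round`` uses banker's rounding (52.85 -> 52.8); printed
    percentages in the field round half away from zero (52.85 -> 52.9).
    """
    x = float(x)
    if not np.isfinite(x):
        return x
    d = decimal.Decimal(repr(x))
    exp = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(exp, rounding=decimal.ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """``count / total`` as a percent, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def child_seed_sequence(root_seed: int, *keys: int) -> np.random.SeedSequence:
    """Derive a sub-stream deterministically from a root seed and integer keys.

    Counter-based: the same ``(root_seed, keys)`` always yields the same
    stream, independent of how many other streams were drawn, so any subset of
    a simulation is reproducible in isolation.
    """
    return np.random.SeedSequence([int(root_seed), *[int(k) for k in keys]])


def child_rng(root_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(root_seed, *keys))


def as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def name_key(name: str) -> int:
    """Stable 32-bit key for a group name, for seed fan-out by name."""
    import zlib

    return zlib.crc32(name.encode("utf-8"))
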