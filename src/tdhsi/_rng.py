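"""Deterministic derivation of per-run RNG streams from one master seed.

A splitmix64 mix of the master seed with a tuple of integer/string keys
yields independent, reproducible sub-seeds (band index, model tag, ...)
without any ordering coupling between runs.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return (x ^ (x >> 31)) & _MASK


def derive_seed(master: int, *keys) -> int:
    """Mix a master seed with arbitrary keys into a 31-bit sub-seed."""
    state = _splitmix64(int(master) & _MASK)
    for key in keys:
        if isinstance(key, str):
            for ch in key.encode():
                state = _splitmix64(state ^ ch)
        else:
            state = _splitmix64(state ^ (int(key) & _MASK))
    return state & 0x7FFFFFFF
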