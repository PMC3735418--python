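"""Reproducible MT19937 random streams.

All stochastic components of the package (fixture sequences, start
sequences, move proposals, Metropolis draws) consume a single
``numpy.random.Generator`` backed by the Mersenne Twister MT19937.
Seeding follows the generator's classic ``init_genrand`` recurrence, so the
raw 32-bit output stream is bit-identical to the reference implementation
(and e.g. ``std::mt19937``) for the same seed, on every platform.
"""

from __future__ import annotations

import numpy as np

#: Default seed of the reference MT19937 implementation.
DEFAULT_SEED = 5489


def _init_genrand_key(seed: int) -> np.ndarray:
    """Classic MT19937 state initialization (Knuth multiplier 1812433253)."""
    key = np.empty(624, dtype=np.uint32)
    key[0] = seed & 0xFFFFFFFF
    prev = int(key[0])
    for i in range(1, 624):
        prev = (1812433253 * (prev ^ (prev >> 30)) + i) & 0xFFFFFFFF
        key[i] = prev
    return key


def make_bitgen(seed: int = DEFAULT_SEED) -> np.random.MT19937:
    """MT19937 bit generator seeded exactly like the reference implementation."""
    bg = np.random.MT19937()
    bg.state = {
        "bit_generator": "MT19937",
        "state": {"key": _init_genrand_key(int(seed)), "pos": 624},
    }
    return bg


def make_rng(seed: int = DEFAULT_SEED) -> np.random.Generator:
    """A ``numpy.random.Generator`` over the classically seeded MT19937 stream."""
    return np.random.Generator(make_bitgen(seed))
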