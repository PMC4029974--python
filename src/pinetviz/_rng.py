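"""Portable deterministic pseudo-random generator.

A 32-bit linear congruential generator with the Numerical Recipes
constants:

    state_{n+1} = (1664525 * state_n + 1013904223) mod 2**32

The recipe is stated here (and in docs/methods.md) so that layouts and
synthetic datasets are reproducible bit-for-bit from a seed in any
language, independent of Python's own ``random`` module internals.
"""

from __future__ import annotations

_A = 1664525
_C = 1013904223
_M = 1 << 32


class PortableRandom:
    """Seeded LCG yielding uniforms in [0, 1)."""

    def __init__(self, seed: int):
        self.state = int(seed) % _M

    def next_uint32(self) -> int:
        self.state = (_A * self.state + _C) % _M
        return self.state

    def random(self) -> float:
        """Uniform float in [0, 1)."""
        return self.next_uint32() / _M

    def uniform(self, low: float, high: float) -> float:
        return low + (high - low) * self.random()

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n). Modulo bias is negligible for small n."""
        if n <= 0:
            raise ValueError("randint requires n >= 1")
        return self.next_uint32() % n

    def choice(self, seq):
        return seq[self.randint(len(seq))]

    def spawn(self) -> "PortableRandom":
        """Derive an independent child stream (for per-trial seeding)."""
        return PortableRandom(self.next_uint32())
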