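"""Deterministic PCG32 stream shared by the Python and compiled move kernels.

All stochastic choices of the cooperative-motion engine (start site, walk
direction) are drawn from this one generator, so a run is bitwise
reproducible from its seed and the pure-Python and JIT-compiled engines
can be cross-checked draw for draw.
"""

from __future__ import annotations

MASK64 = (1 << 64) - 1
PCG_MULT = 6364136223846793005
PCG_INC = 1442695040888963407


class Pcg32:
    """Minimal PCG32 (XSH-RR) generator with a 64-bit state.

    The identical update/output function is compiled into the numba move
    kernel; ``state`` can be handed back and forth between the two.
    """

    __slots__ = ("state",)

    def __init__(self, seed: int):
        # splitmix-style seeding: advance once past the raw seed so that
        # small consecutive seeds give uncorrelated leading draws
        self.state = (seed & MASK64) ^ 0x9E3779B97F4A7C15
        self.next_u32()

    def next_u32(self) -> int:
        old = self.state
        self.state = (old * PCG_MULT + PCG_INC) & MASK64
        xorshifted = (((old >> 18) ^ old) >> 27) & 0xFFFFFFFF
        rot = old >> 59
        return ((xorshifted >> rot) | (xorshifted << ((-rot) & 31))) & 0xFFFFFFFF

    def bounded(self, n: int) -> int:
        """Unbiased uniform integer in ``[0, n)`` via rejection sampling."""
        limit = (1 << 32) - ((1 << 32) % n)
        while True:
            r = self.next_u32()
            if r < limit:
                return r % n

    def uniform(self) -> float:
        return self.next_u32() / 4294967296.0

    def spawn(self, stream: int) -> "Pcg32":
        """Derive an independent child generator (for per-run seeding)."""
        child = Pcg32(0)
        child.state = (self.state ^ ((stream + 1) * 0xBF58476D1CE4E5B9)) & MASK64
        child.next_u32()
        child.next_u32()
        return child
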