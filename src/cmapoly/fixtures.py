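"""Reference configurations and exact ensembles for validating observables.

Deterministic fixtures (rods, the hexagon "disk") carry hand-derived
reference values; the self-avoiding-walk enumerator and the ideal-walk
sampler provide exact/known-statistics ensembles so that every observable
and every exponent fit can be tested without running the move engine —
and so the engine itself can be checked against uniform-over-SAW
statistics in the dilute single-chain limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import IN_PLANE_DIRECTIONS, LatticeSpec, axial_min_image_step
from .state import SystemState

#: Published census of self-avoiding walks on the triangular lattice by
#: number of steps (OEIS A001334); used as an exhaustiveness cross-check.
TRIANGULAR_SAW_COUNTS = {0: 1, 1: 6, 2: 30, 3: 138, 4: 618, 5: 2730}


@dataclass
class Fixture:
    """A named configuration plus reference observable values.

    ``references`` maps observable name -> (expected value, absolute
    tolerance, provenance note).
    """

    name: str
    spec: LatticeSpec
    chains: list[np.ndarray]
    references: dict[str, tuple[float, float, str]] = field(default_factory=dict)

    def to_state(self) -> SystemState:
        return SystemState.from_chains(self.spec, self.chains)


def make_rod(N: int, L: int | None = None) -> Fixture:
    """A collinear N-bead chain along the a axis.

    Exact references: A2 = 1 (fully extended), lam1 = 0,
    Rg^2 = (N^2 - 1)/12, Ree^2 = (N - 1)^2.
    """
    if N < 2:
        raise ValueError("a rod needs at least 2 beads")
    if L is None:
        L = max(N + 1, 4)
    if N > L:
        raise ValueError(f"rod of {N} beads does not fit in a box of edge {L}")
    beads = np.array([(i, 0, 0) for i in range(N)], dtype=np.int32)
    return Fixture(
        name=f"rod-{N}",
        spec=LatticeSpec(L),
        chains=[beads],
        references={
            "A2": (1.0, 0.0, "fully extended chain: lam1 = 0 exactly"),
            "lambda1": (0.0, 1e-12, "collinear beads"),
            "Rg2": ((N**2 - 1) / 12.0, 1e-9, "closed form for N collinear unit steps"),
            "Ree2": (float((N - 1) ** 2), 1e-9, "span of N collinear unit steps"),
        },
    )


def make_disk(L: int = 8) -> Fixture:
    """The 7-bead hexagon-plus-centre chain: the most disk-like lattice object.

    The bonded path runs around the six ring sites and ends on the
    centre.  Sixfold symmetry forces an isotropic gyration tensor, so
    A2 = 0 and lam1 = lam2 = 3/7 exactly; Rg^2 = 6/7 (six beads at unit
    distance from the centroid, one on it).
    """
    ring = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1), (0, 0)]
    off = 2
    beads = np.array([(a + off, b + off, 0) for a, b in ring], dtype=np.int32)
    return Fixture(
        name="hexagon-disk",
        spec=LatticeSpec(L),
        chains=[beads],
        references={
            "A2": (0.0, 1e-12, "sixfold symmetry: isotropic tensor"),
            "lambda1": (3.0 / 7.0, 1e-12, "half of Rg^2 by symmetry"),
            "lambda2": (3.0 / 7.0, 1e-12, "half of Rg^2 by symmetry"),
            "Rg2": (6.0 / 7.0, 1e-12, "6 beads at distance 1 from centroid"),
        },
    )


# --- exact SAW enumeration (brute-force oracle) -------------------------

_SAW_CAP = 10


@dataclass
class SawEnsemble:
    """Every directed self-avoiding walk of ``N`` beads (up to translation)
    on the infinite triangular lattice, with exact per-walk observables."""

    N: int
    steps: np.ndarray  # (M, N-1, 2) axial unit steps
    positions: np.ndarray  # (M, N, 2) Cartesian, bead 0 at origin
    rg2: np.ndarray
    ree2: np.ndarray

    @property
    def count(self) -> int:
        return len(self.steps)

    @property
    def mean_rg2(self) -> float:
        return float(self.rg2.mean())

    @property
    def mean_ree2(self) -> float:
        return float(self.ree2.mean())

    def key_index(self) -> dict[tuple, int]:
        """Map step-sequence key -> walk index, for frequency tests."""
        return {tuple(map(tuple, s)): i for i, s in enumerate(self.steps)}


def _axial_to_cart(ab: np.ndarray) -> np.ndarray:
    x = ab[..., 0] + 0.5 * ab[..., 1]
    y = ab[..., 1] * np.sqrt(3.0) / 2.0
    return np.stack([x, y], axis=-1)


def enumerate_saws(N: int) -> SawEnsemble:
    """Exhaustive depth-first enumeration of N-bead SAWs from the origin.

    Capped at N <= 10 beads (combinatorial explosion guard).
    """
    if N < 2:
        raise ValueError("need at least 2 beads")
    if N > _SAW_CAP:
        raise ValueError(f"enumeration capped at {_SAW_CAP} beads, got {N}")
    dirs = IN_PLANE_DIRECTIONS
    walks: list[list[tuple[int, int]]] = []
    path = [(0, 0)]
    occupied = {(0, 0)}

    def extend() -> None:
        if len(path) == N:
            walks.append(list(path))
            return
        a, b = path[-1]
        for da, db in dirs:
            nxt = (a + da, b + db)
            if nxt in occupied:
                continue
            path.append(nxt)
            occupied.add(nxt)
            extend()
            path.pop()
            occupied.remove(nxt)

    extend()
    ab = np.array(walks, dtype=np.int64)
    pos = _axial_to_cart(ab)
    c = pos - pos.mean(axis=1, keepdims=True)
    rg2 = np.einsum("mni,mni->m", c, c) / N
    d = pos[:, -1] - pos[:, 0]
    return SawEnsemble(
        N=N,
        steps=np.diff(ab, axis=1),
        positions=pos,
        rg2=rg2,
        ree2=np.einsum("mi,mi->m", d, d),
    )


def walk_key(beads: np.ndarray, spec: LatticeSpec) -> tuple:
    """Translation-invariant key of an in-box chain: its bond-step sequence
    (minimum-image), matching :meth:`SawEnsemble.key_index` keys."""
    beads = np.asarray(beads)
    out = []
    for i in range(len(beads) - 1):
        da, db = axial_min_image_step(
            int(beads[i + 1, 0] - beads[i, 0]),
            int(beads[i + 1, 1] - beads[i, 1]),
            spec.edge,
        )
        out.append((da, db))
    return tuple(out)


# --- stochastic reference ensembles ------------------------------------


@dataclass
class IdealWalkEnsemble:
    """Unrestricted random walks (no excluded volume): <Ree^2> = N - 1."""

    N: int
    positions: np.ndarray  # (M, N, 2) Cartesian

    @property
    def ree2(self) -> np.ndarray:
        d = self.positions[:, -1] - self.positions[:, 0]
        return np.einsum("mi,mi->m", d, d)

    @property
    def rg2(self) -> np.ndarray:
        c = self.positions - self.positions.mean(axis=1, keepdims=True)
        return np.einsum("mni,mni->m", c, c) / self.N


def sample_ideal_walks(N: int, M: int, seed: int) -> IdealWalkEnsemble:
    """M ideal chains of N beads: i.i.d. uniform unit steps on the lattice."""
    if M < 1:
        raise ValueError("need at least one walk")
    rng = np.random.default_rng(seed)
    dirs = np.array(IN_PLANE_DIRECTIONS, dtype=np.int64)
    choice = rng.integers(0, 6, size=(M, N - 1))
    ab = np.zeros((M, N, 2), dtype=np.int64)
    ab[:, 1:] = np.cumsum(dirs[choice], axis=1)
    return IdealWalkEnsemble(N=N, positions=_axial_to_cart(ab))


def enumerate_melt_partitions(L: int, N: int):
    """All partitions of the L x L periodic triangular lattice into
    chains of N beads — the exact melt ensemble for tiny boxes.

    This is the brute-force oracle for melt sampling: every valid
    configuration of the fully occupied system, each with equal weight.
    Yields one list of chain paths (tuples of flat site indices) per
    partition.  Guarded to 16 sites; the 4x4 box with 4-bead chains has
    1,042,944 partitions.
    """
    from .lattice import LatticeSpec, neighbors

    if L * L > 16:
        raise ValueError("partition enumeration is capped at 16 sites")
    if (L * L) % N != 0:
        raise ValueError("chain length must divide the site count")
    spec = LatticeSpec(L)
    nbr = {
        spec.site_index(a, b): sorted(
            spec.site_index(*n) for n in neighbors((a, b), spec)
        )
        for a in range(L)
        for b in range(L)
    }

    def paths_through(s, free):
        out = set()
        for start in free:
            stack = [(start, (start,))]
            while stack:
                cur, path = stack.pop()
                if len(path) == N:
                    if s in path:
                        out.add(path if path[0] < path[-1] else path[::-1])
                    continue
                for nb in nbr[cur]:
                    if nb in free and nb not in path:
                        stack.append((nb, path + (nb,)))
        return out

    def recurse(free, chosen):
        if not free:
            yield list(chosen)
            return
        s = min(free)
        for p in paths_through(s, free):
            yield from recurse(free - set(p), chosen + [p])

    yield from recurse(frozenset(range(L * L)), [])


def _rot60(ab: np.ndarray) -> np.ndarray:
    """60-degree rotation in axial coordinates: (a, b) -> (-b, a + b)."""
    return np.stack([-ab[..., 1], ab[..., 0] + ab[..., 1]], axis=-1)


def _reflect(ab: np.ndarray) -> np.ndarray:
    return ab[..., ::-1]


def sample_saw_chains(N: int, M: int, seed: int, thin: int = 25) -> np.ndarray:
    """M equilibrium self-avoiding-walk conformations via the pivot algorithm.

    The pivot algorithm (random bead, random lattice point-group element
    applied to the tail, reject on self-intersection) is the standard
    exact sampler for isolated excluded-volume chains; global observables
    decorrelate within a few accepted pivots.  Conformations are recorded
    on a fixed proposal schedule (every ``thin`` proposals) — recording
    after acceptances would oversample the conformations that accept
    more.  Returns axial coordinates ``(M, N, 2)`` with bead 0 at the
    origin.  Validated against exhaustive enumeration for small N.
    """
    if N < 3:
        raise ValueError("pivot sampling needs N >= 3")
    rng = np.random.default_rng(seed)
    walk = np.stack([np.arange(N), np.zeros(N, dtype=np.int64)], axis=-1)
    out = np.empty((M, N, 2), dtype=np.int64)
    taken = 0
    proposals = 0
    burn_in = 20 * thin  # proposals discarded from the rod start
    while taken < M:
        proposals += 1
        i = int(rng.integers(1, N - 1))
        k = int(rng.integers(1, 12))
        head = walk[: i + 1]
        tail = walk[i + 1 :] - walk[i]
        for _ in range(k % 6):
            tail = _rot60(tail)
        if k >= 6:
            tail = _reflect(tail)
        new_tail = walk[i] + tail
        occupied = set(map(tuple, head))
        ok = True
        for p in map(tuple, new_tail):
            if p in occupied:
                ok = False
                break
            occupied.add(p)
        if ok:
            walk = np.concatenate([head, new_tail])
        if proposals > burn_in and (proposals - burn_in) % thin == 0:
            out[taken] = walk - walk[0]
            taken += 1
    return out


def make_uniform_points(n: int, L: int, seed: int) -> np.ndarray:
    """n uniform random points in the rhombic cell (Cartesian), the
    ideal-gas oracle for the pair-correlation normalisation: g(r) = 1."""
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    u = rng.random((n, 2))
    a, b = u[:, 0] * L, u[:, 1] * L
    return np.column_stack([a + 0.5 * b, b * np.sqrt(3.0) / 2.0])
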