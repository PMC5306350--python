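"""Fully occupied polymer + solvent system state.

Every lattice site holds exactly one molecular element: a polymer bead,
identified by ``(chain id, bead index)``, or a solvent particle.  The
polymer concentration is ``phi = n_chains * N / n_sites``; ``phi = 1`` is
the melt (no solvent).  The state is stored in flat occupancy arrays plus
a per-chain bead-position table so that cooperative moves and observable
sweeps are both O(1) per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator

import numpy as np

from .lattice import LatticeSpec, axial_min_image_step

SOLVENT = -1


@dataclass
class Chain:
    """An ``N``-bead chain; ``beads`` is an ``(N, 3)`` array of ``(a, b, layer)``."""

    id: int
    beads: np.ndarray

    def __len__(self) -> int:
        return len(self.beads)


@dataclass
class RunConfig:
    """Parameters of one simulation run."""

    N: int
    n_chains: int
    L: int
    layers: int = 1
    seed: int = 0
    n_timesteps: int = 1000
    measure_every: int = 10
    max_loop_len: int = 100
    equil_window: int = 200
    equil_max_time: int = 200_000
    fold_width: int | None = None  # None: fold only at the box edge
    mode: str = "uniform"  # move generator: "uniform" or "guided"
    init: str = "extended"  # initial condition: "extended" or "disordered"

    def __post_init__(self) -> None:
        if min(self.N, self.n_chains, self.L) < 1:
            raise ValueError("N, n_chains and L must be positive")
        spec = self.lattice_spec
        if self.n_chains * self.N > spec.n_sites:
            raise ValueError(
                f"{self.n_chains} chains of {self.N} beads exceed "
                f"{spec.n_sites} lattice sites"
            )
        if self.mode not in ("uniform", "guided"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.init not in ("extended", "disordered"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def lattice_spec(self) -> LatticeSpec:
        return LatticeSpec(self.L, self.layers)

    @property
    def phi(self) -> Fraction:
        return concentration(self.n_chains, self.N, self.lattice_spec)


def concentration(n_chains: int, N: int, spec: LatticeSpec) -> Fraction:
    """Polymer concentration: beads per lattice site, as an exact rational.

    E.g. one 1024-bead chain on a 256x256 box gives 1024/256**2 = 0.015625.
    """
    if n_chains * N > spec.n_sites:
        raise ValueError(
            f"{n_chains * N} beads do not fit on {spec.n_sites} sites"
        )
    return Fraction(n_chains * N, spec.n_sites)


#: Maximum area fraction of close-packed discs; lattice concentrations phi
#: correspond to phi * pi/(2*sqrt(3)) in the off-lattice (disc-packing)
#: concentration convention used by some continuum studies.
CLOSE_PACKING_FRACTION = float(np.pi / (2.0 * np.sqrt(3.0)))


class SystemState:
    """Mutable simulation world: occupancy arrays + bead position table.

    Attributes
    ----------
    occ_chain, occ_bead:
        Per-site chain id (``SOLVENT`` = -1 for solvent) and bead index.
    bead_site:
        ``(n_chains, N)`` flat site index of every bead.
    timestep:
        Elapsed simulation time units (one unit = one attempted move per
        lattice element on average).
    """

    def __init__(self, spec: LatticeSpec, N: int, bead_site: np.ndarray):
        self.spec = spec
        self.N = int(N)
        self.bead_site = np.ascontiguousarray(bead_site, dtype=np.int32)
        self.n_chains = self.bead_site.shape[0]
        self.occ_chain = np.full(spec.n_sites, SOLVENT, dtype=np.int32)
        self.occ_bead = np.full(spec.n_sites, SOLVENT, dtype=np.int32)
        for c in range(self.n_chains):
            for i in range(self.N):
                s = self.bead_site[c, i]
                if self.occ_chain[s] != SOLVENT:
                    raise ValueError(f"site {s} doubly occupied")
                self.occ_chain[s] = c
                self.occ_bead[s] = i
        self.timestep = 0
        self.displacement_count = 0  # cumulative attempted element displacements

    # --- constructors --------------------------------------------------

    @classmethod
    def from_chains(cls, spec: LatticeSpec, chains: list[np.ndarray]) -> "SystemState":
        """Build a state from explicit bead coordinate arrays ``(N, 3)``."""
        N = len(chains[0])
        sites = np.empty((len(chains), N), dtype=np.int32)
        for c, beads in enumerate(chains):
            if len(beads) != N:
                raise ValueError("all chains must have equal length")
            for i, (a, b, layer) in enumerate(np.asarray(beads, dtype=int)):
                sites[c, i] = spec.site_index(int(a), int(b), int(layer))
        return cls(spec, N, sites)

    @property
    def phi(self) -> Fraction:
        return concentration(self.n_chains, self.N, self.spec)

    # --- views ----------------------------------------------------------

    def bead_coords(self) -> np.ndarray:
        """Axial ``(n_chains, N, 3)`` integer coordinates of all beads."""
        L = self.spec.edge
        s = self.bead_site.astype(np.int64)
        layer, rem = np.divmod(s, L * L)
        b, a = np.divmod(rem, L)
        return np.stack([a, b, layer], axis=-1).astype(np.int32)

    def chains(self) -> Iterator[Chain]:
        coords = self.bead_coords()
        for c in range(self.n_chains):
            yield Chain(c, coords[c])

    def solvent_sites(self) -> np.ndarray:
        return np.flatnonzero(self.occ_chain == SOLVENT)

    def copy(self) -> "SystemState":
        dup = SystemState.__new__(SystemState)
        dup.spec = self.spec
        dup.N = self.N
        dup.n_chains = self.n_chains
        dup.bead_site = self.bead_site.copy()
        dup.occ_chain = self.occ_chain.copy()
        dup.occ_bead = self.occ_bead.copy()
        dup.timestep = self.timestep
        dup.displacement_count = self.displacement_count
        return dup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SystemState):
            return NotImplemented
        return (
            self.spec == other.spec
            and self.N == other.N
            and np.array_equal(self.bead_site, other.bead_site)
        )


def _boustrophedon_path(spec: LatticeSpec) -> np.ndarray:
    """Hamiltonian path over all sites: rows swept alternately +a / -a,
    rows stacked in +b; in a two-layer box the second layer retraces the
    first layer's path in reverse so the layer crossing is a unit bond."""
    L = spec.edge
    path0 = []
    for b in range(L):
        cols = range(L) if b % 2 == 0 else range(L - 1, -1, -1)
        path0.extend((a, b, 0) for a in cols)
    path = list(path0)
    if spec.layers == 2:
        path.extend((a, b, 1) for a, b, _ in reversed(path0))
    return np.array(path, dtype=np.int32)


def build_initial(config: RunConfig) -> SystemState:
    """Initial condition: chains fully extended along the ``a`` axis,
    folding back (hairpin via a ``+b`` step) at the box edge, stacked
    row-by-row from the origin; all remaining sites are solvent.

    When ``N`` is a multiple of ``L`` the row-aligned fill would make
    every chain a straight line wrapping the periodic box — a state with
    no conformational slack at full occupancy, which cooperative loops
    cannot unjam.  In that case the fill starts mid-row, giving every
    chain a hairpin.  (For even ``L`` the serpentine path closes into a
    Hamiltonian cycle, so a fill wrapping past the last site keeps unit
    bonds.)

    ``config.fold_width`` selects a hairpin-rich variant for dense
    systems: chains serpentine inside vertical strips of that width, so
    every chain of ``N > fold_width`` carries fold defects.  A
    defect-free extended packing at phi = 1 is frozen (no short
    cooperative loop can be accepted), so melts are started from the
    folded fill instead.
    """
    spec = config.lattice_spec
    if config.fold_width is not None:
        return _build_folded(config)
    path = _boustrophedon_path(spec)
    n_beads = config.n_chains * config.N
    offset = 0
    if config.N % config.L == 0 and config.N >= config.L:
        cyclic = config.L % 2 == 0 or spec.layers == 2
        if cyclic or offset + n_beads <= spec.n_sites:
            offset = config.L // 2
    sites = np.array(
        [
            spec.site_index(*path[(offset + k) % spec.n_sites])
            for k in range(n_beads)
        ],
        dtype=np.int32,
    ).reshape(config.n_chains, config.N)
    return SystemState(spec, config.N, sites)


def build_disordered(config: RunConfig, n_backbite: int | None = None) -> SystemState:
    """Disordered initial condition: chains cut from a randomized
    Hamiltonian path.

    The serpentine path over all sites is randomized by backbite moves
    (re-attach one path end to a lattice neighbour inside the path and
    reverse the severed tail), then the first ``n_chains * N`` path sites
    are cut into consecutive chains; the rest is solvent.  Unlike the
    extended fill, this start is defect-rich, which matters at full
    occupancy: cooperative loops cannot unfreeze a perfectly aligned
    phi = 1 packing, but they relax this one quickly.  Deterministic in
    ``config.seed``.

    The default backbite depth (16 moves per site) is past the point
    where the fill's chain statistics stop depending on depth; shallow
    randomization leaves orientationally ordered domains that dense
    dynamics cannot melt on accessible timescales.
    """
    spec = config.lattice_spec
    path0 = _boustrophedon_path(spec)
    order = np.array([spec.site_index(*p) for p in path0], dtype=np.int64)
    n = len(order)
    if n_backbite is None:
        n_backbite = 16 * n
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    rng = np.random.default_rng(config.seed)
    from ._kernel import _DIR_A, _DIR_B  # direction tables shared with the engine

    L = spec.edge
    LL = L * L
    n_dirs = spec.coordination
    for _ in range(n_backbite):
        if rng.integers(2) == 0:  # randomize which end bites
            order = order[::-1].copy()
            pos[order] = np.arange(n)
        e = int(order[-1])
        d = int(rng.integers(n_dirs))
        layer, rem = divmod(e, LL)
        b, a = divmod(rem, L)
        if d == 6:
            y = (1 - layer) * LL + rem
        else:
            y = layer * LL + ((b + int(_DIR_B[d])) % L) * L + ((a + int(_DIR_A[d])) % L)
        j = pos[y]
        if j == n - 2:
            continue
        order[j + 1 :] = order[j + 1 :][::-1]
        pos[order[j + 1 :]] = np.arange(j + 1, n)
    sites = order[: config.n_chains * config.N].reshape(config.n_chains, config.N)
    return SystemState(spec, config.N, sites.astype(np.int32))


def _build_folded(config: RunConfig) -> SystemState:
    """Strip fill: chains boustrophedon within vertical strips of width
    ``fold_width`` (runs of that length joined by hairpins), chains
    stacked consecutively along each strip's serpentine."""
    spec = config.lattice_spec
    w, L = config.fold_width, config.L
    if not 2 <= w <= L:
        raise ValueError(f"fold_width must be in [2, {L}], got {w}")
    strip_sites = w * L * spec.layers
    if config.N % w != 0 and strip_sites % config.N != 0:
        raise ValueError("fold_width must align chains with strips")
    paths = []  # serpentine per strip, strips used left to right
    for a0 in range(0, L, w):
        strip = []
        for layer in range(spec.layers):
            for b in range(L):
                cols = range(w) if b % 2 == 0 else range(w - 1, -1, -1)
                strip.extend((a0 + a, b, layer) for a in cols)
        paths.append(strip)
    n_beads = config.n_chains * config.N
    sites = np.empty(n_beads, dtype=np.int32)
    k = 0
    for strip in paths:
        take = min(len(strip), n_beads - k)
        take -= take % config.N  # chains may not straddle strips
        for j in range(take):
            sites[k + j] = spec.site_index(*strip[j])
        k += take
        if k == n_beads:
            break
    if k < n_beads:
        raise ValueError("folded fill could not place all chains; adjust fold_width")
    return SystemState(spec, config.N, sites.reshape(config.n_chains, config.N))


def validate(state: SystemState) -> list[str]:
    """Diagnostic sweep; empty list iff the state is consistent.

    Checks the occupancy bijection (every site exactly one element, the
    occupancy arrays agreeing with the bead table) and bond adjacency
    (every consecutive bead pair a nearest-neighbour pair).
    """
    issues: list[str] = []
    spec = state.spec
    seen = np.zeros(spec.n_sites, dtype=bool)
    for c in range(state.n_chains):
        for i in range(state.N):
            s = int(state.bead_site[c, i])
            if seen[s]:
                issues.append(f"site {s} occupied by more than one bead")
            seen[s] = True
            if state.occ_chain[s] != c or state.occ_bead[s] != i:
                issues.append(f"occupancy arrays disagree with bead table at site {s}")
    n_beads = state.n_chains * state.N
    if seen.sum() != n_beads:
        issues.append("bead table maps onto fewer sites than beads")
    solvent = np.flatnonzero(state.occ_chain == SOLVENT)
    if len(solvent) != spec.n_sites - n_beads:
        issues.append("solvent site count inconsistent with occupancy")
    coords = state.bead_coords()
    L = spec.edge
    for c in range(state.n_chains):
        for i in range(state.N - 1):
            a1, b1, l1 = coords[c, i]
            a2, b2, l2 = coords[c, i + 1]
            da, db = axial_min_image_step(int(a2 - a1), int(b2 - b1), L)
            in_plane = (da, db) in {(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)}
            vertical = (da, db) == (0, 0) and l1 != l2
            if not ((in_plane and l1 == l2) or vertical):
                issues.append(f"broken bond: chain {c} beads {i}-{i + 1}")
    return issues


# --- snapshot text format ----------------------------------------------


def write_snapshot(state: SystemState, path) -> None:
    """Write the documented plain-text snapshot format (bit-exact round trip)."""
    coords = state.bead_coords()
    with open(path, "w") as fh:
        fh.write(f"L {state.spec.edge}\n")
        fh.write(f"layers {state.spec.layers}\n")
        fh.write(f"N {state.N}\n")
        fh.write(f"n_chains {state.n_chains}\n")
        fh.write(f"phi {state.phi.numerator}/{state.phi.denominator}\n")
        fh.write(f"timestep {state.timestep}\n")
        for c in range(state.n_chains):
            for i in range(state.N):
                a, b, layer = coords[c, i]
                fh.write(f"{c} {i} {a} {b} {layer}\n")


def read_snapshot(path) -> SystemState:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key] = value
        spec = LatticeSpec(int(header["L"]), int(header["layers"]))
        N, n_chains = int(header["N"]), int(header["n_chains"])
        sites = np.empty((n_chains, N), dtype=np.int32)
        filled = np.zeros((n_chains, N), dtype=bool)
        for line in fh:
            if not line.strip():
                continue
            c, i, a, b, layer = map(int, line.split())
            sites[c, i] = spec.site_index(a, b, layer)
            filled[c, i] = True
    if not filled.all():
        raise ValueError("snapshot is missing bead records")
    state = SystemState(spec, N, sites)
    state.timestep = int(header["timestep"])
    if Fraction(header["phi"]) != state.phi:
        raise ValueError("snapshot header phi disagrees with bead count")
    return state
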