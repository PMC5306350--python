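"""Cooperative motion algorithm (CMA) engine.

The system is fully occupied, so single-element moves are impossible:
elements rearrange collectively along closed loops.  A move proposal is a
displacement random walk — a uniform random start site, then uniform
random nearest-neighbour directions; the element at the current site is
tentatively displaced onto the chosen neighbour, and the displaced
element continues the walk.  The walk closes when it steps back onto the
start site; the resulting cyclic permutation has zero net displacement
(the continuity condition) and creates no vacancies.  The move is
accepted iff every polymer bond in every affected chain remains a
nearest-neighbour pair; the system is athermal, so there is no other
acceptance factor.  Because each direction is drawn uniformly, a loop and
its reverse are proposed with equal probability, so accepted dynamics
satisfy detailed balance with respect to the uniform distribution over
allowed configurations.

Simulation time: one time unit elapses when the cumulative number of
attempted element displacements (walk steps, whether or not the walk
closes and is accepted) reaches the total site count — on average one
attempt per lattice element.

Two interchangeable move paths exist: a pure-Python reference
(:func:`propose_loop` / :func:`apply_if_valid` / :func:`run_python`) and
a numba-compiled kernel (:func:`run`); both consume the same PCG32
stream and produce bitwise-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .rng import Pcg32
from .state import SOLVENT, SystemState

DEFAULT_MAX_LOOP_LEN = 100


@dataclass
class CooperativeLoop:
    """A closed displacement cycle: the element at ``sites[i]`` moves to
    ``sites[i+1 mod k]``.

    The displacement vectors sum to zero (the continuity condition) up
    to box winding: a loop that wraps around the periodic cell sums to
    ``L`` times its winding vector, which still creates no vacancies.
    """

    sites: np.ndarray  # flat site indices, length k >= 3, all distinct

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if len(self.sites) < 3:
            raise ValueError("a cooperative loop needs at least 3 sites")
        if len(np.unique(self.sites)) != len(self.sites):
            raise ValueError("loop sites must be distinct")

    def __len__(self) -> int:
        return len(self.sites)

    def reversed(self) -> "CooperativeLoop":
        """The same cycle traversed the other way; applying both is the identity."""
        return CooperativeLoop(np.concatenate([self.sites[:1], self.sites[1:][::-1]]))

    def steps(self, spec) -> list[tuple[int, int, int]]:
        """Displacement vectors (da, db, dlayer); their sum is zero."""
        from .lattice import axial_min_image_step

        out = []
        for i in range(len(self.sites)):
            a1, b1, l1 = spec.site_coord(int(self.sites[i]))
            a2, b2, l2 = spec.site_coord(int(self.sites[(i + 1) % len(self.sites)]))
            da, db = axial_min_image_step(a2 - a1, b2 - b1, spec.edge)
            out.append((da, db, l2 - l1))
        return out


@dataclass
class MoveStats:
    attempts: int = 0
    accepted: int = 0
    displacements: int = 0
    loop_hist: np.ndarray = field(
        default_factory=lambda: np.zeros(DEFAULT_MAX_LOOP_LEN + 1, dtype=np.int64)
    )

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else 0.0

    def merge(self, other: "MoveStats") -> None:
        self.attempts += other.attempts
        self.accepted += other.accepted
        self.displacements += other.displacements
        n = max(len(self.loop_hist), len(other.loop_hist))
        h = np.zeros(n, dtype=np.int64)
        h[: len(self.loop_hist)] += self.loop_hist
        h[: len(other.loop_hist)] += other.loop_hist
        self.loop_hist = h


# --- pure-Python reference path ----------------------------------------


def _neighbor_flat(s: int, d: int, L: int, LL: int) -> int:
    layer, rem = divmod(s, LL)
    b, a = divmod(rem, L)
    if d == 6:
        return (1 - layer) * LL + rem
    da, db = _kernel._DIR_A[d], _kernel._DIR_B[d]
    return layer * LL + ((b + db) % L) * L + ((a + da) % L)


def propose_loop(
    state: SystemState, rng: Pcg32, max_len: int = DEFAULT_MAX_LOOP_LEN
) -> CooperativeLoop | None:
    """One walk attempt; returns a loop or ``None`` (rejection).

    A walk is rejected when it revisits a non-start site (the cycle would
    not be simple), closes after fewer than 3 sites (a pair swap is not a
    cooperative rearrangement), or exceeds ``max_len`` sites.  Rejected
    walk steps still count towards simulation time via
    ``state.displacement_count``.
    """
    spec = state.spec
    L, LL = spec.edge, spec.edge * spec.edge
    n_dirs = spec.coordination
    s0 = rng.bounded(spec.n_sites)
    path = [s0]
    visited = {s0}
    cur = s0
    while True:
        d = rng.bounded(n_dirs)
        nxt = _neighbor_flat(cur, d, L, LL)
        state.displacement_count += 1
        if nxt == s0:
            if len(path) >= 3:
                return CooperativeLoop(np.array(path))
            return None
        if nxt in visited or len(path) >= max_len:
            return None
        path.append(nxt)
        visited.add(nxt)
        cur = nxt


def apply_if_valid(state: SystemState, loop: CooperativeLoop) -> bool:
    """Cyclically permute the elements along ``loop``; accept iff every
    bond of every affected chain is still a nearest-neighbour pair.  On
    rejection the state is restored exactly."""
    spec = state.spec
    L, LL = spec.edge, spec.edge * spec.edge
    sites = loop.sites
    k = len(sites)
    save_chain = state.occ_chain[sites].copy()
    save_bead = state.occ_bead[sites].copy()
    for i in range(k):
        j = (i + 1) % k
        c, bi = save_chain[i], save_bead[i]
        state.occ_chain[sites[j]] = c
        state.occ_bead[sites[j]] = bi
        if c != SOLVENT:
            state.bead_site[c, bi] = sites[j]
    ok = True
    for i in range(k):
        c, bi = int(save_chain[i]), int(save_bead[i])
        if c == SOLVENT:
            continue
        if bi > 0 and not _kernel._adjacent.py_func(
            int(state.bead_site[c, bi - 1]), int(state.bead_site[c, bi]), L, LL
        ):
            ok = False
            break
        if bi < state.N - 1 and not _kernel._adjacent.py_func(
            int(state.bead_site[c, bi]), int(state.bead_site[c, bi + 1]), L, LL
        ):
            ok = False
            break
    if not ok:
        for i in range(k):
            c, bi = save_chain[i], save_bead[i]
            state.occ_chain[sites[i]] = c
            state.occ_bead[sites[i]] = bi
            if c != SOLVENT:
                state.bead_site[c, bi] = sites[i]
    return ok


def run_python(
    state: SystemState,
    n_timesteps: int,
    rng: Pcg32,
    max_loop_len: int = DEFAULT_MAX_LOOP_LEN,
    mode: str = "uniform",
) -> MoveStats:
    """Reference driver: identical trajectory to :func:`run` (same seeds)."""
    if mode not in ("uniform", "guided"):
        raise ValueError(f"unknown mode {mode!r}")
    stats = MoveStats(loop_hist=np.zeros(max_loop_len + 1, dtype=np.int64))
    target = state.displacement_count + n_timesteps * state.spec.n_sites
    start = state.displacement_count
    while state.displacement_count < target:
        stats.attempts += 1
        if mode == "uniform":
            loop = propose_loop(state, rng, max_loop_len)
            k = len(loop) if loop is not None and apply_if_valid(state, loop) else 0
        else:
            k = propose_apply_guided(state, rng, max_loop_len)
        if k:
            stats.accepted += 1
            stats.loop_hist[min(k, max_loop_len)] += 1
    stats.displacements = state.displacement_count - start
    state.timestep += n_timesteps
    return stats


# --- guided proposal (production move generator) ------------------------
#
# In dense systems the uniform-direction walk almost never closes into a
# bond-compatible loop (measured acceptance ~1e-3 in a phi=1 melt), so
# relaxation per CPU time is impractically slow.  The guided generator
# walks the *vacancy* instead: the start element is set aside, and at
# each step one candidate is drawn uniformly among the moves that are
# locally legal right now — a neighbouring element whose bonds all reach
# the vacancy, or (once at least three sites are involved and the
# vacancy neighbours the start) closing the loop by dropping the start
# element in.  Because every element validates all its bonds when it
# moves and each bond's later-moving endpoint re-validates it, a closed
# walk always yields a valid state — but the draw probabilities are no
# longer symmetric between a loop and its reverse.  Symmetry is restored
# exactly by a Metropolis factor min(1, S_rev/S_fwd), where S is the
# total generation probability of the loop (summed over its cyclic
# rotations, each a product of 1/|choices|); the stationary distribution
# is therefore uniform over allowed configurations, as the athermal
# model requires.


def _elem_fits(state: SystemState, overlay: dict, c: int, b: int, site: int) -> bool:
    """Can element (c, b) sit at ``site`` with every bonded partner (at
    its current, possibly overlaid, position) a nearest neighbour?"""
    if c == SOLVENT:
        return True
    L = state.spec.edge
    LL = L * L
    for nb in (b - 1, b + 1):
        if 0 <= nb < state.N:
            p = overlay.get((c, nb))
            if p is None:
                p = int(state.bead_site[c, nb])
            if not _kernel._adjacent.py_func(site, p, L, LL):
                return False
    return True


def _guided_candidates(
    state: SystemState, v0: int, w: int, visited: set, overlay: dict, e0, n_vs: int
):
    """Candidate continuations at vacancy ``w``: (site, is_closure) pairs,
    enumerated in fixed direction order."""
    spec = state.spec
    L, LL = spec.edge, spec.edge * spec.edge
    cands = []
    for d in range(spec.coordination):
        u = _neighbor_flat(w, d, L, LL)
        if u == v0:
            if n_vs >= 3 and _elem_fits(state, overlay, e0[0], e0[1], w):
                cands.append((u, True))
        elif u not in visited:
            c, b = int(state.occ_chain[u]), int(state.occ_bead[u])
            if c == SOLVENT or _elem_fits(state, overlay, c, b, w):
                cands.append((u, False))
    return cands


def _rotation_probability_sum(
    sites: list[int], elems: list[tuple[int, int]], state: SystemState
) -> float:
    """Total probability (bar the 1/n_sites start factor) of generating
    the cycle "element t at sites[t] moves to sites[t-1]" via the guided
    walk, summed over its k cyclic rotations, evaluated against the
    current global state for off-cycle elements."""
    spec = state.spec
    L, LL = spec.edge, spec.edge * spec.edge
    k = len(sites)
    site_to_idx = {s: i for i, s in enumerate(sites)}
    elem_to_idx = {e: i for i, e in enumerate(elems) if e[0] != SOLVENT}
    total = 0.0
    for r in range(k):
        prob = 1.0
        moved = [False] * k
        feasible = True
        for t in range(1, k + 1):
            w = sites[(r + t - 1) % k]  # current vacancy
            # positions of cycle elements at this point of the replay
            def pos_of(c: int, b: int) -> int:
                i = elem_to_idx.get((c, b))
                if i is None:
                    return int(state.bead_site[c, b])
                if moved[i]:
                    return sites[(i - 1) % k]
                return sites[i]

            def fits(c: int, b: int, at: int) -> bool:
                if c == SOLVENT:
                    return True
                for nb in (b - 1, b + 1):
                    if 0 <= nb < state.N and not _kernel._adjacent.py_func(
                        at, pos_of(c, nb), L, LL
                    ):
                        return False
                return True

            n_cand = 0
            prescribed_ok = False
            if t < k:
                prescribed_site = sites[(r + t) % k]
            for d in range(spec.coordination):
                u = _neighbor_flat(w, d, L, LL)
                i = site_to_idx.get(u)
                if u == sites[r]:
                    # closure option: buffered element r drops into w
                    if t >= 3 and fits(elems[r][0], elems[r][1], w):
                        n_cand += 1
                        if t == k:
                            prescribed_ok = True
                elif i is not None and moved[i]:
                    continue  # a previously processed vacancy site
                elif i is not None and (i - r) % k < t:
                    continue  # visited vacancy path site
                else:
                    if i is not None:
                        c, b = elems[i]
                    else:
                        c, b = int(state.occ_chain[u]), int(state.occ_bead[u])
                    if c == SOLVENT or fits(c, b, w):
                        n_cand += 1
                        if t < k and u == prescribed_site:
                            prescribed_ok = True
            if not prescribed_ok or n_cand == 0:
                feasible = False
                break
            prob /= n_cand
            if t < k:
                moved[(r + t) % k] = True
        if feasible:
            total += prob
    return total


def propose_apply_guided(
    state: SystemState, rng: Pcg32, max_len: int = DEFAULT_MAX_LOOP_LEN
) -> int:
    """One guided walk attempt; applies the move and returns the loop
    length on acceptance, 0 otherwise.  Counts simulation time via
    ``state.displacement_count`` exactly like the uniform walk."""
    spec = state.spec
    v0 = rng.bounded(spec.n_sites)
    e0 = (int(state.occ_chain[v0]), int(state.occ_bead[v0]))
    sites = [v0]
    visited = {v0}
    overlay: dict = {}
    elems = [e0]
    w = v0
    while True:
        state.displacement_count += 1
        cands = _guided_candidates(state, v0, w, visited, overlay, e0, len(sites))
        if not cands:
            return 0
        u, is_closure = cands[rng.bounded(len(cands))]
        if is_closure:
            break
        c, b = int(state.occ_chain[u]), int(state.occ_bead[u])
        overlay[(c, b)] = w
        elems.append((c, b))
        sites.append(u)
        visited.add(u)
        w = u
        if len(sites) >= max_len:
            return 0
    k = len(sites)
    if all(c == SOLVENT for c, _ in elems):
        # permuting indistinguishable solvent is a physical no-op: skip the
        # Metropolis bookkeeping and leave the state untouched
        return 0
    s_fwd = _rotation_probability_sum(sites, elems, state)
    # apply: element t moves sites[t] -> sites[t-1]; start element -> sites[k-1]
    for t in range(1, k):
        c, b = elems[t]
        dest = sites[t - 1]
        state.occ_chain[dest] = c
        state.occ_bead[dest] = b
        if c != SOLVENT:
            state.bead_site[c, b] = dest
    dest = sites[k - 1]
    state.occ_chain[dest] = e0[0]
    state.occ_bead[dest] = e0[1]
    if e0[0] != SOLVENT:
        state.bead_site[e0[0], e0[1]] = dest
    rev_sites = sites[::-1]
    rev_elems = [elems[0]] + elems[1:][::-1]
    s_rev = _rotation_probability_sum(rev_sites, rev_elems, state)
    if rng.uniform() * s_fwd < s_rev:
        return k
    # Metropolis reject: undo
    for t in range(k):
        c, b = elems[t]
        state.occ_chain[sites[t]] = c
        state.occ_bead[sites[t]] = b
        if c != SOLVENT:
            state.bead_site[c, b] = sites[t]
    return 0


def exchange_tails(state: SystemState, rng: Pcg32, n_attempts: int) -> int:
    """Tail-exchange (double-bridging) moves: global-conformation mixing.

    Cooperative loops rearrange melts only locally: individual chain
    sizes decorrelate over ~1e5+ time units.  A tail exchange cuts two
    chains at the same contour index and swaps their tails: pick a
    random site holding bead ``(c1, i)``, a random neighbour holding
    ``(c2, i+1)`` of another chain, and — provided the complementary
    pair ``(c2, i)``/``(c1, i+1)`` are also lattice neighbours — give
    ``c1`` the tail of ``c2`` and vice versa.  Occupied sites, chain
    count and chain length are all unchanged; the move is its own
    inverse and is proposed with the same probability in both
    directions, so it satisfies detailed balance with respect to the
    same uniform athermal measure as the cooperative loops.  Verified
    against exhaustive enumeration of the 4x4 melt partition ensemble.

    Returns the number of accepted exchanges.  Effective only where
    chains touch (melts and concentrated solutions).
    """
    spec = state.spec
    L, LL = spec.edge, spec.edge * spec.edge
    n_dirs = spec.coordination
    N = state.N
    accepted = 0
    for _ in range(n_attempts):
        s1 = rng.bounded(spec.n_sites)
        c1, i1 = int(state.occ_chain[s1]), int(state.occ_bead[s1])
        if c1 == SOLVENT or i1 >= N - 1:
            continue
        s2 = _neighbor_flat(s1, rng.bounded(n_dirs), L, LL)
        c2, i2 = int(state.occ_chain[s2]), int(state.occ_bead[s2])
        if c2 == SOLVENT or c2 == c1 or i2 != i1 + 1:
            continue
        if not _kernel._adjacent.py_func(
            int(state.bead_site[c2, i1]), int(state.bead_site[c1, i1 + 1]), L, LL
        ):
            continue
        tail1 = state.bead_site[c1, i1 + 1 :].copy()
        tail2 = state.bead_site[c2, i1 + 1 :].copy()
        state.bead_site[c1, i1 + 1 :] = tail2
        state.bead_site[c2, i1 + 1 :] = tail1
        state.occ_chain[tail2] = c1
        state.occ_chain[tail1] = c2
        accepted += 1
    return accepted


# --- compiled path ------------------------------------------------------


class KernelWorkspace:
    """Reusable scratch arrays for the compiled kernel, tied to one state."""

    def __init__(self, state: SystemState, max_loop_len: int):
        self.mark = np.zeros(state.spec.n_sites, dtype=np.int64)
        self.stamp = np.zeros(1, dtype=np.int64)
        self.max_loop_len = max_loop_len


def run(
    state: SystemState,
    n_timesteps: int,
    rng: Pcg32,
    max_loop_len: int = DEFAULT_MAX_LOOP_LEN,
    hook=None,
    hook_every: int | None = None,
    workspace: KernelWorkspace | None = None,
    mode: str = "uniform",
) -> MoveStats:
    """Advance ``state`` by ``n_timesteps`` time units with the compiled kernel.

    ``mode`` selects the proposal generator: ``"uniform"`` (the plain
    uniform-direction walk with whole-loop rejection) or ``"guided"``
    (locally legal continuations with the exact Metropolis symmetry
    factor — the production choice for dense systems).  ``hook(state)``
    fires every ``hook_every`` timesteps (after the chunk is complete).
    Fully reproducible: the trajectory is a pure function of the initial
    state and the generator's state.
    """
    if n_timesteps < 0:
        raise ValueError("n_timesteps must be >= 0")
    if mode not in ("uniform", "guided"):
        raise ValueError(f"unknown mode {mode!r}")
    stats = MoveStats(loop_hist=np.zeros(max_loop_len + 1, dtype=np.int64))
    if n_timesteps == 0:
        return stats
    if workspace is None:
        workspace = KernelWorkspace(state, max_loop_len)
    spec = state.spec
    chunk = hook_every if hook_every else n_timesteps
    rng_state = np.array([rng.state], dtype=np.uint64)
    counters = np.array([state.displacement_count, 0, 0], dtype=np.int64)
    loop_hist = np.zeros(max_loop_len + 1, dtype=np.int64)
    start_disp = int(counters[0])
    done = 0
    while done < n_timesteps:
        step = min(chunk, n_timesteps - done)
        done += step
        # absolute schedule: a walk overshooting a timestep boundary does
        # not stretch later timesteps
        target = start_disp + done * spec.n_sites
        kernel_fn = (
            _kernel.run_attempts if mode == "uniform" else _kernel.run_attempts_guided
        )
        kernel_fn(
            state.occ_chain,
            state.occ_bead,
            state.bead_site,
            spec.edge,
            spec.layers,
            spec.coordination,
            max_loop_len,
            target,
            rng_state,
            counters,
            workspace.mark,
            workspace.stamp,
            loop_hist,
        )
        state.timestep += step
        state.displacement_count = int(counters[0])
        rng.state = int(rng_state[0])
        if hook is not None:
            hook(state)
    stats.attempts = int(counters[1])
    stats.accepted = int(counters[2])
    stats.displacements = int(counters[0])
    stats.loop_hist = loop_hist
    return stats


class EquilibrationTimeout(RuntimeError):
    """Raised when the equilibration criterion is not met within the cap."""

    def __init__(self, history):
        self.history = history
        super().__init__(
            f"no equilibrium within cap; window means {[f'{m:.3g}' for m, _ in history]}"
        )


def equilibrate(
    state: SystemState,
    rng: Pcg32,
    window: int = 500,
    n_consecutive: int = 2,
    tol_sigmas: float = 2.0,
    max_time: int = 200_000,
    measure_every: int | None = None,
    max_loop_len: int = DEFAULT_MAX_LOOP_LEN,
) -> int:
    """Run until the ensemble-mean squared radius of gyration plateaus.

    The mean Rg^2 is block-averaged over successive windows of ``window``
    timesteps; equilibrium is declared after ``n_consecutive`` consecutive
    window pairs agree within ``tol_sigmas`` combined standard errors.
    Returns the elapsed simulation time.
    """
    from .observables import measure_state

    if measure_every is None:
        measure_every = max(1, window // 20)
    workspace = KernelWorkspace(state, max_loop_len)
    history: list[tuple[float, float]] = []
    elapsed = 0
    consecutive = 0
    while elapsed < max_time:
        samples: list[float] = []
        run(
            state,
            window,
            rng,
            max_loop_len,
            hook=lambda s: samples.append(measure_state(s).rg2.mean()),
            hook_every=measure_every,
            workspace=workspace,
        )
        elapsed += window
        arr = np.asarray(samples)
        history.append((arr.mean(), arr.std(ddof=1) / np.sqrt(len(arr))))
        if len(history) >= 2:
            (m1, e1), (m2, e2) = history[-2], history[-1]
            sigma = np.hypot(e1, e2)
            consecutive = consecutive + 1 if abs(m2 - m1) < tol_sigmas * sigma else 0
            if consecutive >= n_consecutive:
                return elapsed
    raise EquilibrationTimeout(history)
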