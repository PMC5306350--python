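"""Scaled-down simulation studies: dilute, semidilute and melt ensembles.

These are the package's standard desk-scale experiments — short chains
(N = 16..64) on a 64 x 64 single-layer box — used by the reproduction
targets, the acceptance script and the examples.  Production-scale
parameter grids (chains up to N = 1024 on 256^2..512^2 boxes) use the
same machinery through :class:`~cmapoly.plans.ExperimentPlan`; they are
simply longer runs.

Initialisation strategy (see docs/methods.md for the reasoning):

* dilute runs start from pivot-sampled single-chain equilibrium
  conformations placed in the box, so the cooperative dynamics starts in
  its stationary distribution and independent replicas give uncorrelated
  samples of the slow global modes;
* semidilute runs also start from placed SAW conformations — slightly
  over-expanded at phi ~ 0.3, and contraction is the fast relaxation
  direction;
* melts start from the disordered Hamiltonian-path fill (slightly
  compact, again relaxing along the fast direction) and use the guided
  move generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run
from .fixtures import sample_saw_chains
from .lattice import LatticeSpec
from .observables import PairDistanceHistogram, measure_state
from .rng import Pcg32
from .state import RunConfig, SystemState, build_disordered

DILUTE_PHI = 1.0 / 32.0  # 8/4/2 chains of N=16/32/64 on a 64^2 box
STANDARD_L = 64
STANDARD_CHAIN_LENGTHS = (16, 32, 64)


@dataclass
class EnsembleResult:
    """Summary statistics of one (N, phi) ensemble (possibly replicated)."""

    N: int
    n_chains: int
    L: int
    phi: float
    mode: str
    timesteps: int
    n_configs: int
    n_replicas: int
    rg2_series: np.ndarray  # per-config ensemble means
    ree2_series: np.ndarray
    lam_sum_sq_diff: float
    lam_sum_sq_tot: float
    acceptance_rate: float
    pair_hist: PairDistanceHistogram | None = None
    rg2_point: float | None = None  # bracket estimate overriding the series mean
    rg2_spread: float = 0.0  # bracket disagreement (two-sided protocols)

    @property
    def rg2_mean(self) -> float:
        if self.rg2_point is not None:
            return self.rg2_point
        return float(self.rg2_series.mean())

    @property
    def rg2_sem(self) -> float:
        """Blocked standard error: one block per replica, or 16 blocks for
        a single long trajectory; bracketed protocols add half the
        branch disagreement."""
        sem = blocked_sem(self.rg2_series, max(self.n_replicas, 16))
        return float(np.hypot(sem, 0.5 * self.rg2_spread))

    @property
    def ree2_mean(self) -> float:
        return float(self.ree2_series.mean())

    @property
    def asphericity(self) -> float:
        return self.lam_sum_sq_diff / self.lam_sum_sq_tot


def blocked_sem(series: np.ndarray, n_blocks: int = 16) -> float:
    """Standard error of the mean from block averages (guards against the
    serial correlation of Monte Carlo measurements)."""
    series = np.asarray(series, dtype=float)
    n_blocks = min(n_blocks, len(series))
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def place_saw_chains(
    N: int, n_chains: int, L: int, seed: int, max_tries: int = 2000
) -> SystemState:
    """Drop pivot-sampled SAW conformations into the periodic box at
    random positions, rejecting overlaps (with previously placed chains
    or with a chain's own periodic images).

    Above roughly 25% occupancy random insertion of long chains starts
    to fail; chains that cannot be inserted are grown in place instead
    (a self-avoiding walk over free sites with restarts), which slightly
    favours compact conformations but only for the last few chains.
    """
    spec = LatticeSpec(L)
    rng = np.random.default_rng(seed)
    pool = sample_saw_chains(N, 3 * n_chains + 4, seed + 1)
    occupied: set[int] = set()
    chains = []
    pool_i = 0
    for _ in range(n_chains):
        placed = False
        for attempt in range(max_tries):
            conf = pool[pool_i % len(pool)]
            pool_i += 1
            shift = rng.integers(0, L, size=2)
            ab = (conf + shift) % L
            sites = [spec.site_index(int(a), int(b)) for a, b in ab]
            if len(set(sites)) == N and not occupied.intersection(sites):
                occupied.update(sites)
                chains.append(np.column_stack([ab, np.zeros(N, dtype=np.int64)]))
                placed = True
                break
        if not placed:
            ab = _grow_chain(N, spec, occupied, rng)
            occupied.update(spec.site_index(int(a), int(b)) for a, b in ab)
            chains.append(np.column_stack([ab, np.zeros(N, dtype=np.int64)]))
    return SystemState.from_chains(spec, chains)


def _grow_chain(
    N: int, spec: LatticeSpec, occupied: set[int], rng, max_restarts: int = 20000
) -> np.ndarray:
    """Grow one chain on free sites by a uniform self-avoiding walk with
    restarts on dead ends."""
    from .lattice import IN_PLANE_DIRECTIONS

    L = spec.edge
    free = [s for s in range(L * L) if s not in occupied]
    for _ in range(max_restarts):
        start = int(free[rng.integers(len(free))])
        a, b = start % L, start // L
        path = [(a, b)]
        taken = {start}
        while len(path) < N:
            a, b = path[-1]
            options = []
            for da, db in IN_PLANE_DIRECTIONS:
                na, nb = (a + da) % L, (b + db) % L
                s = nb * L + na
                if s not in occupied and s not in taken:
                    options.append((na, nb, s))
            if not options:
                break
            na, nb, s = options[rng.integers(len(options))]
            path.append((na, nb))
            taken.add(s)
        if len(path) == N:
            return np.array(path, dtype=np.int64)
    raise RuntimeError(f"could not grow an N={N} chain; box too crowded")


def run_ensemble(
    state: SystemState,
    rng: Pcg32,
    equil_time: int,
    run_time: int,
    measure_every: int = 10,
    mode: str = "guided",
    collect_sq_every: int = 0,
    max_loop_len: int = 100,
    tail_swaps: bool = False,
) -> EnsembleResult:
    """Equilibrate and measure one system; deterministic in ``rng``.

    ``tail_swaps`` interleaves a burst of ``n_sites`` tail-exchange
    attempts every ``measure_every`` timesteps (melt mixing; see
    :func:`cmapoly.engine.exchange_tails`)."""
    from .engine import exchange_tails

    n_swaps = state.spec.n_sites if tail_swaps else 0
    if n_swaps:
        done = 0
        while done < equil_time:
            step = min(measure_every, equil_time - done)
            run(state, step, rng, mode=mode, max_loop_len=max_loop_len)
            exchange_tails(state, rng, n_swaps)
            done += step
    else:
        run(state, equil_time, rng, mode=mode, max_loop_len=max_loop_len)

    rg2, ree2 = [], []
    lam = {"diff": 0.0, "tot": 0.0}
    pair_hist = PairDistanceHistogram(state.N, state.spec) if collect_sq_every else None
    counter = {"i": 0}

    def hook(s: SystemState) -> None:
        if n_swaps:
            exchange_tails(s, rng, n_swaps)
        rec = measure_state(s)
        rg2.append(rec.rg2.mean())
        ree2.append(rec.ree2.mean())
        l1, l2 = rec.lams[:, -2], rec.lams[:, -1]
        lam["diff"] += float(np.sum((l2 - l1) ** 2))
        lam["tot"] += float(np.sum((l2 + l1) ** 2))
        counter["i"] += 1
        if collect_sq_every and counter["i"] % collect_sq_every == 0:
            pair_hist.add_state(s)

    stats = run(
        state, run_time, rng, mode=mode, hook=hook, hook_every=measure_every,
        max_loop_len=max_loop_len,
    )
    return EnsembleResult(
        N=state.N,
        n_chains=state.n_chains,
        L=state.spec.edge,
        phi=float(state.phi),
        mode=mode,
        timesteps=equil_time + run_time,
        n_configs=len(rg2),
        n_replicas=1,
        rg2_series=np.asarray(rg2),
        ree2_series=np.asarray(ree2),
        lam_sum_sq_diff=lam["diff"],
        lam_sum_sq_tot=lam["tot"],
        acceptance_rate=stats.acceptance_rate,
        pair_hist=pair_hist,
    )


def merge_replicas(results: list[EnsembleResult]) -> EnsembleResult:
    first = results[0]
    hist = None
    if first.pair_hist is not None:
        hist = PairDistanceHistogram(first.N, first.pair_hist.spec)
        for r in results:
            hist.counts += r.pair_hist.counts
            hist.n_chain_samples += r.pair_hist.n_chain_samples
    return EnsembleResult(
        N=first.N,
        n_chains=first.n_chains,
        L=first.L,
        phi=first.phi,
        mode=first.mode,
        timesteps=sum(r.timesteps for r in results),
        n_configs=sum(r.n_configs for r in results),
        n_replicas=len(results),
        rg2_series=np.concatenate([r.rg2_series for r in results]),
        ree2_series=np.concatenate([r.ree2_series for r in results]),
        lam_sum_sq_diff=sum(r.lam_sum_sq_diff for r in results),
        lam_sum_sq_tot=sum(r.lam_sum_sq_tot for r in results),
        acceptance_rate=float(np.mean([r.acceptance_rate for r in results])),
        pair_hist=hist,
    )


def dilute_study(
    seed: int,
    chain_lengths=STANDARD_CHAIN_LENGTHS,
    n_replicas: int = 24,
    run_time: int = 1500,
) -> dict[int, EnsembleResult]:
    """Dilute good-solvent ensembles at phi = 1/32 on a 64^2 box.

    Each replica starts from independently pivot-sampled equilibrium
    conformations; the short cooperative-motion run then samples around
    them (and would expose any drift if the start were not stationary).
    """
    base = Pcg32(seed)
    out = {}
    for i, N in enumerate(chain_lengths):
        n_chains = max(1, int(DILUTE_PHI * STANDARD_L**2) // N)
        reps = []
        for rep in range(n_replicas):
            rng = base.spawn(i * 1000 + rep)
            state = place_saw_chains(
                N, n_chains, STANDARD_L, seed=(rng.state % 2**31) | 1
            )
            reps.append(
                run_ensemble(
                    state, rng,
                    equil_time=200,
                    run_time=run_time,
                    measure_every=30,
                    mode="uniform",
                    collect_sq_every=5 if N == 64 else 0,
                )
            )
        out[N] = merge_replicas(reps)
    return out


#: replica count and (equilibration, production) time units per chain
#: length for the melt studies.  Longer chains mix more slowly and their
#: per-fill ensemble mean carries a frozen-draw error ~ sigma_chain /
#: sqrt(n_chains), so N = 64 gets the most replicas.
MELT_SCHEDULE = {16: (2, 2000, 6000), 32: (3, 3000, 8000), 64: (4, 4000, 9000)}


def melt_study(
    seed: int, chain_lengths=STANDARD_CHAIN_LENGTHS
) -> dict[int, EnsembleResult]:
    """Melt (phi = 1) ensembles on a 64^2 box.

    Cooperative loops alone leave melt chain sizes correlated with the
    start for very long times, so the guided loop dynamics is
    interleaved with tail-exchange moves, which renew global
    conformations while sampling the same uniform measure.  Even so,
    global mixing within one trajectory is partial: each disordered
    fill contributes a nearly frozen draw of chain conformations whose
    ensemble mean fluctuates by ~ sigma_chain / sqrt(n_chains) between
    fills.  The study therefore averages several independent fills and
    quotes the between-replica error.
    """
    base = Pcg32(seed + 1)
    out = {}
    for i, N in enumerate(chain_lengths):
        n_rep, equil, prod = MELT_SCHEDULE.get(N, (3, 3000, 8000))
        reps = []
        for r in range(n_rep):
            rng = base.spawn(16 * i + r)
            config = RunConfig(
                N=N, n_chains=STANDARD_L**2 // N, L=STANDARD_L,
                seed=(rng.state % 2**31) | 1,
            )
            state = build_disordered(config)
            reps.append(
                run_ensemble(
                    state, rng,
                    equil_time=equil,
                    run_time=prod,
                    measure_every=20,
                    mode="guided",
                    collect_sq_every=5 if N == 64 else 0,
                    tail_swaps=True,
                )
            )
        out[N] = merge_replicas(reps)
    return out


#: box edge, trajectory length and replica count per chain length for the
#: phi ~ 0.3 studies.  Global conformational mixing is slowest in this
#: regime; the box is reduced to 32 (still > 5 Rg for N = 64) because the
#: per-chain relaxation rate in time units depends on phi, not box size,
#: while CPU cost per time unit scales with the site count.
SEMIDILUTE_L = 32
SEMIDILUTE_SCHEDULE = {16: 150_000, 32: 500_000, 64: 1_000_000}
SEMIDILUTE_REPLICAS = 2


def semidilute_study(
    seed: int, phi: float = 0.3, chain_lengths=STANDARD_CHAIN_LENGTHS
) -> dict[int, EnsembleResult]:
    """Intermediate-concentration ensembles (default phi ~ 0.3).

    Each system is run from both sides of its equilibrium — replicas
    started from placed single-chain (dilute-swollen) conformations and
    replicas started from the compact disordered fill — and the
    equilibrium chain size is taken from a joint relaxation fit to all
    trajectories (:func:`relaxation_asymptote`): the branches share one
    asymptote, which is constrained to lie inside the late-time bracket
    they define.  The bracket disagreement is folded into the error.
    """
    base = Pcg32(seed + 2)
    L = SEMIDILUTE_L
    out = {}
    for i, N in enumerate(chain_lengths):
        n_chains = max(2, round(phi * L**2 / N))
        total = SEMIDILUTE_SCHEDULE.get(N, 100 * N**2)
        runs, above_series, below_series = [], [], []
        for j in range(2 * SEMIDILUTE_REPLICAS):
            side = "above" if j % 2 == 0 else "below"
            rng = base.spawn(16 * i + j)
            child_seed = (rng.state % 2**31) | 1
            if side == "above":
                state = place_saw_chains(N, n_chains, L, seed=child_seed)
            else:
                state = build_disordered(
                    RunConfig(N=N, n_chains=n_chains, L=L, seed=child_seed)
                )
            res = run_ensemble(
                state, rng,
                equil_time=0,  # whole trajectory feeds the relaxation fit
                run_time=total,
                measure_every=200,
                mode="uniform",
                collect_sq_every=4 if N == 64 else 0,
                tail_swaps=True,
            )
            runs.append(res)
            (above_series if side == "above" else below_series).append(res.rg2_series)
        merged = merge_replicas(runs)
        merged.rg2_point, merged.rg2_spread = relaxation_asymptote(
            above_series, below_series
        )
        out[N] = merged
    return out


def _block_curve(series_list: list[np.ndarray], n_blocks: int = 20) -> np.ndarray:
    stacked = np.mean([s[: min(map(len, series_list))] for s in series_list], axis=0)
    return np.array([b.mean() for b in np.array_split(stacked, n_blocks)])


def relaxation_asymptote(
    above_series: list[np.ndarray], below_series: list[np.ndarray]
) -> tuple[float, float]:
    """Shared-asymptote exponential fit to two-sided relaxation data.

    The replica-averaged block curves of the swollen-start and
    compact-start branches are fitted jointly as
    ``above(t) = A + a exp(-t/tau_a)`` and ``below(t) = A - b exp(-t/tau_b)``
    with a common asymptote ``A`` constrained to the interval spanned by
    the two branches' late-time means — whatever the fit does, the
    estimate stays inside the physical bracket.  If the fit fails
    (e.g. both branches already flat), the midpoint of the late-time
    means is used.  Returns ``(A, late-time branch spread)``.
    """
    from scipy.optimize import curve_fit

    up = _block_curve(above_series)
    dn = _block_curve(below_series)
    t = np.arange(1, len(up) + 1, dtype=float)
    up_late = float(up[len(up) // 2 :].mean())
    dn_late = float(dn[len(dn) // 2 :].mean())
    lo, hi = sorted((up_late, dn_late))
    spread = hi - lo
    mid = 0.5 * (lo + hi)
    if spread < 1e-9:
        return mid, spread

    T = t[-1]

    def model(tt, A, a, ta, b, tb):
        half = len(tt) // 2
        out = np.empty_like(tt)
        out[:half] = A + a * np.exp(-tt[:half] / ta)
        out[half:] = A - b * np.exp(-tt[half:] / tb)
        return out

    x = np.concatenate([t, t])
    y = np.concatenate([up, dn])
    try:
        popt, _ = curve_fit(
            model, x, y,
            p0=[mid, max(up[0] - mid, 1e-3), T / 3, max(mid - dn[0], 1e-3), T / 3],
            bounds=([lo, 0.0, T / 50, 0.0, T / 50], [hi, np.inf, 50 * T, np.inf, 50 * T]),
            maxfev=20000,
        )
        return float(popt[0]), spread
    except (RuntimeError, ValueError):
        return mid, spread
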