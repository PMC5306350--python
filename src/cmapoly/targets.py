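"""Reproduction targets: scaled-down experiments for the headline numbers.

Each target recomputes one published-scale quantity from scratch at desk
scale — short chains (N = 16..64) on a 64 x 64 box — and reports the
measured value next to the reference it is compared against:

========  ================================================  =========
id        quantity                                          reference
========  ================================================  =========
t1        asphericity A2 of fully extended (rod) chains        1
t5        2 nu from <Rg^2> ~ N^(2 nu), dilute good solvent     1.5
t6        2 nu in the melt (phi = 1)                           1
t7        Rg^2-vs-N log-log slope at phi = 0.3                 1.25
t8        melt ensemble asphericity A2 (N = 32)                0.52
t10       S(q) log-log slope, melt chain, fractal window       -2
========  ================================================  =========

``compute_targets`` shares simulation ensembles between targets (the
melt study feeds t6, t8 and t10), so computing everything costs three
study sweeps.  All runs are deterministic in the seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import observables
from .fixtures import make_rod
from .scaling import estimate_2nu, sq_slope
from .study import dilute_study, melt_study, semidilute_study

TARGET_REFERENCES = {
    "t1": (1.0, "rod-ensemble asphericity"),
    "t5": (1.5, "dilute 2D good-solvent exponent 2nu"),
    "t6": (1.0, "melt exponent 2nu"),
    "t7": (1.25, "Rg^2 vs N slope at intermediate concentration"),
    "t8": (0.52, "melt asphericity, N > 16"),
    "t10": (-2.0, "melt single-chain structure-factor slope"),
}


@dataclass
class TargetReport:
    target: str
    value: float
    n: int
    reference: float
    description: str
    runtime_s: float
    detail: str = ""


def _rod_asphericity(seed: int) -> TargetReport:
    t0 = time.time()
    lams = []
    lengths = range(3, 65)
    for N in lengths:
        fx = make_rod(N)
        chain = next(fx.to_state().chains())
        _, lam = observables.gyration_tensor(chain, fx.spec)
        lams.append(lam)
    a2 = observables.asphericity(np.array(lams))
    return TargetReport(
        "t1", float(a2), len(list(lengths)), 1.0,
        TARGET_REFERENCES["t1"][1], time.time() - t0,
        "exact geometry: lam1 = 0 for collinear chains",
    )


def _fit_2nu_report(tid: str, results, t0: float) -> TargetReport:
    Ns = sorted(results)
    rg2 = [results[N].rg2_mean for N in Ns]
    fit = estimate_2nu(Ns, rg2)
    n_cfg = sum(results[N].n_configs * results[N].n_chains for N in Ns)
    ref, desc = TARGET_REFERENCES[tid]
    detail = "; ".join(
        f"N={N}: Rg2={results[N].rg2_mean:.2f}+-{results[N].rg2_sem:.2f}" for N in Ns
    )
    return TargetReport(
        tid, fit.exponent, n_cfg, ref, desc, time.time() - t0,
        f"{detail}; stderr={fit.stderr:.3f}",
    )


def _dilute_exponent(seed: int, results=None) -> TargetReport:
    t0 = time.time()
    if results is None:
        results = dilute_study(seed)
    return _fit_2nu_report("t5", results, t0)


def _melt_exponent(seed: int, results=None) -> TargetReport:
    t0 = time.time()
    if results is None:
        results = melt_study(seed)
    return _fit_2nu_report("t6", results, t0)


def _semidilute_slope(seed: int, results=None) -> TargetReport:
    t0 = time.time()
    if results is None:
        results = semidilute_study(seed)
    return _fit_2nu_report("t7", results, t0)


def _melt_asphericity(seed: int, results=None) -> TargetReport:
    t0 = time.time()
    if results is None:
        results = melt_study(seed, chain_lengths=(32,))
    res = results[32]
    return TargetReport(
        "t8", res.asphericity, res.n_configs * res.n_chains, 0.52,
        TARGET_REFERENCES["t8"][1], time.time() - t0,
        f"phi=1 melt, N=32, {res.n_configs} configurations",
    )


def melt_sq_fit(res):
    """Structure factor and fractal-window slope from a melt ensemble."""
    profile = observables.intramolecular_correlation(res.pair_hist)
    spec_L = res.L
    from .lattice import LatticeSpec

    q = observables.default_q_grid(LatticeSpec(spec_L))
    curve = observables.structure_factor(profile, q)
    rg = np.sqrt(res.rg2_mean)
    window = (2.0 * np.pi / rg, np.pi)
    return curve, sq_slope(curve, window=window), window


def _melt_sq_slope(seed: int, results=None) -> TargetReport:
    t0 = time.time()
    if results is None:
        results = melt_study(seed, chain_lengths=(64,))
    res = results[64]
    curve, fit, window = melt_sq_fit(res)
    return TargetReport(
        "t10", fit.exponent, res.pair_hist.n_chain_samples, -2.0,
        TARGET_REFERENCES["t10"][1], time.time() - t0,
        f"fit window q in [{window[0]:.2f}, {window[1]:.2f}], stderr={fit.stderr:.3f}",
    )


_SINGLE = {
    "t1": _rod_asphericity,
    "t5": _dilute_exponent,
    "t6": _melt_exponent,
    "t7": _semidilute_slope,
    "t8": _melt_asphericity,
    "t10": _melt_sq_slope,
}


def compute_target(target: str, seed: int) -> TargetReport:
    """Recompute a single target from scratch (runs its own simulations)."""
    if target not in _SINGLE:
        raise KeyError(
            f"unknown target {target!r}; available: {sorted(_SINGLE)}"
        )
    return _SINGLE[target](seed)


def compute_targets(seed: int) -> dict[str, TargetReport]:
    """Recompute every target, sharing ensembles between them."""
    out = {"t1": _rod_asphericity(seed)}
    dil = dilute_study(seed)
    out["t5"] = _dilute_exponent(seed, dil)
    melt = melt_study(seed)
    out["t6"] = _melt_exponent(seed, melt)
    out["t8"] = _melt_asphericity(seed, melt)
    out["t10"] = _melt_sq_slope(seed, melt)
    semi = semidilute_study(seed)
    out["t7"] = _semidilute_slope(seed, semi)
    return out
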