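"""Conformational and structural observables.

All single-chain quantities are computed on periodically *unwrapped*
Cartesian coordinates (bead 0 at its in-box position, each subsequent
bead placed by the minimum-image displacement of its bond), so a chain
straddling the boundary is measured as one connected object.  Inter-bead
and inter-chain distances use the minimum-image convention on the
rhombic periodic cell.

Quantities:

* squared radius of gyration  Rg^2 = (1/N) sum_i (r_i - r_cm)^2
* gyration tensor  T_kl = (1/N) sum_i (r_ik - r_cm,k)(r_il - r_cm,l),
  eigenvalues lam_1 <= lam_2 (<= lam_3 in the two-layer box); the trace
  of T equals Rg^2
* asphericity  A2 = <(lam_2 - lam_1)^2> / <(lam_2 + lam_1)^2>, a ratio
  of ensemble means: 1 for fully extended (rod-like) chains, 0 for a disk
* intramolecular correlation  gamma(r) = (1/N) <c(r_i) c(r_j)> over
  ordered bead pairs of one chain (self pairs included), and the
  single-chain structure factor  S(q) = sum_ij gamma(r) sin(qr)/(qr)
  with S(q -> 0) = N
* centre-of-mass pair correlation g_cm-cm(r), normalised so the
  large-r plateau is 1 (the "correlation hole" shows as g < 1 at small r)
* solvent connected-cluster sizes (lattice adjacency)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import j0 as _bessel_j0

from .lattice import SQRT3, LatticeSpec, periodic_images, to_cartesian
from .state import Chain, SystemState

# --- unwrapping ---------------------------------------------------------


def _unwrap_batch(coords: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """Unwrap ``(C, N, 3)`` axial bead coordinates to Cartesian ``(C, N, dim)``."""
    L = spec.edge
    half = L // 2
    d = np.diff(coords[..., :2].astype(np.int64), axis=-2)
    d = (d + half) % L - half  # minimum-image bond step (|da|,|db| <= 1)
    dx = d[..., 0] + 0.5 * d[..., 1]
    dy = d[..., 1] * (SQRT3 / 2.0)
    start = to_cartesian(coords[..., 0, :2].reshape(-1, 2)).reshape(
        coords.shape[:-2] + (2,)
    )
    x = start[..., :1] + np.concatenate(
        [np.zeros(dx.shape[:-1] + (1,)), np.cumsum(dx, axis=-1)], axis=-1
    )
    y = start[..., 1:] + np.concatenate(
        [np.zeros(dy.shape[:-1] + (1,)), np.cumsum(dy, axis=-1)], axis=-1
    )
    if spec.layers == 2:
        z = coords[..., 2].astype(float)
        return np.stack([x, y, z], axis=-1)
    return np.stack([x, y], axis=-1)


def unwrap_chain(chain: Chain, spec: LatticeSpec) -> np.ndarray:
    """Unwrapped ``(N, dim)`` Cartesian coordinates of one chain.

    Raises if a bond is broken; warns if the unwrapped extent exceeds the
    box edge (the box should be larger than the chains it holds).
    """
    coords = np.asarray(chain.beads, dtype=np.int64)[None]
    pos = _unwrap_batch(coords, spec)[0]
    bond = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if not np.allclose(bond, 1.0, atol=1e-9):
        raise ValueError("chain has a broken bond; cannot unwrap")
    span = pos.max(axis=0) - pos.min(axis=0)
    if span[:2].max() > spec.edge:
        warnings.warn("chain extent exceeds the box edge; finite-size bias likely")
    return pos


# --- single-chain scalars ----------------------------------------------


def radius_of_gyration_sq(chain: Chain, spec: LatticeSpec) -> float:
    """Mean squared distance of the beads from their centroid."""
    pos = unwrap_chain(chain, spec)
    c = pos - pos.mean(axis=0)
    return float(np.einsum("ij,ij->", c, c) / len(pos))


def gyration_tensor(chain: Chain, spec: LatticeSpec):
    """Gyration tensor and its ascending eigenvalues.

    Returns ``(T, eigenvalues)`` with ``trace(T) == Rg^2``.
    """
    pos = unwrap_chain(chain, spec)
    c = pos - pos.mean(axis=0)
    T = c.T @ c / len(pos)
    return T, np.linalg.eigvalsh(T)


def end_to_end_sq(chain: Chain, spec: LatticeSpec) -> float:
    pos = unwrap_chain(chain, spec)
    d = pos[-1] - pos[0]
    return float(d @ d)


def asphericity(lams: np.ndarray) -> float:
    """A2 from an ensemble of gyration-tensor eigenvalue samples.

    ``lams`` is ``(n_samples, dim)``, eigenvalues ascending; the two
    largest (the in-plane pair in the quasi-2D box) enter the ratio of
    ensemble means — not a mean of per-sample ratios.
    """
    lams = np.atleast_2d(np.asarray(lams, dtype=float))
    if lams.shape[0] < 1:
        raise ValueError("need at least one eigenvalue sample")
    l1, l2 = lams[:, -2], lams[:, -1]
    denom = np.mean((l2 + l1) ** 2)
    if denom == 0.0:
        raise ValueError("all eigenvalue sums are zero; A2 undefined")
    return float(np.mean((l2 - l1) ** 2) / denom)


@dataclass
class ObservableRecord:
    """Per-configuration chain metrics (one row per chain)."""

    timestep: int
    rg2: np.ndarray  # (n_chains,)
    ree2: np.ndarray  # (n_chains,)
    lams: np.ndarray  # (n_chains, dim) ascending eigenvalues

    def __post_init__(self) -> None:
        trace = self.lams.sum(axis=1)
        if not np.allclose(trace, self.rg2, rtol=1e-10, atol=1e-10):
            raise AssertionError("eigenvalue sum does not reproduce Rg^2")


def measure_state(state: SystemState) -> ObservableRecord:
    """Vectorised per-chain Rg^2, Ree^2 and gyration-tensor eigenvalues."""
    pos = _unwrap_batch(state.bead_coords().astype(np.int64), state.spec)
    c = pos - pos.mean(axis=1, keepdims=True)
    T = np.einsum("cni,cnj->cij", c, c) / state.N
    lams = np.linalg.eigvalsh(T)
    rg2 = np.einsum("cii->c", T)
    d = pos[:, -1] - pos[:, 0]
    ree2 = np.einsum("ci,ci->c", d, d)
    return ObservableRecord(state.timestep, rg2, ree2, lams)


# --- pair-distance machinery -------------------------------------------


def _min_image_sq(delta_xy: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    cands = delta_xy[:, None, :] + periodic_images(spec)[None, :, :]
    return np.einsum("nij,nij->ni", cands, cands).min(axis=1)


def _quarter_r2_pairs(beads: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """4*d^2 (an exact integer on this lattice) for all unordered bead
    pairs of one chain, minimum-image convention."""
    pos = to_cartesian(np.asarray(beads)[:, :2])
    iu, ju = np.triu_indices(len(pos), k=1)
    delta = pos[ju] - pos[iu]
    r2 = _min_image_sq(delta, spec)
    if beads.shape[1] >= 3 and spec.layers == 2:
        dz = beads[ju, 2].astype(float) - beads[iu, 2].astype(float)
        r2 = r2 + dz * dz
    return np.rint(4.0 * r2).astype(np.int64)


class PairDistanceHistogram:
    """Exact multiset of same-chain bead-pair distances, accumulated over
    configurations.  Distances are stored by the integer 4*r^2, so no
    binning error enters the structure factor."""

    def __init__(self, N: int, spec: LatticeSpec):
        self.N = N
        self.spec = spec
        bound = 4 * (spec.edge**2 + spec.layers**2) + 1
        self.counts = np.zeros(bound, dtype=np.int64)  # ordered pairs incl. self
        self.n_chain_samples = 0

    def add_state(self, state: SystemState) -> None:
        coords = state.bead_coords()
        for c in range(state.n_chains):
            self.add_chain(coords[c])

    def add_chain(self, beads: np.ndarray) -> None:
        keys = _quarter_r2_pairs(np.asarray(beads), self.spec)
        self.counts[0] += self.N  # self pairs, r = 0
        np.add.at(self.counts, keys, 2)  # ordered pairs: (i,j) and (j,i)
        self.n_chain_samples += 1

    @property
    def r(self) -> np.ndarray:
        idx = np.flatnonzero(self.counts)
        return np.sqrt(idx / 4.0)

    @property
    def weights(self) -> np.ndarray:
        """Mean ordered-pair count per sampled chain at each distance in ``r``."""
        idx = np.flatnonzero(self.counts)
        return self.counts[idx] / self.n_chain_samples


@dataclass
class CorrelationProfile:
    """A binned radial profile; intramolecular profiles also carry the
    exact pair-distance multiset used for structure-factor evaluation."""

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    exact_r: np.ndarray | None = None
    exact_weight: np.ndarray | None = None
    N: int | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def intramolecular_correlation(
    chain: Chain | PairDistanceHistogram,
    spec: LatticeSpec | None = None,
    bins: np.ndarray | None = None,
) -> CorrelationProfile:
    """gamma(r): mean ordered same-chain pair count at distance r, / N.

    The self pair (i = j, r = 0) is included, so the profile's total
    weight is exactly N.  Accepts a single chain or an accumulated
    :class:`PairDistanceHistogram` for ensemble averages.
    """
    if isinstance(chain, PairDistanceHistogram):
        hist = chain
    else:
        hist = PairDistanceHistogram(len(chain.beads), spec)
        hist.add_chain(chain.beads)
    r, w = hist.r, hist.weights
    if bins is None:
        bins = np.arange(0.0, np.ceil(r.max()) + 1.5) - 0.5  # unit bins on r
    bins = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(r, bins=bins, weights=w)
    return CorrelationProfile(
        bin_edges=bins,
        values=counts / hist.N,
        counts=counts,
        exact_r=r,
        exact_weight=w,
        N=hist.N,
    )


@dataclass
class StructureFactorCurve:
    q: np.ndarray
    s: np.ndarray


def default_q_grid(spec: LatticeSpec, n: int = 64) -> np.ndarray:
    """64 log-spaced scattering vectors between the box scale and pi."""
    return np.geomspace(2.0 * np.pi / spec.edge, np.pi, n)


def structure_factor(
    profile: CorrelationProfile, q_grid: np.ndarray, kernel: str = "sinc"
) -> StructureFactorCurve:
    """S(q) = sum over ordered pairs of gamma(r) sin(qr)/(qr).

    Evaluated on the exact pair distances (the r = 0 self term contributes
    1 per bead), so S(q -> 0+) -> N.  ``kernel='j0'`` swaps the printed
    sin(qr)/(qr) kernel for the Bessel J0 appropriate to a strictly 2D
    isotropic average, as a sensitivity check.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("scattering vectors must be positive")
    if profile.exact_r is not None:
        r, w = profile.exact_r, profile.exact_weight
    else:
        r, w = profile.bin_centers, profile.counts
    qr = q[:, None] * r[None, :]
    if kernel == "sinc":
        k = np.sinc(qr / np.pi)  # np.sinc(x) = sin(pi x)/(pi x); value 1 at 0
    elif kernel == "j0":
        k = _bessel_j0(qr)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    s = (k * w[None, :]).sum(axis=1) / profile.N
    return StructureFactorCurve(q=q, s=s)


# --- inter-chain packing -----------------------------------------------


def chain_centers(state: SystemState) -> np.ndarray:
    """Unwrapped chain centroids mapped back into the periodic cell, (C, 2)."""
    pos = _unwrap_batch(state.bead_coords().astype(np.int64), state.spec)
    cm = pos.mean(axis=1)[:, :2]
    L = state.spec.edge
    # invert the embedding x = a + b/2, y = b*sqrt(3)/2, wrap, re-embed
    b = cm[:, 1] * 2.0 / SQRT3
    a = cm[:, 0] - 0.5 * b
    a %= L
    b %= L
    return np.column_stack([a + 0.5 * b, b * SQRT3 / 2.0])


def points_pair_correlation(
    point_sets: list[np.ndarray], spec: LatticeSpec, bins: np.ndarray
) -> CorrelationProfile:
    """Radial pair correlation of in-box 2D point patterns, annulus-area
    normalised so a uniform (ideal-gas) pattern gives g(r) = 1.

    Only meaningful for r below half the box edge (minimum-image validity).
    """
    bins = np.asarray(bins, dtype=float)
    counts = np.zeros(len(bins) - 1)
    n_pairs = 0
    for pts in point_sets:
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 2:
            raise ValueError("need at least 2 points per configuration")
        iu, ju = np.triu_indices(len(pts), k=1)
        r = np.sqrt(_min_image_sq(pts[ju] - pts[iu], spec))
        c, _ = np.histogram(r, bins=bins)
        counts += c
        n_pairs += len(iu)
    cell_area = spec.edge**2 * SQRT3 / 2.0
    annulus = np.pi * np.diff(bins**2)
    expected = n_pairs * annulus / cell_area
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return CorrelationProfile(bin_edges=bins, values=g, counts=counts)


def cm_pair_correlation(
    states: SystemState | list[SystemState], bins: np.ndarray
) -> CorrelationProfile:
    """g_cm-cm(r) over one or more configurations; plateau-1 convention."""
    if isinstance(states, SystemState):
        states = [states]
    if states[0].n_chains < 2:
        raise ValueError("centre-of-mass correlation needs at least 2 chains")
    return points_pair_correlation(
        [chain_centers(s) for s in states], states[0].spec, bins
    )


# --- solvent clusters ---------------------------------------------------


def solvent_cluster_sizes(state: SystemState) -> list[int]:
    """Connected-component sizes of the solvent sites (lattice adjacency)."""
    from .lattice import neighbors

    sites = state.solvent_sites()
    if len(sites) == 0:
        return []
    index = {int(s): i for i, s in enumerate(sites)}
    rows, cols = [], []
    spec = state.spec
    for s in sites:
        i = index[int(s)]
        for nb in neighbors(spec.site_coord(int(s)), spec):
            j = index.get(spec.site_index(*nb))
            if j is not None:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(sites), len(sites))
    )
    n_comp, labels = connected_components(adj, directed=False)
    return sorted(np.bincount(labels, minlength=n_comp).tolist())
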