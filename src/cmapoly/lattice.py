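"""Triangular-lattice geometry: coordinates, neighbours, periodic metric.

Sites are addressed by axial integer coordinates ``(a, b)`` (plus a layer
index for the quasi-2D two-layer box) on a rhombic periodic cell of edge
``L``: both axial directions wrap modulo ``L``.  The Cartesian embedding

    x = a + b/2,    y = b * sqrt(3)/2

gives every nearest-neighbour bond length exactly 1, i.e. the standard
unit-bond triangular lattice with coordination number six.  In the
two-layer variant each site additionally neighbours its mirror image in
the other layer (coordination seven, interlayer spacing 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SQRT3 = np.sqrt(3.0)

#: The six in-plane unit displacement vectors in axial coordinates.
IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (-1, 0),
    (0, 1),
    (0, -1),
    (1, -1),
    (-1, 1),
)


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the periodic simulation box.

    Parameters
    ----------
    edge:
        Number of sites per side, ``L``.  Must be at least 4 so that the
        minimum-image convention is unambiguous for neighbour bonds.
    layers:
        1 for the strictly 2D box, 2 for the quasi-2D two-layer box.
    """

    edge: int
    layers: int = 1

    def __post_init__(self) -> None:
        if self.edge < 4:
            raise ValueError(f"lattice edge must be >= 4, got {self.edge}")
        if self.layers not in (1, 2):
            raise ValueError(f"layers must be 1 or 2, got {self.layers}")

    @property
    def n_sites(self) -> int:
        return self.layers * self.edge * self.edge

    @property
    def coordination(self) -> int:
        """Nearest neighbours per site: 6 in-plane, +1 mirror site if layered."""
        return 6 if self.layers == 1 else 7

    # --- site indexing -------------------------------------------------

    def site_index(self, a: int, b: int, layer: int = 0) -> int:
        """Flat index ``layer*L^2 + b*L + a`` of a validated site."""
        self.validate_site(a, b, layer)
        return layer * self.edge * self.edge + b * self.edge + a

    def site_coord(self, index: int) -> tuple[int, int, int]:
        L = self.edge
        if not 0 <= index < self.n_sites:
            raise ValueError(f"site index {index} out of range for {self}")
        layer, rem = divmod(index, L * L)
        b, a = divmod(rem, L)
        return a, b, layer

    def validate_site(self, a: int, b: int, layer: int = 0) -> None:
        if not (0 <= a < self.edge and 0 <= b < self.edge):
            raise ValueError(f"site ({a},{b}) outside 0..{self.edge - 1}")
        if not 0 <= layer < self.layers:
            raise ValueError(f"layer {layer} invalid for {self.layers}-layer box")


def neighbors(site: tuple[int, int, int] | tuple[int, int], spec: LatticeSpec):
    """All nearest neighbours of ``site``, periodic-wrapped.

    Returns 6 sites for a single-layer box and 7 (the 6 in-plane plus the
    mirror site in the other layer) for a two-layer box.  The relation is
    symmetric: ``s in neighbors(n)`` whenever ``n in neighbors(s)``.
    """
    a, b, layer = _unpack(site)
    spec.validate_site(a, b, layer)
    L = spec.edge
    out = [((a + da) % L, (b + db) % L, layer) for da, db in IN_PLANE_DIRECTIONS]
    if spec.layers == 2:
        out.append((a, b, 1 - layer))
    return out


def to_cartesian(site, spec: LatticeSpec | None = None) -> np.ndarray:
    """Cartesian embedding of a site (or array of axial coordinates).

    ``x = a + b/2``, ``y = b*sqrt(3)/2``; two-layer boxes add ``z = layer``.
    Accepts a single ``(a, b[, layer])`` tuple or an ``(n, 2)``/``(n, 3)``
    integer array and returns a float array of the same leading shape.
    """
    arr = np.asarray(site, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    x = arr[:, 0] + 0.5 * arr[:, 1]
    y = arr[:, 1] * (SQRT3 / 2.0)
    if arr.shape[1] >= 3:
        cart = np.column_stack([x, y, arr[:, 2]])
    else:
        cart = np.column_stack([x, y])
    return cart[0] if single else cart


def _unpack(site) -> tuple[int, int, int]:
    if len(site) == 2:
        a, b = site
        return int(a), int(b), 0
    a, b, layer = site
    return int(a), int(b), int(layer)


def periodic_images(spec: LatticeSpec) -> np.ndarray:
    """Cartesian offsets of the 9 in-plane periodic images of the rhombic cell."""
    L = spec.edge
    a1 = np.array([L, 0.0])
    a2 = np.array([0.5 * L, L * SQRT3 / 2.0])
    return np.array([i * a1 + j * a2 for i in (-1, 0, 1) for j in (-1, 0, 1)])


def minimum_image_displacement(s1, s2, spec: LatticeSpec) -> np.ndarray:
    """Shortest Cartesian displacement from ``s1`` to ``s2``.

    Exact for the rhombic cell: the true minimum is attained over the 9
    in-plane periodic images (the layer offset, if any, is not wrapped).
    """
    a1, b1, l1 = _unpack(s1)
    a2, b2, l2 = _unpack(s2)
    spec.validate_site(a1, b1, l1)
    spec.validate_site(a2, b2, l2)
    d = to_cartesian((a2, b2))[:2] - to_cartesian((a1, b1))[:2]
    cands = d[None, :] + periodic_images(spec)
    best = cands[np.argmin(np.einsum("ij,ij->i", cands, cands))]
    if spec.layers == 2:
        return np.array([best[0], best[1], float(l2 - l1)])
    return best


def minimum_image_distances(delta_xy: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """Minimum-image Euclidean lengths of an ``(n, 2)`` array of in-plane
    Cartesian separations (vectorised over the 9 periodic images)."""
    cands = delta_xy[:, None, :] + periodic_images(spec)[None, :, :]
    return np.sqrt(np.einsum("nij,nij->ni", cands, cands).min(axis=1))


def axial_min_image_step(da: int, db: int, L: int) -> tuple[int, int]:
    """Centre an axial difference into ``[-L/2, L/2)`` per component.

    For nearest-neighbour bonds this recovers the true unit displacement
    vector across the periodic boundary.
    """
    half = L // 2
    return ((da + half) % L - half, (db + half) % L - half)
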