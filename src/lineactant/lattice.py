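"""Periodic triangular lattice, spin fields and local star sums.

The membrane is discretised as a two-dimensional Ising system on a
triangular lattice: each site carries a spin ``s = +1`` (liquid-disordered,
L_d) or ``s = -1`` (liquid-ordered, L_o).  Composition is conserved, so the
spin counts are fixed at initialisation and never change under the
exchange dynamics.

Coordinates are axial: a site is addressed as ``(q, r)`` with
``0 <= q < W`` and ``0 <= r < H`` and flattened to ``index = r * W + q``.
The six nearest neighbours of ``(q, r)`` are::

    (q+1, r), (q-1, r), (q, r+1), (q, r-1), (q+1, r-1), (q-1, r+1)

all taken modulo ``(W, H)``.  Under this convention a rotation by any
multiple of 60 degrees maps lattice vectors onto lattice vectors exactly
(see :func:`rotate_offset`), which keeps rigid tile rotations free of
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeSpec",
    "TriangularLattice",
    "SpinField",
    "rotate_offset",
    "init_spins",
    "local_star_sum",
    "minority_counts",
]

#: Axial displacements of the six nearest neighbours, in fixed order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (-1, 0),
    (0, 1),
    (0, -1),
    (1, -1),
    (-1, 1),
)


class ConfigurationError(ValueError):
    """Raised when a lattice or model configuration is invalid."""


@dataclass(frozen=True)
class LatticeSpec:
    """Dimensions of the periodic triangular box.

    ``H`` is required to be even so that configurations remain valid under
    the row conventions used elsewhere in the package.
    """

    width: int
    height: int

    def __post_init__(self) -> None:
        # below 3x4 the periodic wrap collapses neighbours and sites no
        # longer have six distinct ones
        if self.width < 3 or self.height < 4:
            raise ConfigurationError(
                f"lattice must be at least 3x4, got {self.width}x{self.height}"
            )
        if self.height % 2 != 0:
            raise ConfigurationError(
                f"lattice height must be even, got {self.height}"
            )

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def n_bonds(self) -> int:
        # six neighbours per site, each bond shared by two sites
        return 3 * self.width * self.height


def rotate_offset(dq: int, dr: int, k: int) -> tuple[int, int]:
    """Rotate an axial offset by ``k`` sixths of a turn (60 deg clockwise each).

    Exact on the lattice: axial -> cube, apply (x, y, z) -> (-z, -x, -y)
    ``k`` times, -> axial.
    """
    x, z = dq, dr
    y = -x - z
    for _ in range(k % 6):
        x, y, z = -z, -x, -y
    return x, z


class TriangularLattice:
    """Neighbour index structure for a :class:`LatticeSpec`.

    Attributes
    ----------
    neighbors : (N, 6) int32 array
        ``neighbors[i, d]`` is the flat index of the ``d``-th neighbour of
        site ``i``, following :data:`NEIGHBOR_OFFSETS`.
    """

    def __init__(self, spec: LatticeSpec):
        self.spec = spec
        W, H = spec.width, spec.height
        q = np.arange(W)
        r = np.arange(H)
        qq, rr = np.meshgrid(q, r)  # shape (H, W)
        neigh = np.empty((H * W, 6), dtype=np.int32)
        for d, (dq, dr) in enumerate(NEIGHBOR_OFFSETS):
            nq = (qq + dq) % W
            nr = (rr + dr) % H
            neigh[:, d] = (nr * W + nq).ravel()
        self.neighbors = neigh

    @property
    def n_sites(self) -> int:
        return self.spec.n_sites

    def index(self, q, r):
        """Flat index of axial coordinates (arrays allowed), with wrap."""
        W, H = self.spec.width, self.spec.height
        return (np.asarray(r) % H) * W + (np.asarray(q) % W)

    def coords(self, idx):
        """Axial ``(q, r)`` of flat indices."""
        W = self.spec.width
        idx = np.asarray(idx)
        return idx % W, idx // W

    def bonds(self) -> np.ndarray:
        """Undirected bond list, shape ``(3*N, 2)``; each bond appears once."""
        i = np.repeat(np.arange(self.n_sites), 6)
        j = self.neighbors.ravel()
        mask = i < j
        out = np.column_stack([i[mask], j[mask]])
        # periodic wrap can place both directed copies with i < j on tiny
        # lattices; deduplicate defensively
        if out.shape[0] != self.spec.n_bonds:
            out = np.unique(np.sort(np.column_stack([i, j]), axis=1), axis=0)
        return out


@dataclass
class SpinField:
    """Spin configuration plus cached composition counts."""

    lattice: TriangularLattice
    spins: np.ndarray  # int8, shape (N,)
    n_up: int = field(init=False)
    n_down: int = field(init=False)

    def __post_init__(self) -> None:
        if self.spins.shape != (self.lattice.n_sites,):
            raise ConfigurationError("spin array does not match lattice size")
        if not np.all(np.abs(self.spins) == 1):
            raise ConfigurationError("spins must be +/-1")
        self.refresh_counts()

    def refresh_counts(self) -> None:
        self.n_up = int(np.sum(self.spins == 1))
        self.n_down = int(np.sum(self.spins == -1))

    @property
    def ratio(self) -> float:
        """Composition ratio n(-1)/n(+1)."""
        return self.n_down / self.n_up

    def copy(self) -> "SpinField":
        return SpinField(self.lattice, self.spins.copy())


def minority_counts(n_sites: int, ratio: float) -> tuple[int, int]:
    """Spin counts for composition ratio ``r = n(-1)/n(+1)``.

    Rounding rule: ``n(-1) = round(N * r / (1 + r))``, remainder to the
    majority (+1) phase.
    """
    if ratio <= 0:
        raise ConfigurationError(f"composition ratio must be > 0, got {ratio}")
    n_down = int(round(n_sites * ratio / (1.0 + ratio)))
    return n_sites - n_down, n_down


def init_spins(
    lattice: TriangularLattice | LatticeSpec,
    ratio: float = 2.0 / 3.0,
    seed: int | np.random.SeedSequence = 0,
    rng: np.random.Generator | None = None,
) -> SpinField:
    """Uniformly random spin field at the given composition ratio.

    Emulates the infinite-temperature preparation: spins are shuffled
    uniformly at random, with exactly ``round(N*r/(1+r))`` spins of the
    minority (-1, L_o) species.
    """
    if isinstance(lattice, LatticeSpec):
        lattice = TriangularLattice(lattice)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_up, n_down = minority_counts(lattice.n_sites, ratio)
    spins = np.empty(lattice.n_sites, dtype=np.int8)
    spins[:n_down] = -1
    spins[n_down:] = 1
    rng.shuffle(spins)
    return SpinField(lattice, spins)


def local_star_sum(field: SpinField, site: int) -> int:
    """Sum of the spin at ``site`` and its six nearest neighbours.

    This is the quantity the anchor couplings act on; it is always odd and
    lies in ``[-7, 7]``.
    """
    s = field.spins
    return int(s[site]) + int(s[field.lattice.neighbors[site]].sum())


def star_sums(spins: np.ndarray, neighbors: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Vectorised :func:`local_star_sum` over an array of sites."""
    sites = np.asarray(sites)
    return spins[sites].astype(np.int64) + spins[neighbors[sites]].sum(axis=1)
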