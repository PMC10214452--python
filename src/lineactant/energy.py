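"""Hamiltonian of the tile-decorated lattice membrane.

The total energy (in k_BT) of a configuration is

    H = -J * sum_<ij> s_i s_j  -  sum_a J_a * s̃_a

where the first sum runs over nearest-neighbour bonds and the second over
all anchors; ``s̃_a`` is the star sum over the anchor's host site and its
six neighbours.  The sign convention makes a positive ``J_sT`` favour the
s = +1 (L_d) phase and a negative ``J_dC`` favour s = -1 (L_o), matching
the partitioning preferences of the two anchor chemistries.  The bulk
transfer free energy of one anchor between uniform phases is then
``14 * J_a`` (the star flips from +7 to -7), which is how the couplings
are calibrated (see :mod:`lineactant.calibration`).
"""

from __future__ import annotations

import numpy as np

from .lattice import SpinField, TriangularLattice
from .params import ModelParams
from .tiles import Tile, anchor_field

__all__ = [
    "spin_energy",
    "anchor_energy",
    "total_energy",
    "exchange_delta_e",
]


def spin_energy(field: SpinField, j: float) -> float:
    """Bond term ``-J * sum_<ij> s_i s_j`` (each bond counted once)."""
    s = field.spins.astype(np.int64)
    # sum over directed pairs double counts every bond
    directed = np.sum(s[:, None] * s[field.lattice.neighbors])
    return -j * 0.5 * float(directed)


def anchor_energy(field: SpinField, tiles: list[Tile], params: ModelParams) -> float:
    """Anchor term ``-sum_a J_a * s̃_a``."""
    from .lattice import local_star_sum

    e = 0.0
    for tile in tiles:
        sites, kinds = tile.anchor_sites(field.lattice)
        for site, kind in zip(sites, kinds):
            e -= params.anchor_j(int(kind)) * local_star_sum(field, int(site))
    return e


def total_energy(field: SpinField, tiles: list[Tile], params: ModelParams) -> float:
    """Full Hamiltonian by direct summation over bonds and anchors."""
    return spin_energy(field, params.j) + anchor_energy(field, tiles, params)


def exchange_delta_e(
    field: SpinField,
    i: int,
    j_site: int,
    h: np.ndarray,
    params: ModelParams,
) -> float:
    """Energy change of swapping the (unlike) spins at neighbouring sites.

    Uses only the local bonds and the anchor field ``h`` of the two sites:

        dE = 2 J [ s_i (S_i - s_j) + s_j (S_j - s_i) ] + 2 (h_i s_i + h_j s_j)

    with ``S_x`` the neighbour sum of site ``x``.  Exact because the i-j
    bond product is invariant under the swap.
    """
    s = field.spins
    neigh = field.lattice.neighbors
    si = int(s[i])
    sj = int(s[j_site])
    if si == sj:
        return 0.0
    s_i_sum = int(s[neigh[i]].sum())
    s_j_sum = int(s[neigh[j_site]].sum())
    de_spin = 2.0 * params.j * (si * (s_i_sum - sj) + sj * (s_j_sum - si))
    de_anchor = 2.0 * (h[i] * si + h[j_site] * sj)
    return de_spin + de_anchor


def tile_move_delta_e(
    field: SpinField,
    tile: Tile,
    new_tile: Tile,
    params: ModelParams,
) -> float:
    """Anchor-energy change of a rigid tile move (spins untouched)."""
    from .lattice import local_star_sum

    de = 0.0
    old_sites, kinds = tile.anchor_sites(field.lattice)
    new_sites, _ = new_tile.anchor_sites(field.lattice)
    for o, n, kind in zip(old_sites, new_sites, kinds):
        j_a = params.anchor_j(int(kind))
        de -= j_a * (local_star_sum(field, int(n)) - local_star_sum(field, int(o)))
    return de


def rebuild_anchor_field(
    lattice: TriangularLattice, tiles: list[Tile], params: ModelParams
) -> np.ndarray:
    """Anchor field recomputed from scratch (oracle for incremental updates)."""
    return anchor_field(lattice, tiles, params.j_st, params.j_dc)
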