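"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lineactant.lattice import LatticeSpec, SpinField, TriangularLattice
from lineactant.params import ModelParams
from lineactant.tiles import ANCHOR_ST, AnchorLayout

# ---------------------------------------------------------------------------
# independent oracles (deliberately written from scratch, no package internals)
# ---------------------------------------------------------------------------

AXIAL_OFFSETS = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]


def oracle_neighbors(W: int, H: int, site: int) -> list[int]:
    """Six neighbours of a flat site index, recomputed from coordinates."""
    q, r = site % W, site // W
    return [((r + dr) % H) * W + (q + dq) % W for dq, dr in AXIAL_OFFSETS]


def oracle_total_energy(spins, W, H, anchor_sites, anchor_js, j):
    """Brute-force Hamiltonian: every bond once, every anchor star explicitly."""
    e = 0.0
    seen = set()
    for i in range(W * H):
        for n in oracle_neighbors(W, H, i):
            key = (min(i, n), max(i, n))
            if key not in seen:
                seen.add(key)
                e -= j * spins[i] * spins[n]
    for site, ja in zip(anchor_sites, anchor_js):
        star = spins[site] + sum(spins[n] for n in oracle_neighbors(W, H, site))
        e -= ja * star
    return e


def oracle_flood_fill(spins, W, H, phase):
    """Connected-component sizes of one phase via BFS on coordinates."""
    visited = [False] * (W * H)
    sizes = []
    for start in range(W * H):
        if visited[start] or spins[start] != phase:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            s = stack.pop()
            size += 1
            for n in oracle_neighbors(W, H, s):
                if not visited[n] and spins[n] == phase:
                    visited[n] = True
                    stack.append(n)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def oracle_unlike_bonds(spins, W, H):
    """Interface length by explicit bond enumeration."""
    count = 0
    for i in range(W * H):
        for n in oracle_neighbors(W, H, i):
            if n > i and spins[i] != spins[n]:
                count += 1
    return count


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spec8():
    return LatticeSpec(8, 8)


@pytest.fixture
def lattice8(spec8):
    return TriangularLattice(spec8)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def tiny_layout():
    """A small-footprint 6x layout that fits comfortably on a 12x12 box."""
    return AnchorLayout.design("6x", nm_per_site=12.0, width_nm=24.0, delta_nm=12.0)


@pytest.fixture
def coarse_layout():
    """The 12x design at the coarse 4 nm/site resolution (22 x 5 sites)."""
    return AnchorLayout.design("12x", nm_per_site=4.0)


def random_field(lattice: TriangularLattice, p_up: float, rng) -> SpinField:
    spins = np.where(rng.random(lattice.n_sites) < p_up, 1, -1).astype(np.int8)
    return SpinField(lattice, spins)
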