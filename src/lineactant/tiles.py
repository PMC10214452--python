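"""Rigid tile inclusions with amphiphilic anchor points.

A tile is a rigid rectangular DNA-origami plate occupying a block of
lattice sites.  Two parallel rows of anchors sit on opposite halves of the
footprint: single-tocopherol (sT) anchors prefer the L_d phase (s = +1),
double-cholesterol (dC) anchors prefer L_o (s = -1).  Each anchor couples
to the star sum s̃ of its host site and the six neighbours through a
coupling constant J_sT or J_dC (see :mod:`lineactant.energy`).

Designs ``6x``, ``12x`` and ``24x`` carry 6, 12 or 24 anchors of each
type.  The default geometry maps the ~90 nm long tile edge onto 45 sites
at 2 nm per site, with a 10-site (20 nm) short edge and an anchor-row
separation of 16 nm, wider than the interface width xi ~ 8 nm so that
each anchor set can sit in its preferred phase when the tile straddles a
domain boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import (
    ConfigurationError,
    LatticeSpec,
    TriangularLattice,
    rotate_offset,
)

__all__ = [
    "ANCHOR_ST",
    "ANCHOR_DC",
    "Anchor",
    "AnchorLayout",
    "Tile",
    "JammingError",
    "place_tiles",
    "anchor_field",
    "occupancy_map",
]

ANCHOR_ST = 0  #: single-tocopherol anchor; prefers s = +1 (L_d)
ANCHOR_DC = 1  #: double-cholesterol anchor; prefers s = -1 (L_o)

#: spin value each anchor type is happiest in
PREFERRED_SPIN = {ANCHOR_ST: 1, ANCHOR_DC: -1}

DESIGN_ANCHOR_COUNTS = {"6x": 6, "12x": 12, "24x": 24}


class JammingError(RuntimeError):
    """Random sequential tile insertion failed to reach the target coverage."""


@dataclass(frozen=True)
class Anchor:
    """One anchor point: axial offset from the tile origin plus its type."""

    dq: int
    dr: int
    kind: int  # ANCHOR_ST or ANCHOR_DC


@dataclass(frozen=True)
class AnchorLayout:
    """Tile footprint and anchor arrangement for one design.

    ``footprint`` is the (length, width) of the unrotated block in sites;
    offsets run over ``0 <= dq < length``, ``0 <= dr < width``.
    """

    name: str
    footprint: tuple[int, int]
    anchors: tuple[Anchor, ...]
    nm_per_site: float = 2.0

    def __post_init__(self) -> None:
        n_st = sum(1 for a in self.anchors if a.kind == ANCHOR_ST)
        n_dc = sum(1 for a in self.anchors if a.kind == ANCHOR_DC)
        if n_st != n_dc:
            raise ConfigurationError(
                f"layout {self.name!r}: unequal anchor sets ({n_st} sT, {n_dc} dC)"
            )
        fl, fw = self.footprint
        for a in self.anchors:
            if not (0 <= a.dq < fl and 0 <= a.dr < fw):
                raise ConfigurationError(
                    f"layout {self.name!r}: anchor {a} outside footprint {self.footprint}"
                )
        # the two sets must occupy opposite halves of the short axis
        st_rows = [a.dr for a in self.anchors if a.kind == ANCHOR_ST]
        dc_rows = [a.dr for a in self.anchors if a.kind == ANCHOR_DC]
        if st_rows and dc_rows and not (
            max(st_rows) < fw / 2 <= min(dc_rows)
            or max(dc_rows) < fw / 2 <= min(st_rows)
        ):
            raise ConfigurationError(
                f"layout {self.name!r}: anchor sets are not on opposite halves"
            )

    @property
    def n_anchors_per_set(self) -> int:
        return len(self.anchors) // 2

    @property
    def footprint_area(self) -> int:
        return self.footprint[0] * self.footprint[1]

    @classmethod
    def design(
        cls,
        name: str,
        nm_per_site: float = 2.0,
        length_nm: float = 90.0,
        width_nm: float = 20.0,
        delta_nm: float = 16.0,
    ) -> "AnchorLayout":
        """Build one of the named designs (``6x``, ``12x``, ``24x``).

        ``delta_nm`` is the separation between the sT and dC anchor rows;
        its nominal value is not critical provided it exceeds the
        interface width.
        """
        if name not in DESIGN_ANCHOR_COUNTS:
            raise ConfigurationError(
                f"unknown design {name!r}; choose from {sorted(DESIGN_ANCHOR_COUNTS)}"
            )
        n = DESIGN_ANCHOR_COUNTS[name]
        fl = max(2, int(round(length_nm / nm_per_site)))
        fw = max(2, int(round(width_nm / nm_per_site)))
        delta = int(round(delta_nm / nm_per_site))
        if delta < 1 or delta > fw - 1:
            raise ConfigurationError(
                f"anchor-row separation {delta_nm} nm does not fit a "
                f"{width_nm} nm wide tile at {nm_per_site} nm/site"
            )
        row_st = (fw - 1 - delta) // 2
        row_dc = row_st + delta
        # evenly spaced along the long edge; at coarse resolution two
        # neighbouring anchors may round onto the same site (couplings add)
        cols = np.round(np.linspace(0, fl - 1, n)).astype(int)
        anchors = tuple(
            [Anchor(int(c), row_st, ANCHOR_ST) for c in cols]
            + [Anchor(int(c), row_dc, ANCHOR_DC) for c in cols]
        )
        return cls(name=name, footprint=(fl, fw), anchors=anchors,
                   nm_per_site=nm_per_site)

    def rotated_footprint(self, k: int) -> np.ndarray:
        """Axial offsets of the footprint rotated by ``k`` * 60 degrees."""
        fl, fw = self.footprint
        dq, dr = np.meshgrid(np.arange(fl), np.arange(fw))
        out = np.empty((fl * fw, 2), dtype=np.int64)
        for i, (a, b) in enumerate(zip(dq.ravel(), dr.ravel())):
            out[i] = rotate_offset(int(a), int(b), k)
        return out

    def rotated_anchors(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Rotated anchor offsets ``(n, 2)`` and their types ``(n,)``."""
        offs = np.empty((len(self.anchors), 2), dtype=np.int64)
        kinds = np.empty(len(self.anchors), dtype=np.int64)
        for i, a in enumerate(self.anchors):
            offs[i] = rotate_offset(a.dq, a.dr, k)
            kinds[i] = a.kind
        return offs, kinds


@dataclass
class Tile:
    """A placed tile: origin site (axial), orientation in sixths of a turn."""

    q: int
    r: int
    orientation: int
    layout: AnchorLayout

    def footprint_sites(self, lattice: TriangularLattice) -> np.ndarray:
        offs = self.layout.rotated_footprint(self.orientation)
        return np.asarray(lattice.index(self.q + offs[:, 0], self.r + offs[:, 1]))

    def anchor_sites(self, lattice: TriangularLattice) -> tuple[np.ndarray, np.ndarray]:
        """Flat site indices of the anchors and their types."""
        offs, kinds = self.layout.rotated_anchors(self.orientation)
        sites = np.asarray(lattice.index(self.q + offs[:, 0], self.r + offs[:, 1]))
        return sites, kinds

    def moved(self, dq: int = 0, dr: int = 0, dk: int = 0) -> "Tile":
        return replace(
            self, q=self.q + dq, r=self.r + dr,
            orientation=(self.orientation + dk) % 6,
        )


def occupancy_map(lattice: TriangularLattice, tiles: list[Tile]) -> np.ndarray:
    """Per-site tile id (-1 where uncovered); raises on overlap."""
    occ = np.full(lattice.n_sites, -1, dtype=np.int32)
    for t_id, tile in enumerate(tiles):
        sites = tile.footprint_sites(lattice)
        if np.any(occ[sites] != -1):
            raise ConfigurationError(f"tile {t_id} overlaps a previous tile")
        occ[sites] = t_id
    return occ


def n_tiles_for_coverage(n_sites: int, sigma: float, layout: AnchorLayout) -> int:
    return int(round(sigma * n_sites / layout.footprint_area))


def place_tiles(
    lattice: TriangularLattice | LatticeSpec,
    layout: AnchorLayout,
    sigma: float,
    seed: int | np.random.SeedSequence = 0,
    rng: np.random.Generator | None = None,
    max_attempts_per_tile: int = 2000,
) -> list[Tile]:
    """Random sequential insertion of non-overlapping tiles at coverage sigma.

    Each attempt draws a uniform origin site and orientation; a proposal
    overlapping an already-placed tile is discarded.  Raises
    :class:`JammingError` (naming the achieved coverage) if a tile cannot
    be inserted within ``max_attempts_per_tile`` attempts.
    """
    if isinstance(lattice, LatticeSpec):
        lattice = TriangularLattice(lattice)
    if not (0.0 <= sigma < 1.0):
        raise ConfigurationError(f"coverage must be in [0, 1), got {sigma}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_target = n_tiles_for_coverage(lattice.n_sites, sigma, layout)
    if sigma > 0 and n_target == 0:
        raise ConfigurationError(
            f"coverage {sigma} is below one footprint "
            f"({layout.footprint_area} sites) on {lattice.n_sites} sites"
        )
    W, H = lattice.spec.width, lattice.spec.height
    occ = np.full(lattice.n_sites, -1, dtype=np.int32)
    tiles: list[Tile] = []
    for t_id in range(n_target):
        for _ in range(max_attempts_per_tile):
            q = int(rng.integers(W))
            r = int(rng.integers(H))
            k = int(rng.integers(6))
            tile = Tile(q, r, k, layout)
            sites = tile.footprint_sites(lattice)
            if sites.size != layout.footprint_area or np.unique(sites).size != sites.size:
                raise ConfigurationError(
                    "tile footprint self-overlaps under periodic wrap; "
                    "lattice too small for this layout"
                )
            if np.all(occ[sites] == -1):
                occ[sites] = t_id
                tiles.append(tile)
                break
        else:
            achieved = len(tiles) * layout.footprint_area / lattice.n_sites
            raise JammingError(
                f"placed {len(tiles)}/{n_target} tiles (coverage "
                f"{achieved:.3f} of requested {sigma:.3f}) before jamming"
            )
    return tiles


def anchor_field(
    lattice: TriangularLattice,
    tiles: list[Tile],
    j_st: float,
    j_dc: float,
) -> np.ndarray:
    """Per-site anchor field ``h``.

    ``h[i]`` is the sum of coupling constants J_a over all anchors whose
    7-site star contains site ``i``; the anchor part of the Hamiltonian is
    then ``-sum_i h[i] * s[i]``.  Maintained incrementally during runs and
    rebuildable from scratch here.
    """
    h = np.zeros(lattice.n_sites, dtype=np.float64)
    for tile in tiles:
        sites, kinds = tile.anchor_sites(lattice)
        for site, kind in zip(sites, kinds):
            j = j_st if kind == ANCHOR_ST else j_dc
            h[site] += j
            h[lattice.neighbors[site]] += j
    return h
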