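"""Trajectory observables: interface length, domains, line occupancy.

These quantify what the simulations are about: how much L_d/L_o boundary
survives (interface length ``L``), how much of it the tiles occupy (line
occupancy ``phi``), how many tiles sit at the line, and how many minority
domains remain (the signature of arrested coarsening).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .lattice import SpinField, TriangularLattice
from .tiles import PREFERRED_SPIN, Tile, occupancy_map

__all__ = [
    "DomainLabels",
    "ObservableSeries",
    "interface_length",
    "label_domains",
    "classify_tile_at_line",
    "line_occupancy",
    "tiles_at_line_fraction",
    "frame_observables",
    "aggregate_replicates",
    "domain_count_histogram",
]

#: default minimum domain size (sites); excludes single-spin thermal noise
DEFAULT_MIN_DOMAIN_SIZE = 10

#: favorable-contact fraction at or above which a tile counts as "at the line"
AT_LINE_THRESHOLD = 0.80


def interface_length(field: SpinField | np.ndarray, neighbors: np.ndarray | None = None) -> int:
    """Number of nearest-neighbour bonds joining unlike spins."""
    if isinstance(field, SpinField):
        spins, neighbors = field.spins, field.lattice.neighbors
    else:
        spins = np.asarray(field)
        if neighbors is None:
            raise ValueError("neighbors required when passing a raw spin array")
    unlike = spins[:, None] != spins[neighbors]
    return int(unlike.sum()) // 2


@dataclass
class DomainLabels:
    """Connected components of one phase under the 6-neighbour adjacency."""

    count: int                      # components of size >= min_size
    sizes: list[int]                # sizes of counted components (descending)
    small_sizes: list[int]          # excluded components (< min_size)
    labels: np.ndarray = dc_field(repr=False, default=None)  # per-site, -1 off-phase

    @property
    def total_sites(self) -> int:
        return int(sum(self.sizes) + sum(self.small_sizes))


def label_domains(
    field: SpinField | np.ndarray,
    phase: int,
    min_size: int = DEFAULT_MIN_DOMAIN_SIZE,
    neighbors: np.ndarray | None = None,
) -> DomainLabels:
    """Label connected domains of ``phase`` with periodic 6-neighbour adjacency.

    Components smaller than ``min_size`` are excluded from ``count`` but
    reported in ``small_sizes``.
    """
    if phase not in (-1, 1):
        raise ValueError(f"phase must be -1 or +1, got {phase}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    if isinstance(field, SpinField):
        spins, neighbors = field.spins, field.lattice.neighbors
    else:
        spins = np.asarray(field)
        if neighbors is None:
            raise ValueError("neighbors required when passing a raw spin array")
    n = spins.size
    mask = spins == phase
    idx = np.flatnonzero(mask)
    labels_full = np.full(n, -1, dtype=np.int64)
    if idx.size == 0:
        return DomainLabels(0, [], [], labels_full)
    compact = np.full(n, -1, dtype=np.int64)
    compact[idx] = np.arange(idx.size)
    rows = np.repeat(compact[idx], 6)
    cols = compact[neighbors[idx].ravel()]
    edge = cols >= 0
    graph = sparse.coo_matrix(
        (np.ones(edge.sum(), dtype=np.int8), (rows[edge], cols[edge])),
        shape=(idx.size, idx.size),
    )
    n_comp, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    labels_full[idx] = comp
    big = sorted((int(s) for s in sizes if s >= min_size), reverse=True)
    small = sorted((int(s) for s in sizes if s < min_size), reverse=True)
    return DomainLabels(len(big), big, small, labels_full)


def classify_tile_at_line(
    tile: Tile, field: SpinField, threshold: float = AT_LINE_THRESHOLD
) -> tuple[bool, float]:
    """Is the tile at the line-interface?

    Each anchor contributes 7 contacts (its star sites); a contact is
    favorable when the spin matches the anchor's preferred phase
    (sT -> +1, dC -> -1).  The tile is "at the line" when at least
    ``threshold`` (default 80%, inclusive) of all contacts are favorable.
    """
    spins = field.spins
    neigh = field.lattice.neighbors
    sites, kinds = tile.anchor_sites(field.lattice)
    favorable = 0
    total = 7 * len(sites)
    for site, kind in zip(sites, kinds):
        pref = PREFERRED_SPIN[int(kind)]
        favorable += int(spins[site] == pref)
        favorable += int(np.sum(spins[neigh[site]] == pref))
    frac = favorable / total
    return frac >= threshold, frac


def line_occupancy(
    field: SpinField,
    tiles: list[Tile],
    occ: np.ndarray | None = None,
    strategy: str = "any",
) -> float:
    """Fraction ``phi`` of interface bonds touching a tile footprint.

    A bond counts as occupied when at least one endpoint lies under a tile.
    ``strategy='any'`` (default) counts every tile; ``'at_line'`` counts
    only tiles currently classified as at the line.  Returns 0 when the
    interface length is zero.
    """
    if strategy not in ("any", "at_line"):
        raise ValueError(f"unknown occupancy strategy {strategy!r}")
    spins = field.spins
    neigh = field.lattice.neighbors
    if occ is None:
        occ = occupancy_map(field.lattice, tiles)
    if strategy == "at_line":
        keep = {
            t_id
            for t_id, tile in enumerate(tiles)
            if classify_tile_at_line(tile, field)[0]
        }
        covered = np.isin(occ, sorted(keep)) if keep else np.zeros_like(occ, bool)
    else:
        covered = occ >= 0
    i = np.repeat(np.arange(spins.size), 6)
    j = neigh.ravel()
    m = i < j
    i, j = i[m], j[m]
    unlike = spins[i] != spins[j]
    n_interface = int(unlike.sum())
    if n_interface == 0:
        return 0.0
    occupied = unlike & (covered[i] | covered[j])
    return float(occupied.sum()) / n_interface


def tiles_at_line_fraction(tiles: list[Tile], field: SpinField) -> float:
    """Fraction of tiles classified as at the line; NaN when no tiles."""
    if not tiles:
        return float("nan")
    at_line = sum(1 for t in tiles if classify_tile_at_line(t, field)[0])
    return at_line / len(tiles)


def frame_observables(
    field: SpinField,
    tiles: list[Tile],
    min_size: int = DEFAULT_MIN_DOMAIN_SIZE,
    occupancy_strategy: str = "any",
) -> dict:
    """All scalar observables of one configuration."""
    dom = label_domains(field, phase=-1, min_size=min_size)
    return {
        "L": interface_length(field),
        "phi": line_occupancy(field, tiles, strategy=occupancy_strategy),
        "frac_tiles_at_line": tiles_at_line_fraction(tiles, field),
        "n_domains_minority": dom.count,
        "n_domains_minority_unfiltered": dom.count + len(dom.small_sizes),
        "n_up": field.n_up,
        "n_down": field.n_down,
    }


@dataclass
class ObservableSeries:
    """Time series of observables for one trajectory."""

    frame: pd.DataFrame  # indexed by cycle; columns from frame_observables

    def __post_init__(self) -> None:
        for col in ("phi", "frac_tiles_at_line"):
            vals = self.frame[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")

    @property
    def cycles(self) -> np.ndarray:
        return self.frame.index.to_numpy()


def aggregate_replicates(series_list: list[ObservableSeries | pd.DataFrame]) -> pd.DataFrame:
    """Pointwise mean and standard error over aligned replicate series.

    Returns a frame indexed by cycle with ``<col>_mean`` and ``<col>_sem``
    columns.  SEM uses the sample standard deviation (ddof=1) over
    replicates divided by sqrt(n); for a single replicate it is 0 by
    convention.
    """
    frames = [s.frame if isinstance(s, ObservableSeries) else s for s in series_list]
    if not frames:
        raise ValueError("no series to aggregate")
    ref = frames[0].index
    for f in frames[1:]:
        if len(f.index) != len(ref) or not np.array_equal(f.index, ref):
            raise ValueError("replicate series are not aligned on the same cycles")
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])  # (n, T, C)
    n = stack.shape[0]
    with warnings.catch_warnings():
        # all-NaN slices (e.g. tile fractions of tileless runs) are fine
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        if n > 1:
            sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n)
        else:
            sem = np.zeros_like(mean)
    cols = list(frames[0].columns)
    out = {}
    for c_i, c in enumerate(cols):
        out[f"{c}_mean"] = mean[:, c_i]
        out[f"{c}_sem"] = sem[:, c_i]
    return pd.DataFrame(out, index=ref)


def domain_count_histogram(
    series_list: list[ObservableSeries | pd.DataFrame], cycles: list[int]
) -> pd.DataFrame:
    """Histogram of minority-domain counts across replicates at given cycles."""
    frames = [s.frame if isinstance(s, ObservableSeries) else s for s in series_list]
    rows = []
    for cyc in cycles:
        counts = []
        for f in frames:
            if cyc not in f.index:
                raise ValueError(f"cycle {cyc} not recorded in all replicates")
            counts.append(int(f.loc[cyc, "n_domains_minority"]))
        for value, freq in zip(*np.unique(counts, return_counts=True)):
            rows.append({"cycle": cyc, "domain_count": int(value), "frequency": int(freq)})
    return pd.DataFrame(rows, columns=["cycle", "domain_count", "frequency"])
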