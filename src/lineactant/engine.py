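"""Kawasaki spin-exchange dynamics with rigid tile moves.

The public entry points are :func:`run_quench` (one trajectory: random
high-temperature initial state evolved at the target couplings) and
:func:`run_replicates` (independent seeds, aggregated observables).
The inner loop is compiled (:mod:`lineactant._kernel`); the move-level
operations :func:`attempt_exchange` and :func:`attempt_tile_move` are
also provided in plain Python as the reference implementation of a
single Monte Carlo move, used for oracle checks and small studies.

Composition is conserved exactly: an exchange swaps two unlike spins,
a tile move never touches spins.  Mid-run deactivation (the simulation
analogue of fuel-driven anchor displacement) removes every tile at a
stated cycle and lets the spin dynamics continue.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _kernel
from .lattice import (
    ConfigurationError,
    LatticeSpec,
    SpinField,
    TriangularLattice,
    init_spins,
)
from .energy import exchange_delta_e, tile_move_delta_e
from .observables import ObservableSeries, aggregate_replicates, frame_observables
from .params import ModelParams, Schedule
from .tiles import (
    ANCHOR_ST,
    AnchorLayout,
    Tile,
    anchor_field,
    occupancy_map,
    place_tiles,
)
from .lattice import NEIGHBOR_OFFSETS

__all__ = [
    "MoveResult",
    "Trajectory",
    "ReplicateSet",
    "attempt_exchange",
    "attempt_tile_move",
    "deactivate_tiles",
    "run_quench",
    "run_replicates",
    "replicate_seeds",
]


# ---------------------------------------------------------------------------
# reference (uncompiled) move operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoveResult:
    accepted: bool
    delta_e: float


def attempt_exchange(
    field: SpinField,
    bond: tuple[int, int],
    h: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> MoveResult:
    """Attempt one Kawasaki exchange across ``bond`` (two lattice neighbours).

    Like-spin bonds leave the configuration unchanged (dE = 0).  Unlike
    spins are swapped with probability ``min(1, exp(-dE))``.
    """
    i, j = bond
    if j not in field.lattice.neighbors[i]:
        raise ValueError(f"sites {i} and {j} are not lattice neighbours")
    if field.spins[i] == field.spins[j]:
        return MoveResult(False, 0.0)
    de = exchange_delta_e(field, i, j, h, params)
    if de <= 0.0 or rng.random() < np.exp(-de):
        field.spins[i], field.spins[j] = field.spins[j], field.spins[i]
        return MoveResult(True, de)
    return MoveResult(False, de)


def attempt_tile_move(
    tiles: list[Tile],
    index: int,
    field: SpinField,
    params: ModelParams,
    rng: np.random.Generator,
    occ: np.ndarray | None = None,
) -> MoveResult:
    """Attempt one rigid-body tile move (translation or +/-60 rotation).

    The proposal is a translation by one random lattice vector or a
    rotation by +/-60 degrees about the tile origin, with equal
    probability.  Overlapping proposals are rejected outright; otherwise
    the anchor-energy change decides via Metropolis.  Spins are untouched.
    ``occ`` (per-site tile id) is updated in place when provided.
    """
    lattice = field.lattice
    if occ is None:
        occ = occupancy_map(lattice, tiles)
    tile = tiles[index]
    if rng.random() < 0.5:
        dq, dr = NEIGHBOR_OFFSETS[int(rng.integers(6))]
        proposal = tile.moved(dq=dq, dr=dr)
    else:
        proposal = tile.moved(dk=1 if rng.random() < 0.5 else -1)
    new_sites = proposal.footprint_sites(lattice)
    blockers = occ[new_sites]
    if np.any((blockers != -1) & (blockers != index)):
        return MoveResult(False, 0.0)
    de = tile_move_delta_e(field, tile, proposal, params)
    if de <= 0.0 or rng.random() < np.exp(-de):
        occ[tile.footprint_sites(lattice)] = -1
        occ[new_sites] = index
        W, H = lattice.spec.width, lattice.spec.height
        tiles[index] = Tile(proposal.q % W, proposal.r % H,
                            proposal.orientation, proposal.layout)
        return MoveResult(True, de)
    return MoveResult(False, de)


def deactivate_tiles(
    tiles: list[Tile], h: np.ndarray, occ: np.ndarray
) -> list[Tile]:
    """Remove every tile: clears the anchor field and occupancy in place."""
    tiles.clear()
    h[:] = 0.0
    occ[:] = -1
    return tiles


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """One simulated trajectory with recorded observables and final state."""

    params: ModelParams
    schedule: Schedule
    spec: LatticeSpec
    layout_name: str | None
    seed_entropy: int
    observables: ObservableSeries
    final_field: SpinField
    final_tiles: list[Tile]
    snapshots: np.ndarray | None = None       # (n_frames, N) int8
    tile_frames: np.ndarray | None = None     # (n_frames, nt, 3) int64
    meta: dict = dc_field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        return self.observables.frame

    @property
    def cycles(self) -> np.ndarray:
        return self.observables.cycles


@dataclass
class ReplicateSet:
    """Independent trajectories plus their pointwise aggregate."""

    trajectories: list[Trajectory]
    aggregate: pd.DataFrame
    base_seed: int

    def __len__(self) -> int:
        return len(self.trajectories)


def _layout_tables(layout: AnchorLayout, params: ModelParams):
    nf = layout.footprint_area
    na = len(layout.anchors)
    foot_dq = np.empty((6, nf), dtype=np.int64)
    foot_dr = np.empty((6, nf), dtype=np.int64)
    anch_dq = np.empty((6, na), dtype=np.int64)
    anch_dr = np.empty((6, na), dtype=np.int64)
    anch_j = np.empty(na, dtype=np.float64)
    for k in range(6):
        offs = layout.rotated_footprint(k)
        foot_dq[k] = offs[:, 0]
        foot_dr[k] = offs[:, 1]
        aoffs, kinds = layout.rotated_anchors(k)
        anch_dq[k] = aoffs[:, 0]
        anch_dr[k] = aoffs[:, 1]
        if k == 0:
            anch_j[:] = np.where(kinds == ANCHOR_ST, params.j_st, params.j_dc)
    return foot_dq, foot_dr, anch_dq, anch_dr, anch_j


def _empty_tables():
    z = np.zeros((6, 0), dtype=np.int64)
    return z, z.copy(), z.copy(), z.copy(), np.zeros(0, dtype=np.float64)


def _record_cycles(t_mc: int, stride: int) -> np.ndarray:
    if t_mc == 0:
        return np.zeros(0, dtype=np.int64)
    pts = list(range(stride, t_mc + 1, stride))
    if not pts or pts[-1] != t_mc:
        pts.append(t_mc)
    return np.asarray(pts, dtype=np.int64)


def replicate_seeds(base_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic independent seed sequences for ``n`` replicates."""
    return list(np.random.SeedSequence(base_seed).spawn(n))


def run_quench(
    spec: LatticeSpec,
    layout: AnchorLayout | None,
    params: ModelParams,
    schedule: Schedule,
    seed: int | np.random.SeedSequence | None = None,
    min_domain_size: int | None = None,
    occupancy_strategy: str = "any",
) -> Trajectory:
    """Simulate one quench: random initial state evolved at target couplings.

    The high-temperature preparation is emulated by the uniformly random
    initial spin and tile placement; the quench is instantaneous (no
    annealing ramp).  Three independent random streams are derived from
    the seed: spin initialisation, tile placement and dynamics, so a run
    whose tiles are deactivated at cycle 0 reproduces the tileless run
    with the same seed exactly.
    """
    from .observables import DEFAULT_MIN_DOMAIN_SIZE

    if min_domain_size is None:
        min_domain_size = DEFAULT_MIN_DOMAIN_SIZE
    if seed is None:
        seed = params.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    spin_ss, tile_ss, dyn_ss = ss.spawn(3)
    lattice = TriangularLattice(spec)
    W, H = spec.width, spec.height
    N = lattice.n_sites

    field = init_spins(lattice, params.ratio, rng=np.random.default_rng(spin_ss))
    if layout is not None and params.sigma > 0.0:
        tiles = place_tiles(lattice, layout, params.sigma,
                            rng=np.random.default_rng(tile_ss))
    else:
        tiles = []
    occ = occupancy_map(lattice, tiles)
    h = anchor_field(lattice, tiles, params.j_st, params.j_dc)

    if tiles:
        tables = _layout_tables(layout, params)
        tile_q = np.array([t.q % W for t in tiles], dtype=np.int64)
        tile_r = np.array([t.r % H for t in tiles], dtype=np.int64)
        tile_o = np.array([t.orientation for t in tiles], dtype=np.int64)
    else:
        tables = _empty_tables()
        tile_q = np.zeros(0, dtype=np.int64)
        tile_r = np.zeros(0, dtype=np.int64)
        tile_o = np.zeros(0, dtype=np.int64)
    foot_dq, foot_dr, anch_dq, anch_dr, anch_j = tables
    nbr = np.asarray(NEIGHBOR_OFFSETS, dtype=np.int64)
    rng_state = _kernel.seed_state(int(dyn_ss.generate_state(1, dtype=np.uint64)[0]))

    rec = _record_cycles(schedule.t_mc, schedule.stride)
    deact = schedule.deactivate_at
    nt = len(tiles)

    all_cycles = [0]
    snapshots = [field.spins.copy()]
    tile_frames = [np.stack([tile_q, tile_r, tile_o], axis=1)]
    tiles_alive_per_frame = [True]

    def _run(n_cycles: int, seg_rec: np.ndarray, with_tiles: bool):
        n_rec = seg_rec.shape[0]
        out_spins = np.empty((n_rec, N), dtype=np.int8)
        ntt = nt if with_tiles else 0
        out_tiles = np.zeros((n_rec, ntt, 3), dtype=np.int64)
        if with_tiles:
            args = (tile_q, tile_r, tile_o, foot_dq, foot_dr,
                    anch_dq, anch_dr, anch_j)
        else:
            e = _empty_tables()
            args = (np.zeros(0, dtype=np.int64),) * 3 + e[:4] + (e[4],)
        _kernel.run_segment(
            field.spins, lattice.neighbors, h, occ, *args,
            nbr[:, 0].copy(), nbr[:, 1].copy(),
            W, H, params.j, n_cycles, seg_rec, out_spins, out_tiles, rng_state,
        )
        for f_i in range(n_rec):
            snapshots.append(out_spins[f_i].copy())
            tile_frames.append(out_tiles[f_i].copy())
            tiles_alive_per_frame.append(with_tiles)

    if deact is None or not tiles:
        _run(schedule.t_mc, rec, with_tiles=bool(tiles))
        all_cycles.extend(rec.tolist())
    else:
        rec_a = rec[rec <= deact]
        rec_b = rec[rec > deact] - deact
        if deact > 0:
            _run(deact, rec_a, with_tiles=True)
            all_cycles.extend(rec_a.tolist())
        deactivate_tiles(tiles, h, occ)
        nt_after = 0
        _run(schedule.t_mc - deact, rec_b, with_tiles=False)
        all_cycles.extend((rec_b + deact).tolist())
        nt = nt_after

    # observables per recorded frame
    rows = []
    for spins_f, tile_f, alive in zip(snapshots, tile_frames, tiles_alive_per_frame):
        f_field = SpinField(lattice, spins_f)
        if alive and layout is not None and tile_f.shape[0] > 0:
            f_tiles = [Tile(int(q), int(r), int(o), layout) for q, r, o in tile_f]
        else:
            f_tiles = []
        rows.append(frame_observables(f_field, f_tiles,
                                      min_size=min_domain_size,
                                      occupancy_strategy=occupancy_strategy))
    obs = pd.DataFrame(rows, index=pd.Index(all_cycles, name="cycle"))

    final_tiles = (
        [Tile(int(q), int(r), int(o), layout) for q, r, o in
         np.stack([tile_q, tile_r, tile_o], axis=1)]
        if (tiles and (deact is None)) else list(tiles)
    )
    traj = Trajectory(
        params=params,
        schedule=schedule,
        spec=spec,
        layout_name=layout.name if layout is not None else None,
        seed_entropy=int(ss.entropy or 0),
        observables=ObservableSeries(obs),
        final_field=field,
        final_tiles=final_tiles,
        snapshots=np.stack(snapshots) if schedule.record_snapshots else None,
        tile_frames=None,
        meta={
            "seed_entropy": ss.entropy,
            "n_tiles": len(final_tiles),
            "deactivate_at": deact,
            # incrementally maintained state, kept for bookkeeping checks
            "final_h": h,
            "final_occ": occ,
        },
    )
    return traj


def run_replicates(
    spec: LatticeSpec,
    layout: AnchorLayout | None,
    params: ModelParams,
    schedule: Schedule,
    base_seed: int | None = None,
    **kwargs,
) -> ReplicateSet:
    """Run ``schedule.n_replicates`` independent trajectories and aggregate.

    Replicate seeds are spawned deterministically from the base seed; the
    aggregate holds pointwise mean and SEM of every observable.
    """
    if base_seed is None:
        base_seed = params.seed
    seeds = replicate_seeds(base_seed, schedule.n_replicates)
    trajectories = [
        run_quench(spec, layout, params, schedule, seed=s, **kwargs) for s in seeds
    ]
    agg = aggregate_replicates([t.observables for t in trajectories])
    return ReplicateSet(trajectories, agg, base_seed)
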