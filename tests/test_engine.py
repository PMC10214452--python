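"""Monte Carlo engine: conservation, determinism, bookkeeping, deactivation."""

import numpy as np
import pytest

from lineactant.energy import anchor_energy, total_energy
from lineactant.engine import (
    attempt_exchange,
    attempt_tile_move,
    deactivate_tiles,
    replicate_seeds,
    run_quench,
    run_replicates,
)
from lineactant.lattice import LatticeSpec, SpinField, TriangularLattice
from lineactant.params import ModelParams, Schedule
from lineactant.tiles import Tile, anchor_field, occupancy_map, place_tiles

from conftest import random_field


class TestReferenceMoves:
    def test_like_spin_bond_is_noop(self, lattice8, params, rng):
        f = SpinField(lattice8, np.ones(64, dtype=np.int8))
        h = np.zeros(64)
        res = attempt_exchange(f, (0, int(lattice8.neighbors[0][0])), h, params, rng)
        assert not res.accepted and res.delta_e == 0.0
        assert f.spins.all()

    def test_exchange_conserves_composition(self, lattice8, params, rng):
        f = random_field(lattice8, 0.6, rng)
        n_up, n_down = f.n_up, f.n_down
        h = np.zeros(64)
        for _ in range(500):
            i = int(rng.integers(64))
            j = int(lattice8.neighbors[i][rng.integers(6)])
            attempt_exchange(f, (i, j), h, params, rng)
        f.refresh_counts()
        assert (f.n_up, f.n_down) == (n_up, n_down)

    def test_non_neighbor_bond_rejected(self, lattice8, params, rng):
        f = random_field(lattice8, 0.5, rng)
        with pytest.raises(ValueError):
            attempt_exchange(f, (0, 30), np.zeros(64), params, rng)

    def test_overlapping_tile_proposal_rejected(self, tiny_layout, params):
        lat = TriangularLattice(LatticeSpec(12, 12))
        f = SpinField(lat, np.ones(144, dtype=np.int8))
        # two tiles side by side: any move of tile 0 toward tile 1 must refuse
        tiles = [Tile(0, 0, 0, tiny_layout), Tile(0, 2, 0, tiny_layout)]
        occ = occupancy_map(lat, tiles)
        rng = np.random.default_rng(0)
        before = [(t.q, t.r, t.orientation) for t in tiles]
        for _ in range(50):
            res = attempt_tile_move(tiles, 0, f, params, rng, occ)
            if res.accepted:
                # never lands on tile 1
                assert not np.any(
                    (occ[tiles[0].footprint_sites(lat)] != 0)
                    & (occ[tiles[0].footprint_sites(lat)] != -1)
                )
        assert [(t.q, t.r, t.orientation) for t in tiles][1] == before[1]

    def test_translation_on_uniform_field_always_accepted(self, tiny_layout, params):
        lat = TriangularLattice(LatticeSpec(12, 12))
        f = SpinField(lat, np.ones(144, dtype=np.int8))
        tiles = [Tile(4, 4, 0, tiny_layout)]
        occ = occupancy_map(lat, tiles)

        class TranslationOnly:
            """Forces the translation branch; direction then acceptance draw."""

            def __init__(self):
                self._r = np.random.default_rng(2)

            def random(self):
                return 0.0  # < 0.5 -> translation; also accepts any dE <= 0

            def integers(self, n):
                return self._r.integers(n)

        res = attempt_tile_move(tiles, 0, f, params, TranslationOnly(), occ)
        assert res.accepted and res.delta_e == pytest.approx(0.0)


class TestRunQuench:
    def test_zero_cycles_keeps_initial_state_only(self):
        traj = run_quench(LatticeSpec(16, 16), None, ModelParams(seed=4),
                          Schedule(t_mc=0, stride=10))
        assert list(traj.cycles) == [0]

    def test_composition_conserved_exactly(self):
        spec = LatticeSpec(20, 20)
        traj = run_quench(spec, None, ModelParams(seed=9),
                          Schedule(t_mc=2000, stride=500))
        assert (traj.frame["n_up"] == 240).all()
        assert (traj.frame["n_down"] == 160).all()

    def test_same_seed_identical_trajectories(self):
        spec = LatticeSpec(16, 16)
        a = run_quench(spec, None, ModelParams(seed=3), Schedule(t_mc=500, stride=100))
        b = run_quench(spec, None, ModelParams(seed=3), Schedule(t_mc=500, stride=100))
        assert np.array_equal(a.final_field.spins, b.final_field.spins)
        assert a.frame.equals(b.frame)

    def test_incremental_state_matches_rebuild_after_run(self, tiny_layout):
        """Anchor field and occupancy maintained across many accepted tile
        moves must equal a from-scratch rebuild from the final tiles."""
        spec = LatticeSpec(12, 12)
        p = ModelParams(sigma=0.2, seed=6)
        traj = run_quench(spec, tiny_layout, p, Schedule(t_mc=300, stride=300))
        lat = traj.final_field.lattice
        h_rebuilt = anchor_field(lat, traj.final_tiles, p.j_st, p.j_dc)
        occ_rebuilt = occupancy_map(lat, traj.final_tiles)
        assert np.allclose(traj.meta["final_h"], h_rebuilt, atol=1e-9)
        assert np.array_equal(traj.meta["final_occ"], occ_rebuilt)

    def test_snapshots_recorded_on_request(self):
        traj = run_quench(LatticeSpec(16, 16), None, ModelParams(seed=1),
                          Schedule(t_mc=100, stride=50, record_snapshots=True))
        assert traj.snapshots.shape == (3, 256)


class TestDeactivation:
    def test_anchor_term_zero_after_removal(self, tiny_layout):
        spec = LatticeSpec(12, 12)
        p = ModelParams(sigma=0.2, seed=2)
        traj = run_quench(spec, tiny_layout, p,
                          Schedule(t_mc=400, stride=100, deactivate_at=200))
        assert traj.final_tiles == []
        assert not traj.meta["final_h"].any()
        assert anchor_energy(traj.final_field, traj.final_tiles, p) == 0.0

    def test_removal_at_cycle_zero_equals_tileless_run(self, tiny_layout):
        spec = LatticeSpec(12, 12)
        sch = Schedule(t_mc=300, stride=100, deactivate_at=0)
        with_t = run_quench(spec, tiny_layout, ModelParams(sigma=0.2, seed=5), sch)
        without = run_quench(spec, None, ModelParams(sigma=0.0, seed=5),
                             Schedule(t_mc=300, stride=100))
        assert np.array_equal(with_t.final_field.spins, without.final_field.spins)

    def test_deactivate_tiles_clears_state(self, tiny_layout):
        lat = TriangularLattice(LatticeSpec(12, 12))
        tiles = place_tiles(lat, tiny_layout, 0.2, seed=1)
        h = anchor_field(lat, tiles, 0.136, -0.057)
        occ = occupancy_map(lat, tiles)
        deactivate_tiles(tiles, h, occ)
        assert tiles == [] and not h.any() and (occ == -1).all()


class TestReplicates:
    def test_single_replicate_aggregate(self):
        rs = run_replicates(LatticeSpec(16, 16), None, ModelParams(seed=8),
                            Schedule(t_mc=200, stride=100, n_replicates=1))
        traj = rs.trajectories[0]
        assert np.allclose(rs.aggregate["L_mean"], traj.frame["L"])
        assert (rs.aggregate["L_sem"] == 0).all()

    def test_replicate_seeds_distinct(self):
        seeds = replicate_seeds(123, 15)
        keys = {tuple(s.spawn_key) for s in seeds}
        assert len(keys) == 15

    def test_aggregate_is_arithmetic_mean(self):
        rs = run_replicates(LatticeSpec(16, 16), None, ModelParams(seed=8),
                            Schedule(t_mc=200, stride=100, n_replicates=3))
        manual = np.mean([t.frame["L"].to_numpy() for t in rs.trajectories], axis=0)
        assert np.allclose(rs.aggregate["L_mean"], manual)

    def test_replicates_differ(self):
        rs = run_replicates(LatticeSpec(16, 16), None, ModelParams(seed=8),
                            Schedule(t_mc=200, stride=200, n_replicates=2))
        a, b = rs.trajectories
        assert not np.array_equal(a.final_field.spins, b.final_field.spins)
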