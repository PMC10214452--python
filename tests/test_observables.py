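"""Interface length, domain labeling, line occupancy and aggregation."""

import numpy as np
import pandas as pd
import pytest

from lineactant.lattice import LatticeSpec, SpinField, TriangularLattice
from lineactant.observables import (
    aggregate_replicates,
    classify_tile_at_line,
    domain_count_histogram,
    interface_length,
    label_domains,
    line_occupancy,
    tiles_at_line_fraction,
)
from lineactant.synthetic import gen_lattice_fixture
from lineactant.tiles import ANCHOR_DC, ANCHOR_ST, Anchor, AnchorLayout, Tile

from conftest import oracle_flood_fill, oracle_unlike_bonds, random_field


class TestInterfaceLength:
    def test_uniform_field_zero(self, lattice8):
        assert interface_length(SpinField(lattice8, np.ones(64, dtype=np.int8))) == 0

    def test_single_minority_site(self, lattice8):
        spins = np.ones(64, dtype=np.int8)
        spins[27] = -1
        assert interface_length(SpinField(lattice8, spins)) == 6

    def test_stripe_has_two_straight_interfaces(self):
        # each row-aligned interface cuts 2 bonds per column on the
        # triangular lattice; a periodic stripe has two of them
        spec = LatticeSpec(12, 12)
        f = gen_lattice_fixture("stripe", spec, rows=4)
        expect = oracle_unlike_bonds(f.spins, 12, 12)
        assert interface_length(f) == expect == 4 * 12

    def test_random_field_expectation(self):
        # E[unlike fraction] = 2 p (1-p) for independent spins
        spec = LatticeSpec(40, 40)
        vals = [
            interface_length(
                gen_lattice_fixture("random", spec, p=0.6, seed=s)
            ) / (3 * 1600)
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(0.48, abs=0.01)


class TestLabelDomains:
    def test_single_disk(self):
        f = gen_lattice_fixture("disk", LatticeSpec(24, 24), radius=5)
        dom = label_domains(f, phase=-1, min_size=1)
        assert dom.count == 1

    def test_two_separated_disks(self):
        f = gen_lattice_fixture("two_disks", LatticeSpec(32, 32), radius=3)
        dom = label_domains(f, phase=-1, min_size=1)
        assert dom.count == 2

    def test_matches_flood_fill_oracle_on_random_fields(self):
        spec = LatticeSpec(10, 10)
        lat = TriangularLattice(spec)
        for seed in range(30):
            f = random_field(lat, 0.55, np.random.default_rng(seed))
            dom = label_domains(f, phase=-1, min_size=1)
            assert sorted(dom.sizes, reverse=True) == oracle_flood_fill(
                f.spins.tolist(), 10, 10, -1
            )

    def test_min_size_filter_reports_small_separately(self):
        spec = LatticeSpec(24, 24)
        f = gen_lattice_fixture("disk", spec, radius=4)
        f.spins[0] = -1  # far corner singleton
        f = SpinField(f.lattice, f.spins)
        dom = label_domains(f, phase=-1, min_size=10)
        assert dom.count == 1
        assert dom.small_sizes == [1]
        assert dom.total_sites == f.n_down

    def test_invalid_phase(self, lattice8):
        with pytest.raises(ValueError):
            label_domains(SpinField(lattice8, np.ones(64, dtype=np.int8)), phase=0)


def _two_anchor_layout():
    return AnchorLayout("pair", (3, 2),
                        (Anchor(1, 0, ANCHOR_ST), Anchor(1, 1, ANCHOR_DC)))


class TestTileAtLine:
    def test_tile_wholly_in_ld_is_half_favorable(self):
        lat = TriangularLattice(LatticeSpec(12, 12))
        f = SpinField(lat, np.ones(144, dtype=np.int8))
        at_line, frac = classify_tile_at_line(Tile(4, 4, 0, _two_anchor_layout()), f)
        assert frac == pytest.approx(0.5)
        assert not at_line

    def test_perfect_straddle_fully_favorable(self):
        spec = LatticeSpec(12, 12)
        f = gen_lattice_fixture("stripe", spec, rows=6)  # rows 0..5 are -1 (L_o)
        # dC star spans rows 0..2 (all L_o), sT star rows 6..8 (all L_d)
        lay = AnchorLayout("pair2", (3, 8),
                           (Anchor(1, 6, ANCHOR_ST), Anchor(1, 0, ANCHOR_DC)))
        at_line, frac = classify_tile_at_line(Tile(5, 1, 0, lay), f)
        assert frac == pytest.approx(1.0)
        assert at_line

    def test_exact_threshold_counts_as_at_line(self):
        # 5 anchors per set -> 70 contacts; all 35 sT contacts plus the full
        # stars of 3 dC anchors favorable gives exactly 56/70 = 0.80
        lat = TriangularLattice(LatticeSpec(16, 16))
        cols = [0, 3, 6, 9, 12]
        lay = AnchorLayout(
            "five", (15, 8),
            tuple([Anchor(c, 6, ANCHOR_ST) for c in cols]
                  + [Anchor(c, 0, ANCHOR_DC) for c in cols]),
        )
        tile = Tile(0, 1, 0, lay)
        spins = np.ones(256, dtype=np.int8)
        sites, kinds = tile.anchor_sites(lat)
        dc_sites = [int(s) for s, k in zip(sites, kinds) if k == ANCHOR_DC]
        for s in dc_sites[:3]:  # anchor stars 3 columns apart are disjoint
            spins[s] = -1
            spins[lat.neighbors[s]] = -1
        f = SpinField(lat, spins)
        at_line, frac = classify_tile_at_line(tile, f)
        assert frac == pytest.approx(0.80)
        assert at_line  # threshold is inclusive
        # one decorated star fewer drops below threshold
        spins[dc_sites[2]] = 1
        spins[lat.neighbors[dc_sites[2]]] = 1
        at_line2, frac2 = classify_tile_at_line(tile, SpinField(lat, spins))
        assert frac2 == pytest.approx(49 / 70)
        assert not at_line2


class TestLineOccupancy:
    def test_no_tiles_zero(self):
        f = gen_lattice_fixture("stripe", LatticeSpec(12, 12), rows=4)
        assert line_occupancy(f, []) == 0.0

    def test_uniform_field_zero_by_convention(self, lattice8):
        f = SpinField(lattice8, np.ones(64, dtype=np.int8))
        assert line_occupancy(f, []) == 0.0

    def test_interface_fully_under_one_tile(self):
        spec = LatticeSpec(12, 12)
        f = gen_lattice_fixture("stripe", spec, rows=4)
        # a periodic-width tile covering the whole band around both interfaces
        lay = AnchorLayout("wide", (12, 7),
                           (Anchor(0, 6, ANCHOR_ST), Anchor(0, 0, ANCHOR_DC)))
        tile = Tile(0, 10, 0, lay)  # rows 10,11,0..4: covers rows around 0 and 4
        assert line_occupancy(f, [tile]) == pytest.approx(1.0)

    def test_matches_bond_membership_oracle(self, coarse_layout):
        from lineactant.tiles import occupancy_map, place_tiles

        spec = LatticeSpec(24, 24)
        lat = TriangularLattice(spec)
        rng = np.random.default_rng(5)
        f = random_field(lat, 0.6, rng)
        tiles = place_tiles(lat, coarse_layout, 0.3, rng=rng)
        occ = occupancy_map(lat, tiles)
        covered = set(np.flatnonzero(occ >= 0).tolist())
        n_int, n_occ = 0, 0
        for i in range(576):
            for n in lat.neighbors[i]:
                if n > i and f.spins[i] != f.spins[n]:
                    n_int += 1
                    if i in covered or int(n) in covered:
                        n_occ += 1
        assert line_occupancy(f, tiles) == pytest.approx(n_occ / n_int)

    def test_at_line_strategy_is_bounded_by_any(self, coarse_layout):
        from lineactant.tiles import place_tiles

        spec = LatticeSpec(24, 24)
        lat = TriangularLattice(spec)
        rng = np.random.default_rng(6)
        f = random_field(lat, 0.6, rng)
        tiles = place_tiles(lat, coarse_layout, 0.3, rng=rng)
        assert line_occupancy(f, tiles, strategy="at_line") <= line_occupancy(
            f, tiles, strategy="any"
        )


class TestTilesAtLineFraction:
    def test_no_tiles_is_nan(self, lattice8):
        f = SpinField(lattice8, np.ones(64, dtype=np.int8))
        assert np.isnan(tiles_at_line_fraction([], f))

    def test_counts_fraction(self):
        spec = LatticeSpec(12, 12)
        f = gen_lattice_fixture("stripe", spec, rows=6)
        lay = AnchorLayout("pair2", (3, 8),
                           (Anchor(1, 6, ANCHOR_ST), Anchor(1, 0, ANCHOR_DC)))
        straddle = Tile(5, 1, 0, lay)         # fully favorable
        deep_a = Tile(0, 7, 0, _two_anchor_layout())   # in L_d
        deep_b = Tile(8, 7, 0, _two_anchor_layout())
        frac = tiles_at_line_fraction([straddle, deep_a, deep_b], f)
        assert frac == pytest.approx(1 / 3)


class TestAggregation:
    def _series(self, values):
        return pd.DataFrame({"L": values}, index=pd.Index([0, 1, 2], name="cycle"))

    def test_identical_replicates_zero_sem(self):
        s = self._series([5.0, 4.0, 3.0])
        agg = aggregate_replicates([s, s.copy(), s.copy()])
        assert (agg["L_sem"] == 0).all()

    def test_mean_of_two(self):
        agg = aggregate_replicates([self._series([1, 1, 1]), self._series([3, 3, 3])])
        assert (agg["L_mean"] == 2).all()

    def test_sem_matches_direct_formula(self, rng):
        data = rng.normal(size=(6, 3))
        frames = [self._series(row) for row in data]
        agg = aggregate_replicates(frames)
        expect = data.std(axis=0, ddof=1) / np.sqrt(6)
        assert np.allclose(agg["L_sem"], expect)

    def test_misaligned_series_rejected(self):
        a = self._series([1, 2, 3])
        b = pd.DataFrame({"L": [1, 2]}, index=pd.Index([0, 5], name="cycle"))
        with pytest.raises(ValueError):
            aggregate_replicates([a, b])

    def test_domain_count_histogram(self):
        frames = [
            pd.DataFrame({"n_domains_minority": [4, c]},
                         index=pd.Index([0, 10], name="cycle"))
            for c in (1, 1, 2)
        ]
        hist = domain_count_histogram(frames, cycles=[10])
        freq = dict(zip(hist["domain_count"], hist["frequency"]))
        assert freq == {1: 2, 2: 1}
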