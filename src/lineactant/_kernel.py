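"""Compiled inner loop of the Kawasaki / tile-move Monte Carlo.

One MC cycle is ``N = W*H`` attempted nearest-neighbour spin exchanges
(bonds drawn uniformly at random) followed by one attempted rigid-body
move per tile.  Exchanges use Metropolis acceptance ``min(1, exp(-dE))``
with energies in k_BT; tile moves are translations by one lattice vector
or rotations by +/-60 degrees, rejected outright on footprint overlap and
otherwise Metropolis-accepted on the anchor-energy change.

The per-site anchor field ``h`` (sum of J_a over anchors whose 7-site
star covers the site) is maintained incrementally so that an exchange
costs O(1); its correctness against a from-scratch rebuild is exercised
in the test suite.

Randomness is a xorshift128+ stream seeded via splitmix64 so that runs
are bit-reproducible for a given seed and resumable across kernel calls
(the two-word state is passed in and out).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


def seed_state(seed: int) -> np.ndarray:
    """Two-word xorshift128+ state from a 64-bit seed via splitmix64."""
    mask = (1 << 64) - 1
    state = np.empty(2, dtype=np.uint64)
    z = int(seed) & mask
    for k in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        state[k] = np.uint64(t ^ (t >> 31))
    if state[0] == 0 and state[1] == 0:  # degenerate state is invalid
        state[0] = _U64(1)
    return state


@njit(cache=True, inline="always")
def _rng_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    s1 ^= s1 >> _U64(17)
    s1 ^= s0 ^ (s0 >> _U64(26))
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _rng_float(state):
    return (_rng_next(state) >> _U64(11)) * _INV53


@njit(cache=True)
def run_segment(
    spins,          # int8[N], in/out
    neigh,          # int32[N, 6]
    h,              # float64[N], in/out
    occ,            # int32[N], in/out
    tile_q, tile_r, tile_o,   # int64[nt], in/out
    foot_dq, foot_dr,         # int64[6, nf]
    anch_dq, anch_dr,         # int64[6, na]
    anch_j,         # float64[na]
    nbr_dq, nbr_dr,  # int64[6] translation vectors
    W, H, J,
    n_cycles,
    record_cycles,  # int64[nrec], 1-based cycle numbers within this segment
    out_spins,      # int8[nrec, N]
    out_tiles,      # int64[nrec, nt, 3]
    rng_state,      # uint64[2], in/out
):
    N = W * H
    nt = tile_q.shape[0]
    nf = foot_dq.shape[1]
    na = anch_dq.shape[1]
    nrec = record_cycles.shape[0]

    # exp(-dE) lookup for exchanges away from any anchor field:
    # dE = 2J*m with integer m in [-14, 14]
    exp_spin = np.empty(29, dtype=np.float64)
    for m in range(-14, 15):
        exp_spin[m + 14] = np.exp(-2.0 * J * m)

    rec_i = 0
    for c in range(1, n_cycles + 1):
        # --- spin exchanges -------------------------------------------
        for _ in range(N):
            u = _rng_next(rng_state)
            i = int(u % _U64(N))
            d = int((u >> _U64(40)) % _U64(6))
            j_site = neigh[i, d]
            si = spins[i]
            sj = spins[j_site]
            if si == sj:
                continue
            s_i = 0
            s_j = 0
            for k in range(6):
                s_i += spins[neigh[i, k]]
                s_j += spins[neigh[j_site, k]]
            m = si * (s_i - sj) + sj * (s_j - si)
            hi = h[i]
            hj = h[j_site]
            if hi == 0.0 and hj == 0.0:
                if m <= 0:
                    accept = True
                else:
                    accept = _rng_float(rng_state) < exp_spin[m + 14]
            else:
                de = 2.0 * J * m + 2.0 * (hi * si + hj * sj)
                if de <= 0.0:
                    accept = True
                else:
                    accept = _rng_float(rng_state) < np.exp(-de)
            if accept:
                spins[i] = sj
                spins[j_site] = si

        # --- tile moves -----------------------------------------------
        for t in range(nt):
            u = _rng_next(rng_state)
            if (u & _U64(1)) == _U64(0):
                # translation by one lattice vector
                d = int((u >> _U64(1)) % _U64(6))
                nq = (tile_q[t] + nbr_dq[d]) % W
                nr = (tile_r[t] + nbr_dr[d]) % H
                no = tile_o[t]
            else:
                # rotation by +/-60 degrees about the origin site
                if (u & _U64(2)) == _U64(0):
                    no = (tile_o[t] + 1) % 6
                else:
                    no = (tile_o[t] + 5) % 6
                nq = tile_q[t]
                nr = tile_r[t]
            # hard-core overlap check on the proposed footprint
            ok = True
            for f in range(nf):
                q = (nq + foot_dq[no, f]) % W
                r = (nr + foot_dr[no, f]) % H
                o = occ[r * W + q]
                if o != -1 and o != t:
                    ok = False
                    break
            if not ok:
                continue
            # anchor-energy change: -sum_a J_a (star_new - star_old)
            oq = tile_q[t]
            orr = tile_r[t]
            oo = tile_o[t]
            de = 0.0
            for a in range(na):
                q = (oq + anch_dq[oo, a]) % W
                r = (orr + anch_dr[oo, a]) % H
                so = r * W + q
                q = (nq + anch_dq[no, a]) % W
                r = (nr + anch_dr[no, a]) % H
                sn = r * W + q
                star_o = spins[so]
                star_n = spins[sn]
                for k in range(6):
                    star_o += spins[neigh[so, k]]
                    star_n += spins[neigh[sn, k]]
                de -= anch_j[a] * (star_n - star_o)
            if de <= 0.0:
                accept = True
            else:
                accept = _rng_float(rng_state) < np.exp(-de)
            if not accept:
                continue
            # commit: occupancy, anchor field, tile record
            for f in range(nf):
                q = (oq + foot_dq[oo, f]) % W
                r = (orr + foot_dr[oo, f]) % H
                occ[r * W + q] = -1
            for f in range(nf):
                q = (nq + foot_dq[no, f]) % W
                r = (nr + foot_dr[no, f]) % H
                occ[r * W + q] = t
            for a in range(na):
                ja = anch_j[a]
                q = (oq + anch_dq[oo, a]) % W
                r = (orr + anch_dr[oo, a]) % H
                so = r * W + q
                h[so] -= ja
                for k in range(6):
                    h[neigh[so, k]] -= ja
                q = (nq + anch_dq[no, a]) % W
                r = (nr + anch_dr[no, a]) % H
                sn = r * W + q
                h[sn] += ja
                for k in range(6):
                    h[neigh[sn, k]] += ja
            tile_q[t] = nq
            tile_r[t] = nr
            tile_o[t] = no

        # --- recording -------------------------------------------------
        if rec_i < nrec and c == record_cycles[rec_i]:
            out_spins[rec_i, :] = spins
            for t in range(nt):
                out_tiles[rec_i, t, 0] = tile_q[t]
                out_tiles[rec_i, t, 1] = tile_r[t]
                out_tiles[rec_i, t, 2] = tile_o[t]
            rec_i += 1
    return rec_i
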