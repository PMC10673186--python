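"""Compiled Metropolis kernel for the lattice adhesion model.

The kernel owns its RNG (xorshift128+, seeded via splitmix64) so that runs
are bit-reproducible for a given seed and resumable across chunked calls:
all mutable state (separation field, Laplacian cache, ligand positions,
bond counter, RNG state) lives in arrays passed in by the driver.

The bending-energy change of a single-site displacement is evaluated from a
cached Laplacian field: displacing site j by u changes the Laplacian at j by
-4u and at its four nearest neighbours by +u, so

    dH_el = (kappa/2a^2) * (-8 u Lap_j + 2 u sum_nn Lap_k + 20 u^2)

which involves five cached values instead of a 13-site re-evaluation.
"""

from __future__ import annotations

import numba
import numpy as np

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@numba.njit(numba.uint64(numba.uint64), cache=True)
def _splitmix64(z):
    z = (z + numba.uint64(0x9E3779B97F4A7C15)) & numba.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> numba.uint64(30))) * numba.uint64(0xBF58476D1CE4E5B9)) & numba.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> numba.uint64(27))) * numba.uint64(0x94D049BB133111EB)) & numba.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> numba.uint64(31))


def seed_rng_state(seed: int) -> np.ndarray:
    """Initialize the two-word xorshift128+ state from an integer seed."""
    st = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
    s0 = _splitmix64(z)
    s1 = _splitmix64(s0)
    if s0 == 0 and s1 == 0:  # all-zero state is a fixed point
        s1 = np.uint64(1)
    st[0], st[1] = s0, s1
    return st


@numba.njit(numba.float64(numba.uint64[:]), inline="always", cache=True)
def _rand_u01(st):
    # xorshift128+; top 53 bits -> double in [0, 1)
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= (s1 << numba.uint64(23)) & numba.uint64(0xFFFFFFFFFFFFFFFF)
    st[1] = s1 ^ s0 ^ (s1 >> numba.uint64(18)) ^ (s0 >> numba.uint64(5))
    x = (st[1] + s0) & numba.uint64(0xFFFFFFFFFFFFFFFF)
    return numba.float64(x >> numba.uint64(11)) * _INV_2_53


@numba.njit(cache=True)
def run_chunk(
    l,  # float64[N] separation field (flat)
    lap,  # float64[N] cached Laplacian of l
    occ,  # int8[N] ligand occupancy
    lig,  # int64[NL] ligand -> flat site
    nbr,  # int64[N, 4] periodic nearest-neighbour table
    nb_box,  # int64[1] current bond count
    rng_state,  # uint64[2]
    cycle_start,  # int64: first global cycle of this chunk
    cycle_stop,  # int64: run cycles [cycle_start, cycle_stop)
    n_vert,  # attempts of type (i) per cycle (= vertical_sweeps * N)
    n_hop,  # attempts of type (ii) per cycle (= ligand_sweeps * NL)
    pref,  # kappa / (2 a^2)
    U,
    whalf,  # lwe / 2
    lb,
    delta,  # max vertical step (nm)
    hard_wall,  # bool
    sample_every,
    snapshot_every,
    ev_t,  # float64[cap] event times (cycles)
    ev_n,  # int32[cap] bond count after event
    ev_c,  # int8[cap] causing channel: 0 = vertical move, 1 = ligand hop
    ev_count0,  # events already recorded
    samp_nb,  # int64[n_samples]
    samp_sl,  # float64[n_samples] spatial sum of l at sample
    samp_sl2,  # float64[n_samples] spatial sum of l^2
    snap_counts,  # int64[n_snapshots]
    snap_flat,  # int64[n_snapshots * NL] complex positions, packed
    counters,  # int64[4]: vert_att, vert_acc, hop_att, hop_acc
):
    """Run MC cycles; returns (next_cycle, ev_count).

    Returns early (next_cycle < cycle_stop) if the event buffer cannot be
    guaranteed to hold a worst-case cycle; the driver grows it and resumes.
    """
    N = l.shape[0]
    NL = lig.shape[0]
    att_per_cycle = n_vert + n_hop
    inv_att = 1.0 / att_per_cycle
    ev_cap = ev_t.shape[0]
    ev_count = ev_count0
    nb = nb_box[0]

    for cycle in range(cycle_start, cycle_stop):
        if ev_cap - ev_count < att_per_cycle:
            nb_box[0] = nb
            return cycle, ev_count
        t0 = np.float64(cycle)

        for k in range(n_vert):
            site = np.int64(_rand_u01(rng_state) * N)
            u = (2.0 * _rand_u01(rng_state) - 1.0) * delta
            l_old = l[site]
            l_new = l_old + u
            counters[0] += 1
            if hard_wall and l_new <= 0.0:
                continue
            s_nn = (
                lap[nbr[site, 0]] + lap[nbr[site, 1]] + lap[nbr[site, 2]] + lap[nbr[site, 3]]
            )
            dE = pref * (u * (-8.0 * lap[site] + 2.0 * s_nn) + 20.0 * u * u)
            flip = 0
            if occ[site] == 1:
                in_old = abs(l_old - lb) < whalf
                in_new = abs(l_new - lb) < whalf
                if in_old and not in_new:
                    dE += U
                    flip = -1
                elif in_new and not in_old:
                    dE -= U
                    flip = 1
            if dE > 0.0 and _rand_u01(rng_state) >= np.exp(-dE):
                continue
            counters[1] += 1
            l[site] = l_new
            lap[site] -= 4.0 * u
            lap[nbr[site, 0]] += u
            lap[nbr[site, 1]] += u
            lap[nbr[site, 2]] += u
            lap[nbr[site, 3]] += u
            if flip != 0:
                nb += flip
                ev_t[ev_count] = t0 + k * inv_att
                ev_n[ev_count] = nb
                ev_c[ev_count] = 0
                ev_count += 1

        for k in range(n_hop):
            j = np.int64(_rand_u01(rng_state) * NL)
            src = lig[j]
            dst = nbr[src, np.int64(_rand_u01(rng_state) * 4)]
            counters[2] += 1
            if occ[dst] == 1:
                continue
            in_src = abs(l[src] - lb) < whalf
            in_dst = abs(l[dst] - lb) < whalf
            dE = 0.0
            if in_src and not in_dst:
                dE = U
            elif in_dst and not in_src:
                dE = -U
            if dE > 0.0 and _rand_u01(rng_state) >= np.exp(-dE):
                continue
            counters[3] += 1
            occ[src] = 0
            occ[dst] = 1
            lig[j] = dst
            dnb = np.int64(in_dst) - np.int64(in_src)
            if dnb != 0:
                nb += dnb
                ev_t[ev_count] = t0 + (n_vert + k) * inv_att
                ev_n[ev_count] = nb
                ev_c[ev_count] = 1
                ev_count += 1

        c1 = cycle + 1
        if sample_every > 0 and c1 % sample_every == 0:
            idx = c1 // sample_every - 1
            sl = 0.0
            sl2 = 0.0
            for s in range(N):
                sl += l[s]
                sl2 += l[s] * l[s]
            samp_nb[idx] = nb
            samp_sl[idx] = sl
            samp_sl2[idx] = sl2
        if snapshot_every > 0 and NL > 0 and c1 % snapshot_every == 0:
            idx = c1 // snapshot_every - 1
            cnt = 0
            base = idx * NL
            for j in range(NL):
                s = lig[j]
                if abs(l[s] - lb) < whalf:
                    snap_flat[base + cnt] = s
                    cnt += 1
            snap_counts[idx] = cnt

    nb_box[0] = nb
    return cycle_stop, ev_count
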