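"""Fused numba simulation loop.

A direct transcription of the scheduler's event loop over the reference
kernels in :mod:`plasmidlattice.dynamics`, compiled with numba for
production-scale grids. It consumes random draws from numpy's legacy
Mersenne-Twister stream in exactly the same order as the pure-Python
engine, so both engines produce bit-identical trajectories from the same
seed (asserted in the test suite).

All lattice state is passed as flat arrays; census output is written into
preallocated arrays. Cell-type codes: 0 empty, 1 recipient, 2 donor,
3 transconjugant, 4/5/6 adapted/non-adapted/donor segregants.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Moore-neighbourhood scan order; must match lattice.LOCAL_OFFSETS.
_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

STATUS_OK = 0
STATUS_EXTINCT = 1


@njit(cache=True)
def _empty_fraction(types, edge, x, y):
    empties = 0
    for dx in range(-3, 4):
        row = ((x + dx) % edge) * edge
        for dy in range(-3, 4):
            if types[row + (y + dy) % edge] == 0:
                empties += 1
    return empties / 49.0


@njit(cache=True)
def run_kernel(
    types,
    cost,
    countdown,
    occupied_sites,
    position_of,
    n_occ,
    type_counts,
    edge,
    psi_max,
    gamma_max,
    theta,
    theta1,
    theta2,
    b,
    c,
    adaptation_time,
    seg_prob,
    fill_threshold,
    cull_target,
    n_cull_events,
    mode_plasmid,
    loop_seed,
    census_counts,
    census_gen,
):
    """Run the asynchronous event loop until ``n_cull_events`` culls occurred.

    Mutates the state arrays in place and fills ``census_counts`` (one row
    of six type counts per fill event) and ``census_gen`` (cumulative
    log2-expansion generation clock). Returns ``(status, n_occ)``.
    """
    np.random.seed(loop_seed)
    offsets = _OFFSETS
    slot_buf = np.empty(8, dtype=np.int64)
    cycles = 0
    generations = 0.0
    cycle_start = n_occ

    while cycles < n_cull_events:
        if n_occ <= 0:
            return STATUS_EXTINCT, n_occ

        filled = n_occ >= fill_threshold
        birth = False
        if not filled:
            # ---- select a focal occupied site -------------------------
            u = np.random.random()
            idx = int(u * n_occ)
            if idx >= n_occ:
                idx = n_occ - 1
            s = occupied_sites[idx]
            x = s // edge
            y = s % edge

            # ---- growth attempt ---------------------------------------
            n_e = 0
            for i in range(8):
                nb = ((x + offsets[i, 0]) % edge) * edge + (y + offsets[i, 1]) % edge
                if types[nb] == 0:
                    slot_buf[n_e] = nb
                    n_e += 1
            if n_e > 0:
                C = _empty_fraction(types, edge, x, y)
                psi_eff = psi_max * (1.0 - cost[s])
                rate = psi_eff if C >= theta else psi_eff * C / theta
                if np.random.random() <= rate:
                    u2 = np.random.random()
                    k = int(u2 * n_e)
                    if k >= n_e:
                        k = n_e - 1
                    d = slot_buf[k]
                    tf = types[s]
                    if tf == 3 and countdown[s] > 0:
                        countdown[s] -= 1
                        if countdown[s] == 0:
                            cost[s] = c
                    dtype = tf
                    dcost = cost[s]
                    dcd = countdown[s]
                    if tf == 2 or tf == 3:
                        if np.random.random() <= seg_prob:
                            if tf == 2:
                                dtype = 6
                            elif countdown[s] == 0:
                                dtype = 4
                            else:
                                dtype = 5
                            dcost = 0.0
                            dcd = 0
                    types[d] = dtype
                    cost[d] = dcost
                    countdown[d] = dcd
                    occupied_sites[n_occ] = d
                    position_of[d] = n_occ
                    n_occ += 1
                    type_counts[dtype] += 1
                    type_counts[0] -= 1
                    birth = True
                    filled = n_occ >= fill_threshold

            # ---- conjugation attempt (skipped when the birth filled the
            #      grid: the census/cull takes precedence) ---------------
            if not filled:
                tf = types[s]
                if tf == 2 or tf == 3:
                    n_p = 0
                    for i in range(8):
                        nb = ((x + offsets[i, 0]) % edge) * edge + (y + offsets[i, 1]) % edge
                        tt = types[nb]
                        if tt == 1 or tt >= 4:
                            slot_buf[n_p] = nb
                            n_p += 1
                    if n_p > 0:
                        C = _empty_fraction(types, edge, x, y)
                        if C >= theta2:
                            g = gamma_max
                        elif C < theta1:
                            g = 0.0
                        else:
                            g = gamma_max * (C - theta1) / (theta2 - theta1)
                        if np.random.random() <= g:
                            u5 = np.random.random()
                            k = int(u5 * n_p)
                            if k >= n_p:
                                k = n_p - 1
                            t = slot_buf[k]
                            tt = types[t]
                            if tt == 6:
                                ntype, ncost, ncd = 2, c, 0
                            elif mode_plasmid:
                                if tf == 2:
                                    ntype, ncost, ncd = 3, b, adaptation_time
                                else:
                                    ntype, ncost, ncd = 3, cost[s], countdown[s]
                            elif tt == 4:
                                ntype, ncost, ncd = 3, c, 0
                            else:
                                ntype, ncost, ncd = 3, b, adaptation_time
                            type_counts[tt] -= 1
                            type_counts[ntype] += 1
                            types[t] = ntype
                            cost[t] = ncost
                            countdown[t] = ncd

        # ---- census + cull at the fill threshold ----------------------
        if filled:
            for j in range(6):
                census_counts[cycles, j] = type_counts[j + 1]
            generations += np.log2(n_occ / cycle_start)
            census_gen[cycles] = generations
            while n_occ > cull_target:
                u = np.random.random()
                j = int(u * n_occ)
                if j >= n_occ:
                    j = n_occ - 1
                srem = occupied_sites[j]
                last = occupied_sites[n_occ - 1]
                occupied_sites[j] = last
                position_of[last] = j
                position_of[srem] = -1
                n_occ -= 1
                type_counts[types[srem]] -= 1
                type_counts[0] += 1
                types[srem] = 0
                cost[srem] = 0.0
                countdown[srem] = 0
            cycles += 1
            cycle_start = n_occ

    return STATUS_OK, n_occ
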