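"""Numba kernels for the conserved-order-parameter Ising membrane model.

Hot loops only; all bookkeeping and validation live in
:mod:`phasecorr.ising_signaling`.  Randomness comes from an inline
xorshift64* generator keyed by the run seed, so trajectories are
bit-reproducible regardless of the numpy/numba RNG bridge.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# species codes (shared with ising_signaling)
BG = 0
RECEPTOR = 1
KINASE = 2
PHOSPHATASE = 3


@njit(inline="always", cache=True)
def _rng_next(state):
    """xorshift64* step; returns (new_state, uniform float64 in [0, 1))."""
    x = state
    x ^= (x >> np.uint64(12)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= (x >> np.uint64(27)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    out = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, (np.float64(out >> np.uint64(11))) * (1.0 / 9007199254740992.0)


@njit(inline="always", cache=True)
def _react_site(spin, species, phospho, i, j, p_phos, p_dephos, p_rbk, rbk, rng, L):
    """Apply reaction rules to the receptor at (i, j); returns rng state."""
    saw_kinase = False
    saw_rbk = False
    saw_phosphatase = False
    n_kin = 0
    n_rbk = 0
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ni = (i + di) % L
        nj = (j + dj) % L
        sp = species[ni, nj]
        if sp == KINASE:
            saw_kinase = True
            n_kin += 1
        elif sp == PHOSPHATASE:
            saw_phosphatase = True
        elif rbk and sp == RECEPTOR and phospho[ni, nj] == 1:
            saw_rbk = True
            n_rbk += 1
    # kinase / receptor-bound-kinase draws first, one draw per adjacency
    if saw_kinase:
        for _ in range(n_kin):
            rng, u = _rng_next(rng)
            if u < p_phos:
                phospho[i, j] = 1
    if saw_rbk:
        for _ in range(n_rbk):
            rng, u = _rng_next(rng)
            if u < p_rbk:
                phospho[i, j] = 1
    # phosphatase draw last so p_dephos = 1 dominates within one update
    if saw_phosphatase:
        rng, u = _rng_next(rng)
        if u < p_dephos:
            phospho[i, j] = 0
    return rng


@njit(cache=True)
def run_updates(
    spin,
    species,
    phospho,
    field_r,
    field_d,
    beta,
    n_proposals,
    local,
    react,
    p_phos,
    p_dephos,
    p_rbk,
    rbk,
    rng_state,
):
    """Propose ``n_proposals`` exchanges (Kawasaki dynamics); returns rng state.

    ``local``: partner is a random nearest neighbor (diffusive dynamics);
    otherwise two distinct random sites (non-local, fast equilibration).
    Spins, species identities, and phosphorylation flags move together, so
    all composition totals are conserved exactly.  When ``react`` is set,
    reaction rules fire on accepted moves for the two exchanged sites and
    any receptor in their 4-neighborhoods.
    """
    L = spin.shape[0]
    rng = rng_state
    up = np.empty(L, dtype=np.int64)
    dn = np.empty(L, dtype=np.int64)
    for i in range(L):
        up[i] = (i - 1) % L
        dn[i] = (i + 1) % L
    for _ in range(n_proposals):
        rng, u = _rng_next(rng)
        a = np.int64(u * L * L)
        ia = a // L
        ja = a % L
        adjacent = True
        if local:
            rng, u = _rng_next(rng)
            k = np.int64(u * 4)
            if k == 0:
                ib, jb = up[ia], ja
            elif k == 1:
                ib, jb = dn[ia], ja
            elif k == 2:
                ib, jb = ia, up[ja]
            else:
                ib, jb = ia, dn[ja]
        else:
            rng, u = _rng_next(rng)
            b = np.int64(u * L * L)
            ib = b // L
            jb = b % L
            if ia == ib and ja == jb:
                continue
            adjacent = (ia == ib and (jb == up[ja] or jb == dn[ja])) or (
                ja == jb and (ib == up[ia] or ib == dn[ia])
            )
        sa = spin[ia, ja]
        sb = spin[ib, jb]
        if sa == sb and species[ia, ja] == species[ib, jb]:
            continue  # exchange of identical sites: dH = 0, state unchanged
        ds = np.float64(sb - sa)
        nb_a = (
            np.int64(spin[up[ia], ja])
            + spin[dn[ia], ja]
            + spin[ia, up[ja]]
            + spin[ia, dn[ja]]
        )
        nb_b = (
            np.int64(spin[up[ib], jb])
            + spin[dn[ib], jb]
            + spin[ib, up[jb]]
            + spin[ib, dn[jb]]
        )
        # bond energy change for exchanging a and b; the shared a-b bond (if
        # adjacent) is unchanged, contributing the +ds^2 constant
        dh = -ds * nb_a + ds * nb_b
        if adjacent:
            dh += ds * ds
        # receptor field couples to receptor occupancy, domain field to spin
        if species[ia, ja] == RECEPTOR:
            dh += field_r[ia, ja] - field_r[ib, jb]
        if species[ib, jb] == RECEPTOR:
            dh += field_r[ib, jb] - field_r[ia, ja]
        dh += ds * (field_d[ib, jb] - field_d[ia, ja])
        if dh > 0:
            rng, u = _rng_next(rng)
            if u >= np.exp(-beta * dh):
                continue
        spin[ia, ja], spin[ib, jb] = sb, sa
        tmp_sp = species[ia, ja]
        species[ia, ja] = species[ib, jb]
        species[ib, jb] = tmp_sp
        tmp_ph = phospho[ia, ja]
        phospho[ia, ja] = phospho[ib, jb]
        phospho[ib, jb] = tmp_ph
        if react:
            # reactions for the moved sites and receptors in their neighborhoods
            for ii, jj in ((ia, ja), (ib, jb)):
                if species[ii, jj] == RECEPTOR:
                    rng = _react_site(
                        spin, species, phospho, ii, jj, p_phos, p_dephos, p_rbk, rbk, rng, L
                    )
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ni = (ii + di) % L
                    nj = (jj + dj) % L
                    if species[ni, nj] == RECEPTOR:
                        rng = _react_site(
                            spin, species, phospho, ni, nj, p_phos, p_dephos, p_rbk, rbk, rng, L
                        )
    return rng


@njit(cache=True)
def total_energy(spin, species, field_r, field_d):
    """Hamiltonian: H = -sum_<ij> S_i S_j - sum_i R_i Phi^R_i - sum_i S_i Phi^D_i."""
    L = spin.shape[0]
    e = 0.0
    for i in range(L):
        for j in range(L):
            s = spin[i, j]
            e -= s * spin[(i + 1) % L, j]  # each bond counted once
            e -= s * spin[i, (j + 1) % L]
            if species[i, j] == RECEPTOR:
                e -= field_r[i, j]
            e -= s * field_d[i, j]
    return e


@njit(cache=True)
def run_single_flip(spin, beta, n_flips, rng_state):
    """Non-conserved single-spin-flip Metropolis sampler (Tc validation only)."""
    L = spin.shape[0]
    rng = rng_state
    for _ in range(n_flips):
        rng, u = _rng_next(rng)
        a = np.int64(u * L * L)
        i = a // L
        j = a % L
        nb = (
            spin[(i - 1) % L, j]
            + spin[(i + 1) % L, j]
            + spin[i, (j - 1) % L]
            + spin[i, (j + 1) % L]
        )
        dh = 2.0 * spin[i, j] * nb
        if dh <= 0:
            spin[i, j] = -spin[i, j]
        else:
            rng, u = _rng_next(rng)
            if u < np.exp(-beta * dh):
                spin[i, j] = -spin[i, j]
    return rng
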