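"""Gillespie event loop over cell- and group-level channels.

Event channels, per group ``i`` (fixed ordering, also the column order of the
rate table): wild-type birth, mutant birth, cell death, emigration, group
fission, group extinction.  The community-wide total rate ``R`` is the sum
over groups and channels; waiting times are exponential with rate ``R`` and
one channel fires per step, proportionally to its rate.

Two implementations coexist on purpose:

* a pure-Python reference path (:func:`compute_rate_table`, :func:`step`,
  ``apply_*``) built directly on the rate functions of
  :mod:`fragmodes.model_core` — slow, transparent, used by the validation
  suite;
* a numba-compiled kernel (:func:`run` drives it in chunks) that mirrors the
  same rates on flat integer arrays and is what every experiment uses.  For
  speed it updates per-group rates incrementally (only the groups an event
  touched) and carries the extinction channel analytically as ``G * D``;
  a full rebuild happens after every group-level event and every couple of
  million steps, and the test suite asserts that the kernel's rate table
  equals the reference one exactly on randomly generated states.

Bookkeeping conventions: the state is sampled once per integer time unit (at
the last event before each boundary, since an event-driven clock does not
hit integers exactly); outputs are smoothed with a 200-sample moving
average; steady state is declared when, over the last 200 smoothed points,
the RMS deviation of the total wild-type count is below 1% of its window
mean and that of the group count below 5%.  Runs that hit the unbounded-
growth guard (``N_total > 50 * K_total``), a wall-clock limit or ``t_max``
are flagged ``excluded``.
"""

from __future__ import annotations

import math
import time as _wallclock
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .fragmentation import FragmentationStrategy, fragment_group, validate_strategy
from .model_core import (
    CONSTANT_FORCED_FISSION,
    CommunityState,
    GroupState,
    ModelParams,
    death_rate,
    extinction_rate,
    fission_rate,
    migration_rate,
    mutant_birth_rate,
)
from .evolution import TraitGrid, group_mean_strategy, mutate_trait

__all__ = [
    "EventRateTable",
    "RunResult",
    "init_community",
    "compute_rate_table",
    "step",
    "apply_birth",
    "apply_migration",
    "apply_fission",
    "apply_extinction",
    "run",
    "moving_average",
    "steady_state_reached",
    "COUNTER_NAMES",
]

# -- termination reasons ----------------------------------------------------
REASON_STEADY = "steady_state"
REASON_EXTINCT = "extinct"
REASON_TMAX = "t_max"
REASON_UNBOUNDED = "unbounded_growth"
REASON_WALL = "wall_time"

_EXCLUDED_REASONS = {REASON_TMAX, REASON_UNBOUNDED, REASON_WALL}

# -- kernel status codes ----------------------------------------------------
_ST_TSTOP = 0
_ST_EXTINCT = 1
_ST_UNBOUNDED = 2
_ST_CAPACITY = 3
_ST_MAXEVENTS = 4
_ST_FROZEN = 5
_ST_SAMPLE_OVERFLOW = 6

# -- event counters ---------------------------------------------------------
COUNTER_NAMES = (
    "births_wt",
    "births_mut",
    "deaths",
    "migrations",
    "fissions",
    "extinctions",
    "extinction_cells",
    "offspring_groups",
    "events",
    "forced_fissions",
)
_C_BWT, _C_BMUT, _C_DEATH, _C_MIG, _C_FIS, _C_EXT, _C_EXTC, _C_OFF, _C_EV, _C_FF = range(10)


# ===========================================================================
# numba kernels
# ===========================================================================

@njit(cache=True)
def _tp_draw(lam, max_support):
    """One draw from Poisson(lam) renormalised on {1..max_support}."""
    if max_support <= 1:
        return 1
    M = max_support
    logl = math.log(lam)
    w = np.empty(M)
    best = -1.0e300
    lg = 0.0
    for k in range(1, M + 1):
        lg += math.log(k)
        v = k * logl - lg
        w[k - 1] = v
        if v > best:
            best = v
    tot = 0.0
    for k in range(M):
        w[k] = math.exp(w[k] - best)
        tot += w[k]
    u = np.random.random() * tot
    acc = 0.0
    for k in range(M):
        acc += w[k]
        if u <= acc:
            return k + 1
    return M


@njit(cache=True)
def _pick_bin(row, total):
    """Index into a count vector, chosen with probability count/total."""
    u = np.random.random() * total
    acc = 0.0
    for b in range(row.shape[0]):
        acc += row[b]
        if u < acc:
            return b
    for b in range(row.shape[0] - 1, -1, -1):
        if row[b] > 0:
            return b
    return 0


@njit(cache=True)
def _copy_group(counts, nwt, nmut, Ng, src, dst):
    m = counts.shape[1]
    B = counts.shape[3]
    for j in range(m):
        for tt in range(2):
            for b in range(B):
                counts[dst, j, tt, b] = counts[src, j, tt, b]
        nwt[dst, j] = nwt[src, j]
        nmut[dst, j] = nmut[src, j]
    Ng[dst] = Ng[src]


@njit(cache=True)
def _refresh_aggregates(counts, nwt, nmut, Ng, g):
    m = counts.shape[1]
    B = counts.shape[3]
    tot = 0
    for j in range(m):
        w = 0
        mm = 0
        for b in range(B):
            w += counts[g, j, 0, b]
            mm += counts[g, j, 1, b]
        nwt[g, j] = w
        nmut[g, j] = mm
        tot += w + mm
    Ng[g] = tot
    return tot


@njit(cache=True)
def _mean_strategy(counts, Ng, g, bin_s, bin_n):
    """Count-weighted mean (s, n) of a group's cells, projected along n
    into the closed triangle."""
    m = counts.shape[1]
    B = counts.shape[3]
    ssum = 0.0
    nsum = 0.0
    for j in range(m):
        for tt in range(2):
            for b in range(B):
                c = counts[g, j, tt, b]
                if c > 0:
                    ssum += c * bin_s[b]
                    nsum += c * bin_n[b]
    s_ = ssum / Ng[g]
    n_ = nsum / Ng[g]
    if n_ < s_:
        n_ = s_
    if n_ > 1.0 - s_:
        n_ = 1.0 - s_
    return s_, n_


@njit(cache=True)
def _do_fission(counts, nwt, nmut, Ng, G, g, s_, n_, counters):
    """Fragment group ``g`` in place; returns the new G, or -1 if the group
    arrays are too small (caller must grow them and retry)."""
    cap = counts.shape[0]
    Ni = Ng[g]
    if G + Ni > cap:  # worst case: all-singleton offspring
        return -1
    m = counts.shape[1]
    B = counts.shape[3]
    C = m * 2 * B

    Noff = _tp_draw(n_ * Ni, Ni)
    Soff = _tp_draw(s_ * Ni, Noff)
    Goff = (Noff + Soff - 1) // Soff

    remflat = counts[g].copy().reshape(C)
    T = Ni
    for o in range(Goff):
        size_o = Soff if o < Goff - 1 else Noff - (Goff - 1) * Soff
        slot = G + o
        slv = counts[slot].reshape(C)
        kk = size_o
        Tcur = T
        for c in range(C):
            pc = remflat[c]
            x = 0
            if kk > 0 and pc > 0:
                nbad = Tcur - pc
                if nbad <= 0 or kk >= Tcur:
                    x = kk if kk < pc else pc
                else:
                    x = np.random.hypergeometric(pc, nbad, kk)
            slv[c] = x
            remflat[c] = pc - x
            kk -= x
            Tcur -= pc
        T -= size_o
        _refresh_aggregates(counts, nwt, nmut, Ng, slot)

    pv = counts[g].reshape(C)
    for c in range(C):
        pv[c] = remflat[c]
    Np = _refresh_aggregates(counts, nwt, nmut, Ng, g)

    newG = G + Goff
    counters[_C_FIS] += 1
    counters[_C_OFF] += Goff
    if Np == 0:
        # every cell transmitted: relabel the last allocated part as parent
        _copy_group(counts, nwt, nmut, Ng, newG - 1, g)
        newG -= 1
        counters[_C_OFF] -= 1
    return newG


@njit(cache=True)
def _group_rates(counts, nwt, nmut, Ng, g, m, gamma, K_cells, B0, sigma, nu,
                 death_constant, many_groups, wtb, mub):
    """Channel rates of one group; species-resolved birth rates in wtb/mub."""
    N = Ng[g]
    bw = 0.0
    bm = 0.0
    if m == 1:
        b = nwt[g, 0] / N
        wtb[0] = (1.0 - gamma) * nwt[g, 0] * b
        mub[0] = nmut[g, 0] * b
        bw = wtb[0]
        bm = mub[0]
    else:
        coef = float(m) ** (m - 1)
        for j in range(m):
            prod = 1.0
            for k in range(m):
                if k != j:
                    prod *= nwt[g, k] / N
            b = coef * prod
            wtb[j] = (1.0 - gamma) * nwt[g, j] * b
            mub[j] = nmut[g, j] * b
            bw += wtb[j]
            bm += mub[j]
    d = (1.0 / K_cells) if death_constant else (N / K_cells)
    dg = N * d
    mg = N * nu if many_groups else 0.0
    fg = B0 + sigma * N / K_cells
    return bw, bm, dg, mg, fg


@njit(cache=True)
def _advance(counts, nwt, nmut, Ng, occ, G, t, next_sample,
             m, gamma, mu, K_cells, B0, sigma, K_total_inv, nu,
             death_constant, evolution, mu_s, mu_n, s_fixed, n_fixed,
             bin_s, bin_n, proj,
             t_stop, guard_N, max_events,
             samp_t, samp_G, samp_N, samp_wt, samp_mut, samp_sp,
             samp_s, samp_n,
             counters, seed):
    """Advance the community to ``t_stop`` (or an absorbing/guard state).

    Returns (G, t, next_sample, n_samples, status).
    """
    np.random.seed(seed)
    cap = counts.shape[0]
    B = counts.shape[3]
    rates_g = np.empty(cap)  # per-group local rates (all channels but extinction)
    wtb = np.empty(m)
    mub = np.empty(m)
    n_samples = 0
    events = 0
    status = _ST_TSTOP
    rebuild = True
    since_rebuild = 0
    R_local = 0.0
    N_total = 0
    for g in range(G):
        N_total += Ng[g]

    # forced-fission sweep (handles resumption after an array resize)
    if death_constant:
        g = 0
        while g < G:
            if Ng[g] >= K_cells:
                if evolution:
                    s_, n_ = _mean_strategy(counts, Ng, g, bin_s, bin_n)
                else:
                    s_ = s_fixed
                    n_ = n_fixed
                newG = _do_fission(counts, nwt, nmut, Ng, G, g, s_, n_, counters)
                if newG < 0:
                    return G, t, next_sample, n_samples, _ST_CAPACITY
                counters[_C_FF] += 1
                G = newG
            g += 1

    while True:
        if G == 0 or N_total == 0:
            status = _ST_EXTINCT
            break
        if N_total > guard_N:
            status = _ST_UNBOUNDED
            break
        D = N_total * K_total_inv

        if rebuild or since_rebuild >= 2_000_000:
            many = G > 1
            R_local = 0.0
            for g in range(G):
                bw, bm, dg, mg, fg = _group_rates(
                    counts, nwt, nmut, Ng, g, m, gamma, K_cells, B0, sigma,
                    nu, death_constant, many, wtb, mub)
                rates_g[g] = bw + bm + dg + mg + fg
                R_local += rates_g[g]
            rebuild = False
            since_rebuild = 0

        R = R_local + G * D
        if R <= 0.0:
            status = _ST_FROZEN
            break

        dt = np.random.exponential(1.0 / R)

        # emit the state at every integer sampling time crossed by dt
        while next_sample <= t + dt and next_sample <= t_stop:
            if n_samples >= samp_t.shape[0]:
                return G, t, next_sample, n_samples, _ST_SAMPLE_OVERFLOW
            samp_t[n_samples] = next_sample
            samp_G[n_samples] = G
            wtT = 0
            mutT = 0
            for j in range(m):
                samp_sp[n_samples, j] = 0
            for g2 in range(G):
                for j in range(m):
                    wtT += nwt[g2, j]
                    mutT += nmut[g2, j]
                    samp_sp[n_samples, j] += nwt[g2, j] + nmut[g2, j]
            samp_wt[n_samples] = wtT
            samp_mut[n_samples] = mutT
            samp_N[n_samples] = wtT + mutT
            if evolution:
                ssum = 0.0
                nsum = 0.0
                for b in range(B):
                    if occ[b] > 0:
                        ssum += occ[b] * bin_s[b]
                        nsum += occ[b] * bin_n[b]
                samp_s[n_samples] = ssum / (wtT + mutT)
                samp_n[n_samples] = nsum / (wtT + mutT)
            else:
                samp_s[n_samples] = s_fixed
                samp_n[n_samples] = n_fixed
            n_samples += 1
            next_sample += 1.0

        if t + dt >= t_stop:
            t = t_stop
            status = _ST_TSTOP
            break
        t += dt
        events += 1
        since_rebuild += 1
        counters[_C_EV] += 1

        u = np.random.random() * R
        ext_total = G * D
        if u < ext_total:
            # ---- group extinction (equal rate D for every group) ----
            g = int(u / D)
            if g >= G:
                g = G - 1
            counters[_C_EXT] += 1
            counters[_C_EXTC] += Ng[g]
            N_total -= Ng[g]
            for j in range(m):
                for tt in range(2):
                    for b in range(B):
                        c = counts[g, j, tt, b]
                        if c > 0:
                            occ[b] -= c
            if g != G - 1:
                _copy_group(counts, nwt, nmut, Ng, G - 1, g)
            G -= 1
            rebuild = True
            if events >= max_events:
                status = _ST_MAXEVENTS
                break
            continue

        u -= ext_total
        g = G - 1
        acc = 0.0
        for gg in range(G):
            acc += rates_g[gg]
            if u < acc:
                g = gg
                break
        bw, bm, dg, mg, fg = _group_rates(
            counts, nwt, nmut, Ng, g, m, gamma, K_cells, B0, sigma, nu,
            death_constant, G > 1, wtb, mub)
        tot_g = bw + bm + dg + mg + fg
        u2 = np.random.random() * tot_g

        if u2 < bw + bm:
            # ---- cell birth ----
            parent_mut = u2 >= bw
            if parent_mut:
                u3 = u2 - bw
                j = m - 1
                acc = 0.0
                for jj in range(m):
                    acc += mub[jj]
                    if u3 < acc:
                        j = jj
                        break
                tt_parent = 1
                pool = nmut[g, j]
            else:
                u3 = u2
                j = m - 1
                acc = 0.0
                for jj in range(m):
                    acc += wtb[jj]
                    if u3 < acc:
                        j = jj
                        break
                tt_parent = 0
                pool = nwt[g, j]
            pb = 0
            if evolution:
                pb = _pick_bin(counts[g, j, tt_parent], pool)
            child_mut = parent_mut or (mu > 0.0 and np.random.random() < mu)
            cb = pb
            if evolution:
                ds = 0
                if mu_s > 0.0 and np.random.random() < mu_s:
                    ds = 1 if np.random.random() < 0.5 else -1
                dn = 0
                if mu_n > 0.0 and np.random.random() < mu_n:
                    dn = 1 if np.random.random() < 0.5 else -1
                if ds != 0 or dn != 0:
                    cb = proj[pb, ds + 1, dn + 1]
            if child_mut:
                counts[g, j, 1, cb] += 1
                nmut[g, j] += 1
                counters[_C_BMUT] += 1
            else:
                counts[g, j, 0, cb] += 1
                nwt[g, j] += 1
                counters[_C_BWT] += 1
            Ng[g] += 1
            N_total += 1
            occ[cb] += 1
            if death_constant and Ng[g] >= K_cells:
                # constant-death variant: reaching K_cells forces a fission
                if evolution:
                    s_, n_ = _mean_strategy(counts, Ng, g, bin_s, bin_n)
                else:
                    s_ = s_fixed
                    n_ = n_fixed
                newG = _do_fission(counts, nwt, nmut, Ng, G, g, s_, n_, counters)
                if newG < 0:
                    status = _ST_CAPACITY
                    break
                counters[_C_FF] += 1
                G = newG
                rebuild = True
            else:
                bw, bm, dg, mg, fg = _group_rates(
                    counts, nwt, nmut, Ng, g, m, gamma, K_cells, B0, sigma,
                    nu, death_constant, G > 1, wtb, mub)
                new_local = bw + bm + dg + mg + fg
                R_local += new_local - rates_g[g]
                rates_g[g] = new_local

        elif u2 < bw + bm + dg:
            # ---- cell death ----
            u3 = np.random.random() * Ng[g]
            j = m - 1
            tt = 1
            acc = 0.0
            done = False
            for jj in range(m):
                acc += nwt[g, jj]
                if u3 < acc:
                    j = jj
                    tt = 0
                    done = True
                    break
                acc += nmut[g, jj]
                if u3 < acc:
                    j = jj
                    tt = 1
                    done = True
                    break
            if not done:
                j = m - 1
                tt = 1 if nmut[g, j] > 0 else 0
            pool = nwt[g, j] if tt == 0 else nmut[g, j]
            bb = _pick_bin(counts[g, j, tt], pool) if evolution else 0
            counts[g, j, tt, bb] -= 1
            if tt == 0:
                nwt[g, j] -= 1
            else:
                nmut[g, j] -= 1
            Ng[g] -= 1
            N_total -= 1
            occ[bb] -= 1
            counters[_C_DEATH] += 1
            if Ng[g] == 0:
                if g != G - 1:
                    _copy_group(counts, nwt, nmut, Ng, G - 1, g)
                G -= 1
                rebuild = True
            else:
                bw, bm, dg, mg, fg = _group_rates(
                    counts, nwt, nmut, Ng, g, m, gamma, K_cells, B0, sigma,
                    nu, death_constant, G > 1, wtb, mub)
                new_local = bw + bm + dg + mg + fg
                R_local += new_local - rates_g[g]
                rates_g[g] = new_local

        elif u2 < bw + bm + dg + mg:
            # ---- migration: one cell joins a uniformly chosen other group
            u3 = np.random.random() * Ng[g]
            j = m - 1
            tt = 1
            done = False
            acc = 0.0
            for jj in range(m):
                acc += nwt[g, jj]
                if u3 < acc:
                    j = jj
                    tt = 0
                    done = True
                    break
                acc += nmut[g, jj]
                if u3 < acc:
                    j = jj
                    tt = 1
                    done = True
                    break
            if not done:
                j = m - 1
                tt = 1 if nmut[g, j] > 0 else 0
            pool = nwt[g, j] if tt == 0 else nmut[g, j]
            bb = _pick_bin(counts[g, j, tt], pool) if evolution else 0
            h = int(np.random.random() * (G - 1))
            if h >= g:
                h += 1
            counts[g, j, tt, bb] -= 1
            counts[h, j, tt, bb] += 1
            if tt == 0:
                nwt[g, j] -= 1
                nwt[h, j] += 1
            else:
                nmut[g, j] -= 1
                nmut[h, j] += 1
            Ng[g] -= 1
            Ng[h] += 1
            counters[_C_MIG] += 1
            if Ng[g] == 0:
                if g != G - 1:
                    _copy_group(counts, nwt, nmut, Ng, G - 1, g)
                G -= 1
                rebuild = True
            else:
                for gidx in (g, h):
                    bw, bm, dg, mg, fg = _group_rates(
                        counts, nwt, nmut, Ng, gidx, m, gamma, K_cells, B0,
                        sigma, nu, death_constant, G > 1, wtb, mub)
                    new_local = bw + bm + dg + mg + fg
                    R_local += new_local - rates_g[gidx]
                    rates_g[gidx] = new_local

        else:
            # ---- group fission ----
            if evolution:
                s_, n_ = _mean_strategy(counts, Ng, g, bin_s, bin_n)
            else:
                s_ = s_fixed
                n_ = n_fixed
            newG = _do_fission(counts, nwt, nmut, Ng, G, g, s_, n_, counters)
            if newG < 0:
                status = _ST_CAPACITY
                break
            G = newG
            rebuild = True

        if events >= max_events:
            status = _ST_MAXEVENTS
            break

    return G, t, next_sample, n_samples, status


# -- kernel test hooks ------------------------------------------------------

@njit(cache=True)
def _tp_counts_kernel(lam, sup, n, seed):
    np.random.seed(seed)
    out = np.zeros(sup + 1, dtype=np.int64)
    for _ in range(n):
        out[_tp_draw(lam, sup)] += 1
    return out


@njit(cache=True)
def _fission_sizes_kernel(N, s_, n_, n_draws, seed):
    np.random.seed(seed)
    out = np.zeros((n_draws, N), dtype=np.int64)
    counters = np.zeros(10, dtype=np.int64)
    for it in range(n_draws):
        counts = np.zeros((N + 1, 1, 2, 1), dtype=np.int64)
        nwt = np.zeros((N + 1, 1), dtype=np.int64)
        nmut = np.zeros((N + 1, 1), dtype=np.int64)
        Ng = np.zeros(N + 1, dtype=np.int64)
        counts[0, 0, 0, 0] = N
        nwt[0, 0] = N
        Ng[0] = N
        G = _do_fission(counts, nwt, nmut, Ng, 1, 0, s_, n_, counters)
        for g in range(G):
            out[it, g] = Ng[g]
    return out


def kernel_tp_counts(lam: float, max_support: int, n: int, seed: int) -> np.ndarray:
    """Histogram of ``n`` draws from the kernel's truncated-Poisson sampler
    (counts for values 0..max_support; index 0 is always zero)."""
    return np.asarray(_tp_counts_kernel(float(lam), int(max_support), int(n),
                                        int(seed)))


def kernel_fission_shapes(N: int, strategy: FragmentationStrategy,
                          n_draws: int, seed: int) -> list[tuple[int, ...]]:
    """Resulting group-size multisets of repeated kernel fission events on a
    pristine N-cell group (for comparison with the brute-force oracle)."""
    raw = _fission_sizes_kernel(int(N), float(strategy.s), float(strategy.n),
                                int(n_draws), int(seed))
    return [tuple(sorted(int(x) for x in row if x > 0)) for row in np.asarray(raw)]


# ===========================================================================
# array <-> CommunityState conversion
# ===========================================================================

class _SimState:
    """Flat-array mirror of a CommunityState used by the kernel."""

    def __init__(self, community: CommunityState, m: int, n_bins: int,
                 capacity: int | None = None):
        G = community.G
        cap = capacity or max(4 * G, 128)
        self.counts = np.zeros((cap, m, 2, n_bins), dtype=np.int64)
        self.nwt = np.zeros((cap, m), dtype=np.int64)
        self.nmut = np.zeros((cap, m), dtype=np.int64)
        self.Ng = np.zeros(cap, dtype=np.int64)
        for i, grp in enumerate(community.groups):
            if grp.bin_counts is not None:
                self.counts[i] = grp.bin_counts
            else:
                self.counts[i, :, 0, 0] = grp.wt_counts
                self.counts[i, :, 1, 0] = grp.mut_counts
            self.nwt[i] = grp.wt_counts
            self.nmut[i] = grp.mut_counts
            self.Ng[i] = grp.N
        self.G = G
        self.t = community.time
        self.occ = self.counts[:G].sum(axis=(0, 1, 2)).astype(np.int64)

    def grow(self) -> None:
        cap = 2 * self.counts.shape[0]
        for name in ("counts", "nwt", "nmut", "Ng"):
            old = getattr(self, name)
            new = np.zeros((cap,) + old.shape[1:], dtype=old.dtype)
            new[: old.shape[0]] = old
            setattr(self, name, new)

    def to_community(self, trait_resolved: bool) -> CommunityState:
        groups = []
        for i in range(self.G):
            if trait_resolved:
                groups.append(GroupState(self.nwt[i], self.nmut[i], self.counts[i]))
            else:
                groups.append(GroupState(self.nwt[i], self.nmut[i]))
        return CommunityState(groups, self.t)


# ===========================================================================
# initialization
# ===========================================================================

def init_community(
    params: ModelParams,
    n_groups: int = 100,
    init_cells: int | None = None,
    grid: TraitGrid | None = None,
    initial_bin: int | None = None,
) -> CommunityState:
    """Identical founder groups of K_cells/2 wild-type cells.

    Each group starts with ``init_cells`` (default ``K_cells // 2``)
    wild-type cells, split equally over the ``m`` species; remainder cells
    go to the lowest-index species (a deterministic reading of "equal within
    rounding errors").  In evolution mode every founder cell sits in
    ``initial_bin`` of the trait grid.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    m = params.m
    cells = params.K_cells // 2 if init_cells is None else int(init_cells)
    if cells < 1:
        raise ValueError("initial groups must contain at least one cell")
    base, rem = divmod(cells, m)
    wt = np.full(m, base, dtype=np.int64)
    wt[:rem] += 1
    mut = np.zeros(m, dtype=np.int64)

    bins = None
    if params.evolution_enabled:
        if grid is None or initial_bin is None:
            raise ValueError("evolution mode requires a TraitGrid and an initial bin")
        bins = np.zeros((m, 2, grid.n_bins), dtype=np.int64)
        bins[:, 0, initial_bin] = wt

    groups = [GroupState(wt, mut, None if bins is None else bins.copy())
              for _ in range(n_groups)]
    return CommunityState(groups, 0.0)


# ===========================================================================
# pure-Python reference path
# ===========================================================================

@dataclass
class EventRateTable:
    """Per-group channel rates plus the community total R."""

    wt_birth: np.ndarray
    mut_birth: np.ndarray
    death: np.ndarray
    migration: np.ndarray
    fission: np.ndarray
    extinction: np.ndarray

    @property
    def per_group(self) -> np.ndarray:
        return (self.wt_birth + self.mut_birth + self.death
                + self.migration + self.fission + self.extinction)

    @property
    def R(self) -> float:
        return float(self.per_group.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wt_birth": self.wt_birth, "mut_birth": self.mut_birth,
            "death": self.death, "migration": self.migration,
            "fission": self.fission, "extinction": self.extinction,
        })


def compute_rate_table(community: CommunityState, params: ModelParams) -> EventRateTable:
    """From-scratch rate table built on the model_core rate functions."""
    G = community.G
    m = params.m
    wt_b = np.zeros(G)
    mut_b = np.zeros(G)
    dth = np.zeros(G)
    mig = np.zeros(G)
    fis = np.zeros(G)
    D = extinction_rate(community, params)
    for i, grp in enumerate(community.groups):
        for j in range(m):
            bmut = mutant_birth_rate(grp, j, params)
            wt_b[i] += grp.wt_counts[j] * (1.0 - params.gamma) * bmut
            mut_b[i] += grp.mut_counts[j] * bmut
        dth[i] = grp.N * death_rate(grp, params)
        mig[i] = migration_rate(grp, params, n_groups=G)
        fis[i] = fission_rate(grp, params)
    return EventRateTable(wt_b, mut_b, dth, mig, fis, np.full(G, D))


def kernel_rate_table(community: CommunityState, params: ModelParams,
                      grid: TraitGrid | None = None) -> EventRateTable:
    """Rate table as the numba kernel computes it (for audits against
    :func:`compute_rate_table`)."""
    evolution = params.evolution_enabled
    n_bins = grid.n_bins if (evolution and grid is not None) else 1
    state = _SimState(community, params.m, n_bins)
    G = state.G
    death_constant = params.death_variant == CONSTANT_FORCED_FISSION
    wtb = np.empty(params.m)
    mub = np.empty(params.m)
    wt_b = np.zeros(G)
    mut_b = np.zeros(G)
    dth = np.zeros(G)
    mig = np.zeros(G)
    fis = np.zeros(G)
    for g in range(G):
        bw, bm, dg, mg, fg = _group_rates(
            state.counts, state.nwt, state.nmut, state.Ng, g, params.m,
            params.gamma, params.K_cells, params.B0, params.sigma, params.nu,
            death_constant, G > 1, wtb, mub)
        wt_b[g], mut_b[g], dth[g], mig[g], fis[g] = bw, bm, dg, mg, fg
    D = extinction_rate(community, params)
    return EventRateTable(wt_b, mut_b, dth, mig, fis, np.full(G, D))


def apply_birth(
    group: GroupState,
    j: int,
    parent_type: str,
    params: ModelParams,
    rng: np.random.Generator,
    grid: TraitGrid | None = None,
) -> str:
    """One birth in place; returns the offspring type ('wt' or 'mut').

    A wild-type parent produces a mutant with probability ``mu``; mutants
    always breed mutants (no back-mutation).  With a trait grid, the parent
    bin is drawn uniformly among the parent-category cells and the offspring
    bin may mutate to an adjacent one.
    """
    tt = 0 if parent_type == "wt" else 1
    child_mut = (tt == 1) or (rng.random() < params.mu)
    if group.bin_counts is not None:
        if grid is None:
            raise ValueError("trait-resolved group needs a TraitGrid")
        row = group.bin_counts[j, tt]
        pb = int(rng.choice(np.flatnonzero(row), p=row[row > 0] / row.sum()))
        cb = mutate_trait(pb, params.mu_s, params.mu_n, grid, rng)
        group.bin_counts[j, 1 if child_mut else 0, cb] += 1
    if child_mut:
        group.mut_counts[j] += 1
        return "mut"
    group.wt_counts[j] += 1
    return "wt"


def _draw_cell(group: GroupState, rng: np.random.Generator) -> tuple[int, int, int]:
    """(species, type, bin) of a uniformly chosen cell of the group."""
    m = group.m
    weights = np.concatenate([group.wt_counts, group.mut_counts]).astype(float)
    idx = int(rng.choice(2 * m, p=weights / weights.sum()))
    tt, j = divmod(idx, m)
    bb = 0
    if group.bin_counts is not None:
        row = group.bin_counts[j, tt]
        bb = int(rng.choice(np.flatnonzero(row), p=row[row > 0] / row.sum()))
    return j, tt, bb


def _remove_cell(group: GroupState, j: int, tt: int, bb: int) -> None:
    if tt == 0:
        group.wt_counts[j] -= 1
    else:
        group.mut_counts[j] -= 1
    if group.bin_counts is not None:
        group.bin_counts[j, tt, bb] -= 1


def apply_migration(
    community: CommunityState, source: int, rng: np.random.Generator
) -> None:
    """Move one uniformly chosen cell to a uniformly chosen *other* group."""
    if community.G < 2:
        raise ValueError("migration needs at least two groups")
    src = community.groups[source]
    j, tt, bb = _draw_cell(src, rng)
    dest = int(rng.integers(community.G - 1))
    if dest >= source:
        dest += 1
    dst = community.groups[dest]
    _remove_cell(src, j, tt, bb)
    if tt == 0:
        dst.wt_counts[j] += 1
    else:
        dst.mut_counts[j] += 1
    if dst.bin_counts is not None:
        dst.bin_counts[j, tt, bb] += 1
    if src.N == 0:
        community.groups.pop(source)


def apply_fission(
    community: CommunityState,
    index: int,
    rng: np.random.Generator,
    strategy: FragmentationStrategy | None = None,
    grid: TraitGrid | None = None,
) -> list[GroupState]:
    """Fragment a group; offspring are appended as new groups.

    In evolution mode (``strategy is None``) the group's strategy for the
    event is the count-weighted mean (s, n) of its member cells.
    """
    grp = community.groups[index]
    if strategy is None:
        if grid is None:
            raise ValueError("need either a fixed strategy or a TraitGrid")
        strategy = group_mean_strategy(grp, grid)
    parent, offspring, _ = fragment_group(grp, strategy, rng)
    community.groups[index] = parent
    community.groups.extend(offspring)
    return offspring


def apply_extinction(community: CommunityState, index: int) -> GroupState:
    """Remove a group and all its cells; returns the removed group."""
    return community.groups.pop(index)


def step(
    community: CommunityState,
    params: ModelParams,
    rng: np.random.Generator,
    strategy: FragmentationStrategy | None = None,
    grid: TraitGrid | None = None,
) -> tuple[float | None, str]:
    """One Gillespie step of the reference path (mutates the community).

    Returns (elapsed time, event label); ``(None, "absorbed")`` when the
    total rate is zero.  In the constant-death variant a group reaching
    ``K_cells`` cells after a birth fissions immediately.
    """
    table = compute_rate_table(community, params)
    R = table.R
    if R <= 0.0:
        return None, "absorbed"
    dt = float(rng.exponential(1.0 / R))
    community.time += dt

    per_group = table.per_group
    g = int(rng.choice(community.G, p=per_group / R))
    grp = community.groups[g]
    channels = np.array([
        table.wt_birth[g], table.mut_birth[g], table.death[g],
        table.migration[g], table.fission[g], table.extinction[g],
    ])
    ch = int(rng.choice(6, p=channels / channels.sum()))

    if ch in (0, 1):
        parent_type = "wt" if ch == 0 else "mut"
        m = params.m
        sp_rates = np.array([
            (grp.wt_counts[j] if ch == 0 else grp.mut_counts[j])
            * mutant_birth_rate(grp, j, params)
            for j in range(m)
        ])
        j = int(rng.choice(m, p=sp_rates / sp_rates.sum()))
        kind = apply_birth(grp, j, parent_type, params, rng, grid)
        label = f"birth_{kind}"
        if (params.death_variant == CONSTANT_FORCED_FISSION
                and grp.N >= params.K_cells):
            apply_fission(community, g, rng, strategy, grid)
            label += "+forced_fission"
    elif ch == 2:
        j, tt, bb = _draw_cell(grp, rng)
        _remove_cell(grp, j, tt, bb)
        if grp.N == 0:
            community.groups.pop(g)
        label = "death"
    elif ch == 3:
        apply_migration(community, g, rng)
        label = "migration"
    elif ch == 4:
        apply_fission(community, g, rng, strategy, grid)
        label = "fission"
    else:
        apply_extinction(community, g)
        label = "extinction"
    return dt, label


# ===========================================================================
# smoothing and steady-state detection
# ===========================================================================

def moving_average(x, window: int = 200) -> np.ndarray:
    """Trailing moving average; NaN until a full window is available."""
    return pd.Series(np.asarray(x, dtype=float)).rolling(window).mean().to_numpy()


def _window_ok(ma: np.ndarray, check_window: int, tol: float) -> bool:
    tail = ma[-check_window:]
    mean = tail.mean()
    if not mean > 0:
        return False
    rms = float(np.sqrt(np.mean((tail - mean) ** 2)))
    return rms < tol * mean


def steady_state_reached(
    wt_series,
    group_series,
    ma_window: int = 200,
    check_window: int = 200,
    wt_tol: float = 0.01,
    g_tol: float = 0.05,
) -> bool:
    """Operational steady state on the moving-averaged sampled series.

    Over the last ``check_window`` moving-average points, the RMS deviation
    of the total wild-type count from its window mean must be below
    ``wt_tol`` (1%) of that mean, and that of the group count below
    ``g_tol`` (5%).  Returns False when fewer than ``check_window`` smoothed
    points exist.
    """
    wt_ma = moving_average(wt_series, ma_window)
    g_ma = moving_average(group_series, ma_window)
    valid = ~np.isnan(wt_ma)
    if valid.sum() < check_window:
        return False
    return (_window_ok(wt_ma[valid], check_window, wt_tol)
            and _window_ok(g_ma[~np.isnan(g_ma)], check_window, g_tol))


# ===========================================================================
# the run driver
# ===========================================================================

@dataclass
class RunResult:
    """Trajectory and summary of a single simulation."""

    trajectory: pd.DataFrame
    reason: str
    excluded: bool
    counters: dict
    seed: int
    params: ModelParams
    strategy: FragmentationStrategy | None
    steady: dict | None
    final_community: CommunityState | None = None
    grid: TraitGrid | None = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "reason": self.reason,
            "excluded": self.excluded,
            "params": self.params.to_dict(),
            "strategy": None if self.strategy is None else
            {"s": self.strategy.s, "n": self.strategy.n},
            "steady": self.steady,
            "counters": self.counters,
        }


def _steady_values(traj: pd.DataFrame, ma_window: int, check_window: int) -> dict:
    out = {}
    for col, key in (("wt_total", "wt"), ("G", "G"),
                     ("N_total", "N_total"), ("mut_total", "mut")):
        ma = moving_average(traj[col].to_numpy(), ma_window)
        ma = ma[~np.isnan(ma)]
        out[key] = float(ma[-check_window:].mean()) if ma.size else float("nan")
    denom = out["wt"] + out["mut"]
    out["wt_fraction"] = out["wt"] / denom if denom > 0 else float("nan")
    return out


def run(
    params: ModelParams,
    strategy: FragmentationStrategy | None = None,
    *,
    community: CommunityState | None = None,
    n_groups: int = 100,
    init_cells: int | None = None,
    seed: int = 0,
    t_max: float = 10_000.0,
    grid: TraitGrid | None = None,
    initial_bin: int | None = None,
    ma_window: int = 200,
    check_window: int = 200,
    wt_tol: float = 0.01,
    g_tol: float = 0.05,
    stop_on_steady: bool = True,
    chunk: float = 100.0,
    guard_factor: float = 50.0,
    max_wall: float | None = None,
) -> RunResult:
    """Simulate until steady state, extinction, a guard, or ``t_max``.

    A single integer ``seed`` fully determines the run.  The state is
    sampled at every integer time; the returned trajectory additionally
    carries ``ma_window``-point moving averages (``wt_ma``, ``G_ma``,
    ``N_ma``).  ``reason`` is one of ``steady_state``, ``extinct``,
    ``t_max``, ``unbounded_growth`` or ``wall_time``; the last three are
    flagged ``excluded`` (mirroring the exclusion of runs that neither
    equilibrate nor die).
    """
    evolution = params.evolution_enabled
    if evolution:
        if grid is None:
            raise ValueError("evolution mode requires a TraitGrid")
        if initial_bin is None and community is None:
            if strategy is None:
                raise ValueError("give an initial strategy or bin for evolution mode")
            initial_bin = grid.bin_of(strategy.s, strategy.n)
        n_bins = grid.n_bins
        bin_s, bin_n, proj = grid.bin_s, grid.bin_n, grid.proj
        s_fixed = n_fixed = float("nan")
    else:
        if strategy is None:
            raise ValueError("a fixed FragmentationStrategy is required")
        if not validate_strategy(strategy):
            raise ValueError(f"invalid strategy {strategy}")
        n_bins = 1
        bin_s = np.zeros(1)
        bin_n = np.zeros(1)
        proj = np.zeros((1, 3, 3), dtype=np.int64)
        s_fixed, n_fixed = float(strategy.s), float(strategy.n)

    if community is None:
        community = init_community(params, n_groups, init_cells, grid, initial_bin)
    state = _SimState(community, params.m, n_bins)

    master = np.random.Generator(np.random.PCG64(seed))
    counters = np.zeros(len(COUNTER_NAMES), dtype=np.int64)
    K_total_inv = 0.0 if not np.isfinite(params.K_total) else 1.0 / params.K_total
    guard_N = (np.iinfo(np.int64).max // 2 if not np.isfinite(params.K_total)
               else int(guard_factor * params.K_total))
    death_constant = params.death_variant == CONSTANT_FORCED_FISSION

    frames: list[pd.DataFrame] = []
    next_sample = float(math.ceil(state.t)) if state.t > 0 else 0.0
    reason = REASON_TMAX
    t_start_wall = _wallclock.monotonic()
    n_kept = 0

    while True:
        t_stop = min(state.t + chunk, t_max)
        cap_samp = int(t_stop - next_sample) + 3
        samp_t = np.empty(cap_samp)
        samp_G = np.empty(cap_samp, dtype=np.int64)
        samp_N = np.empty(cap_samp, dtype=np.int64)
        samp_wt = np.empty(cap_samp, dtype=np.int64)
        samp_mut = np.empty(cap_samp, dtype=np.int64)
        samp_sp = np.empty((cap_samp, params.m), dtype=np.int64)
        samp_s = np.empty(cap_samp)
        samp_n = np.empty(cap_samp)
        chunk_seed = int(master.integers(1, 2**31 - 1))

        (state.G, state.t, next_sample, n_new, status) = _advance(
            state.counts, state.nwt, state.nmut, state.Ng, state.occ,
            state.G, state.t, next_sample,
            params.m, params.gamma, params.mu, params.K_cells,
            params.B0, params.sigma, K_total_inv, params.nu,
            death_constant, evolution, params.mu_s, params.mu_n,
            s_fixed, n_fixed, bin_s, bin_n, proj,
            t_stop, guard_N, 100_000_000,
            samp_t, samp_G, samp_N, samp_wt, samp_mut, samp_sp,
            samp_s, samp_n, counters, chunk_seed,
        )

        if n_new:
            data = {"time": samp_t[:n_new], "G": samp_G[:n_new],
                    "N_total": samp_N[:n_new], "wt_total": samp_wt[:n_new],
                    "mut_total": samp_mut[:n_new]}
            for j in range(params.m):
                data[f"N_sp{j}"] = samp_sp[:n_new, j]
            data["mean_s"] = samp_s[:n_new]
            data["mean_n"] = samp_n[:n_new]
            frames.append(pd.DataFrame(data))
            n_kept += n_new

        if status == _ST_EXTINCT or status == _ST_FROZEN:
            reason = REASON_EXTINCT
            break
        if status == _ST_UNBOUNDED:
            reason = REASON_UNBOUNDED
            break
        if status == _ST_CAPACITY:
            state.grow()
            continue
        if status == _ST_MAXEVENTS:
            continue
        if status == _ST_SAMPLE_OVERFLOW:  # pragma: no cover - sizing bug guard
            raise RuntimeError("sample buffer overflow")

        # status == _ST_TSTOP
        if state.t >= t_max:
            reason = REASON_TMAX
            break
        if max_wall is not None and _wallclock.monotonic() - t_start_wall > max_wall:
            reason = REASON_WALL
            break
        if stop_on_steady and n_kept >= ma_window + check_window - 1:
            traj_so_far = pd.concat(frames, ignore_index=True)
            if steady_state_reached(
                traj_so_far["wt_total"], traj_so_far["G"],
                ma_window, check_window, wt_tol, g_tol,
            ):
                reason = REASON_STEADY
                break

    traj = (pd.concat(frames, ignore_index=True) if frames else
            pd.DataFrame(columns=["time", "G", "N_total", "wt_total", "mut_total",
                                  "mean_s", "mean_n"]))
    if len(traj):
        traj["wt_ma"] = moving_average(traj["wt_total"].to_numpy(), ma_window)
        traj["G_ma"] = moving_average(traj["G"].to_numpy(), ma_window)
        traj["N_ma"] = moving_average(traj["N_total"].to_numpy(), ma_window)

    steady = None
    if reason == REASON_STEADY:
        steady = _steady_values(traj, ma_window, check_window)

    return RunResult(
        trajectory=traj,
        reason=reason,
        excluded=reason in _EXCLUDED_REASONS,
        counters={name: int(c) for name, c in zip(COUNTER_NAMES, counters)},
        seed=seed,
        params=params,
        strategy=strategy,
        steady=steady,
        final_community=state.to_community(evolution),
        grid=grid,
    )
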