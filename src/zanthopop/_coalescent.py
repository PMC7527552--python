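"""Low-level structured-coalescent simulation kernels.

The kernels simulate genealogies of samples drawn from multiple demes under a
piecewise demography: per-epoch diploid sizes with optional exponential
growth, a backward-in-time migration matrix per epoch, and lineage-relocation
("join") events at epoch boundaries.  Times are in generations, sizes in
diploids, so the pairwise coalescence rate within a deme of size N is
1/(2N) per pair per generation.

Two kernels are provided:

- ``sim_branch_sfs`` accumulates branch lengths indexed by the joint
  descendant-count configuration of each branch, yielding a Monte-Carlo
  estimate of the expected (unfolded, joint) site-frequency spectrum in
  branch-length units.
- ``sim_trees`` records full genealogies (parent pointers + node times) so
  that mutations can be placed on branches to produce genotypes.

Everything here is deliberately free of Python objects so numba can compile
it; the public API lives in :mod:`zanthopop.simulate`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_branch_sfs", "sim_trees"]

_INF = np.inf


@njit(cache=True)
def _coal_wait(k, n0, growth, s, t_epoch, u):
    """Waiting time from age ``s`` to the next coalescence among ``k`` lineages.

    Deme size at age t is ``n0 * exp(-growth * (t - t_epoch))`` (``growth`` is
    the forward-time exponential rate; ``n0`` the size at the epoch's younger
    edge).  ``u`` is a unit-exponential draw.  Returns np.inf if the
    integrated hazard over the epoch never reaches ``u``.
    """
    c = 0.5 * k * (k - 1.0) / (2.0 * n0)
    if growth == 0.0:
        return u / c
    x = growth * (s - t_epoch)
    if x > 700.0:
        return 0.0
    rhs = np.exp(x) + u * growth / c
    if rhs <= 0.0:
        return _INF
    return np.log(rhs) / growth + t_epoch - s


@njit(cache=True)
def sim_branch_sfs(seed, n_reps, samp, epoch_t, size, growth, mig,
                   mv_epoch, mv_src, mv_dst):
    """Accumulate branch lengths per joint descendant-count class.

    Parameters are compiled demography arrays (see ``Demography.compile``):
    ``samp`` haploid sample sizes per deme, ``epoch_t`` ascending epoch start
    ages (epoch_t[0] == 0), ``size``/``growth`` of shape (E, D), ``mig`` of
    shape (E, D, D) with zero diagonal, and boundary moves (src deme emptied
    into dst when entering epoch mv_epoch[i]).

    Returns a flat float64 array over the joint classes
    (samp[0]+1) x (samp[1]+1) x ... in C order, total branch length summed
    over ``n_reps`` independent genealogies.
    """
    np.random.seed(seed)
    D = samp.shape[0]
    E = epoch_t.shape[0]
    n_tot = 0
    for d in range(D):
        n_tot += samp[d]

    # strides for flattening a joint count vector
    strides = np.empty(D, dtype=np.int64)
    strides[D - 1] = 1
    for d in range(D - 2, -1, -1):
        strides[d] = strides[d + 1] * (samp[d + 1] + 1)
    sfs = np.zeros(strides[0] * (samp[0] + 1), dtype=np.float64)

    deme_of = np.empty(n_tot, dtype=np.int64)
    alive = np.empty(n_tot, dtype=np.bool_)
    desc = np.empty((n_tot, D), dtype=np.int64)
    kcount = np.empty(D, dtype=np.int64)
    mrow = np.empty(D, dtype=np.float64)

    for rep in range(n_reps):
        i = 0
        for d in range(D):
            for _ in range(samp[d]):
                deme_of[i] = d
                alive[i] = True
                for dd in range(D):
                    desc[i, dd] = 0
                desc[i, d] = 1
                i += 1
        n_live = n_tot
        for d in range(D):
            kcount[d] = samp[d]
        t = 0.0
        e = 0
        # apply any moves registered at epoch 0 (e.g. a split at time 0)
        for m in range(mv_epoch.shape[0]):
            if mv_epoch[m] == 0:
                src = mv_src[m]
                dst = mv_dst[m]
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == src:
                        deme_of[j] = dst
                kcount[dst] += kcount[src]
                kcount[src] = 0
        for d in range(D):
            mrow[d] = 0.0
            for j in range(D):
                mrow[d] += mig[0, d, j]

        while n_live > 1:
            t_end = epoch_t[e + 1] if e + 1 < E else _INF
            best = _INF
            btype = -1
            bdeme = -1
            for d in range(D):
                k = kcount[d]
                if k >= 2:
                    w = _coal_wait(k, size[e, d], growth[e, d], t,
                                   epoch_t[e], np.random.exponential(1.0))
                    if t + w < best:
                        best = t + w
                        btype = 0
                        bdeme = d
            rtot = 0.0
            for d in range(D):
                rtot += kcount[d] * mrow[d]
            if rtot > 0.0:
                w = np.random.exponential(1.0 / rtot)
                if t + w < best:
                    best = t + w
                    btype = 1
            if best >= t_end:
                dt = t_end - t
                for j in range(n_tot):
                    if alive[j]:
                        idx = 0
                        for d in range(D):
                            idx += desc[j, d] * strides[d]
                        sfs[idx] += dt
                t = t_end
                e += 1
                for m in range(mv_epoch.shape[0]):
                    if mv_epoch[m] == e:
                        src = mv_src[m]
                        dst = mv_dst[m]
                        for j in range(n_tot):
                            if alive[j] and deme_of[j] == src:
                                deme_of[j] = dst
                        kcount[dst] += kcount[src]
                        kcount[src] = 0
                for d in range(D):
                    mrow[d] = 0.0
                    for j in range(D):
                        mrow[d] += mig[e, d, j]
                continue
            dt = best - t
            for j in range(n_tot):
                if alive[j]:
                    idx = 0
                    for d in range(D):
                        idx += desc[j, d] * strides[d]
                    sfs[idx] += dt
            t = best
            if btype == 0:
                # choose two distinct alive lineages in bdeme
                k = kcount[bdeme]
                a = np.random.randint(0, k)
                b = np.random.randint(0, k - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                cnt = 0
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == bdeme:
                        if cnt == a:
                            ia = j
                        if cnt == b:
                            ib = j
                        cnt += 1
                for d in range(D):
                    desc[ia, d] += desc[ib, d]
                alive[ib] = False
                kcount[bdeme] -= 1
                n_live -= 1
            else:
                # migration: deme with prob prop to kcount*mrow, then lineage
                r = np.random.random() * rtot
                acc = 0.0
                sd = D - 1
                for d in range(D):
                    acc += kcount[d] * mrow[d]
                    if r < acc:
                        sd = d
                        break
                a = np.random.randint(0, kcount[sd])
                ia = -1
                cnt = 0
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == sd:
                        if cnt == a:
                            ia = j
                        cnt += 1
                r2 = np.random.random() * mrow[sd]
                acc = 0.0
                dest = -1
                for j in range(D):
                    acc += mig[e, sd, j]
                    if r2 < acc:
                        dest = j
                        break
                if dest < 0:
                    for j in range(D - 1, -1, -1):
                        if mig[e, sd, j] > 0.0:
                            dest = j
                            break
                deme_of[ia] = dest
                kcount[sd] -= 1
                kcount[dest] += 1
    return sfs


@njit(cache=True)
def sim_trees(seed, n_reps, samp, epoch_t, size, growth, mig,
              mv_epoch, mv_src, mv_dst):
    """Simulate ``n_reps`` genealogies, returning parent pointers and times.

    Leaves are numbered 0..n-1 in deme-block order (all of deme 0 first).
    Internal nodes get ids n..2n-2 in coalescence order, so node times are
    non-decreasing with id.  The root's parent is -1.

    Returns (parent, ntime) of shapes (n_reps, 2n-1).
    """
    np.random.seed(seed)
    D = samp.shape[0]
    E = epoch_t.shape[0]
    n_tot = 0
    for d in range(D):
        n_tot += samp[d]
    n_nodes = 2 * n_tot - 1

    parent = np.full((n_reps, n_nodes), -1, dtype=np.int64)
    ntime = np.zeros((n_reps, n_nodes), dtype=np.float64)

    deme_of = np.empty(n_tot, dtype=np.int64)
    node_of = np.empty(n_tot, dtype=np.int64)
    alive = np.empty(n_tot, dtype=np.bool_)
    kcount = np.empty(D, dtype=np.int64)
    mrow = np.empty(D, dtype=np.float64)

    for rep in range(n_reps):
        i = 0
        for d in range(D):
            for _ in range(samp[d]):
                deme_of[i] = d
                node_of[i] = i
                alive[i] = True
                i += 1
        n_live = n_tot
        next_node = n_tot
        for d in range(D):
            kcount[d] = samp[d]
        t = 0.0
        e = 0
        for m in range(mv_epoch.shape[0]):
            if mv_epoch[m] == 0:
                src = mv_src[m]
                dst = mv_dst[m]
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == src:
                        deme_of[j] = dst
                kcount[dst] += kcount[src]
                kcount[src] = 0
        for d in range(D):
            mrow[d] = 0.0
            for j in range(D):
                mrow[d] += mig[0, d, j]

        while n_live > 1:
            t_end = epoch_t[e + 1] if e + 1 < E else _INF
            best = _INF
            btype = -1
            bdeme = -1
            for d in range(D):
                k = kcount[d]
                if k >= 2:
                    w = _coal_wait(k, size[e, d], growth[e, d], t,
                                   epoch_t[e], np.random.exponential(1.0))
                    if t + w < best:
                        best = t + w
                        btype = 0
                        bdeme = d
            rtot = 0.0
            for d in range(D):
                rtot += kcount[d] * mrow[d]
            if rtot > 0.0:
                w = np.random.exponential(1.0 / rtot)
                if t + w < best:
                    best = t + w
                    btype = 1
            if best >= t_end:
                t = t_end
                e += 1
                for m in range(mv_epoch.shape[0]):
                    if mv_epoch[m] == e:
                        src = mv_src[m]
                        dst = mv_dst[m]
                        for j in range(n_tot):
                            if alive[j] and deme_of[j] == src:
                                deme_of[j] = dst
                        kcount[dst] += kcount[src]
                        kcount[src] = 0
                for d in range(D):
                    mrow[d] = 0.0
                    for j in range(D):
                        mrow[d] += mig[e, d, j]
                continue
            t = best
            if btype == 0:
                k = kcount[bdeme]
                a = np.random.randint(0, k)
                b = np.random.randint(0, k - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                cnt = 0
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == bdeme:
                        if cnt == a:
                            ia = j
                        if cnt == b:
                            ib = j
                        cnt += 1
                pid = next_node
                next_node += 1
                parent[rep, node_of[ia]] = pid
                parent[rep, node_of[ib]] = pid
                ntime[rep, pid] = t
                node_of[ia] = pid
                alive[ib] = False
                kcount[bdeme] -= 1
                n_live -= 1
            else:
                r = np.random.random() * rtot
                acc = 0.0
                sd = D - 1
                for d in range(D):
                    acc += kcount[d] * mrow[d]
                    if r < acc:
                        sd = d
                        break
                a = np.random.randint(0, kcount[sd])
                ia = -1
                cnt = 0
                for j in range(n_tot):
                    if alive[j] and deme_of[j] == sd:
                        if cnt == a:
                            ia = j
                        cnt += 1
                r2 = np.random.random() * mrow[sd]
                acc = 0.0
                dest = -1
                for j in range(D):
                    acc += mig[e, sd, j]
                    if r2 < acc:
                        dest = j
                        break
                if dest < 0:
                    for j in range(D - 1, -1, -1):
                        if mig[e, sd, j] > 0.0:
                            dest = j
                            break
                deme_of[ia] = dest
                kcount[sd] -= 1
                kcount[dest] += 1
    return parent, ntime
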