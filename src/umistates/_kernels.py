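"""Numba inner loops for the partition search.

The search state is a flat set of arrays (documented in
:class:`umistates.optimize.SearchState`); clusters live in "slots"
``0..n_cells-1``, of which the occupied ones are tracked in a compact
``active`` list and the empty ones in a ``free`` stack.  ``meta`` packs the
mutable counters ``[n_active, n_free, proposals_since_improvement]``.

Log-gamma values ``lnG(theta_g + k)`` for small integer ``k`` are served from
a per-gene lookup table (the dominant cost of the search is log-gamma
evaluation); counts beyond the table fall back to ``math.lgamma``.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-10  # strict-improvement threshold, guards against float noise loops


@njit(cache=True)
def build_lgamma_table(theta, kmax):
    """table[g, k] = lnG(theta_g + k) for k in [0, kmax)."""
    G = theta.size
    table = np.empty((G, kmax), dtype=np.float64)
    for g in range(G):
        for k in range(kmax):
            table[g, k] = math.lgamma(theta[g] + k)
    return table


@njit(cache=True, inline="always")
def _lg(table, theta, g, k):
    if k < table.shape[1]:
        return table[g, k]
    return math.lgamma(theta[g] + k)


@njit(cache=True)
def _delta_leave(indptr, gidx, gcnt, cell_tot, ccnt, ctot, theta, theta_sum,
                 table, c, s):
    """Change of cluster s's log-marginal when cell c leaves it.

    Valid also when s empties: lnG(theta + 0) = lnG(theta) makes the result
    equal minus the cluster's whole term.
    """
    d = math.lgamma(theta_sum + ctot[s]) - math.lgamma(
        theta_sum + ctot[s] - cell_tot[c]
    )
    for p in range(indptr[c], indptr[c + 1]):
        g = gidx[p]
        n = ccnt[s, g]
        d += _lg(table, theta, g, n - gcnt[p]) - _lg(table, theta, g, n)
    return d


@njit(cache=True)
def _delta_join(indptr, gidx, gcnt, cell_tot, ccnt, ctot, theta, theta_sum,
                table, c, t):
    """Change of cluster t's log-marginal when cell c joins it (t may be an
    empty slot, i.e. a NEW cluster)."""
    d = math.lgamma(theta_sum + ctot[t]) - math.lgamma(
        theta_sum + ctot[t] + cell_tot[c]
    )
    for p in range(indptr[c], indptr[c + 1]):
        g = gidx[p]
        n = ccnt[t, g]
        d += _lg(table, theta, g, n + gcnt[p]) - _lg(table, theta, g, n)
    return d


@njit(cache=True)
def _apply_move(indptr, gidx, gcnt, cell_tot, assign, ccnt, ctot, csize,
                active, apos, free, meta, c, s, t):
    """Move cell c from slot s to slot t, maintaining active/free lists."""
    if csize[t] == 0:  # t is the top of the free stack -> becomes active
        meta[1] -= 1
        active[meta[0]] = t
        apos[t] = meta[0]
        meta[0] += 1
    for p in range(indptr[c], indptr[c + 1]):
        g = gidx[p]
        ccnt[s, g] -= gcnt[p]
        ccnt[t, g] += gcnt[p]
    ctot[s] -= cell_tot[c]
    ctot[t] += cell_tot[c]
    csize[s] -= 1
    csize[t] += 1
    assign[c] = t
    if csize[s] == 0:  # s leaves the active list
        pos = apos[s]
        last = meta[0] - 1
        active[pos] = active[last]
        apos[active[pos]] = pos
        meta[0] -= 1
        apos[s] = -1
        free[meta[1]] = s
        meta[1] += 1


@njit(cache=True)
def run_proposals(indptr, gidx, gcnt, cell_tot, assign, ccnt, ctot, csize,
                  active, apos, free, meta, theta, theta_sum, table,
                  u_cell, u_tgt, u_acc, allow_new, uphill_only, window):
    """Run up to len(u_cell) single-cell move proposals.

    Each proposal picks a cell uniformly and a target uniformly over the
    other clusters plus (for non-singleton cells, if allow_new) a NEW
    cluster.  Moves with a positive log-likelihood change are accepted; in
    Metropolis-Hastings mode (uphill_only=False) a non-positive change d is
    accepted with probability exp(d) * q, where q is the ratio of the number
    of legal targets before versus after the move (the proposal-probability
    correction for the changing target set).

    Stops early once `window` consecutive proposals pass without an accepted
    improving move.  Returns (proposals_done, n_accepted_up, n_accepted_down,
    accumulated delta log-likelihood).
    """
    n_cells = assign.size
    n_done = 0
    n_up = 0
    n_down = 0
    dll = 0.0
    for i in range(u_cell.size):
        if meta[2] >= window:
            break
        n_done += 1
        meta[2] += 1
        c = int(u_cell[i] * n_cells)
        if c >= n_cells:
            c = n_cells - 1
        s = assign[c]
        can_new = allow_new and csize[s] > 1
        n_targets = meta[0] - 1 + (1 if can_new else 0)
        if n_targets <= 0:
            continue
        j = int(u_tgt[i] * n_targets)
        if j >= n_targets:
            j = n_targets - 1
        if j < meta[0] - 1:
            if j >= apos[s]:
                j += 1
            t = active[j]
            is_new = False
        else:
            t = free[meta[1] - 1]
            is_new = True

        d = _delta_leave(indptr, gidx, gcnt, cell_tot, ccnt, ctot, theta,
                         theta_sum, table, c, s)
        d += _delta_join(indptr, gidx, gcnt, cell_tot, ccnt, ctot, theta,
                         theta_sum, table, c, t)
        if not np.isfinite(d):
            raise ValueError("non-finite log-likelihood change in proposal")

        accept = False
        if d > 0.0:
            accept = True
            meta[2] = 0
            n_up += 1
        elif not uphill_only:
            # legal-target count seen by the reverse move
            k_after = meta[0] + (1 if is_new else 0) - (1 if csize[s] == 1 else 0)
            can_new_after = allow_new and not is_new  # after joining, size(t) > 1
            n_after = k_after - 1 + (1 if can_new_after else 0)
            if n_after > 0:
                p_acc = math.exp(d) * n_targets / n_after
                if u_acc[i] < p_acc:
                    accept = True
                    n_down += 1
        if accept:
            _apply_move(indptr, gidx, gcnt, cell_tot, assign, ccnt, ctot,
                        csize, active, apos, free, meta, c, s, t)
            dll += d
    return n_done, n_up, n_down, dll


@njit(cache=True)
def refine_cells_pass(indptr, gidx, gcnt, cell_tot, assign, ccnt, ctot, csize,
                      active, apos, free, meta, theta, theta_sum, table):
    """One deterministic sweep: for each cell in index order, apply the best
    strictly-improving move over all other clusters and NEW (ties broken
    toward the lowest slot index; NEW is considered last)."""
    n_cells = assign.size
    n_moves = 0
    dll = 0.0
    for c in range(n_cells):
        s = assign[c]
        drem = _delta_leave(indptr, gidx, gcnt, cell_tot, ccnt, ctot, theta,
                            theta_sum, table, c, s)
        targets = np.sort(active[: meta[0]])
        best_d = _EPS
        best_t = -1
        for idx in range(targets.size):
            t = targets[idx]
            if t == s:
                continue
            d = drem + _delta_join(indptr, gidx, gcnt, cell_tot, ccnt, ctot,
                                   theta, theta_sum, table, c, t)
            if d > best_d:
                best_d = d
                best_t = t
        if csize[s] > 1:
            t = free[meta[1] - 1]
            d = drem + _delta_join(indptr, gidx, gcnt, cell_tot, ccnt, ctot,
                                   theta, theta_sum, table, c, t)
            if d > best_d:
                best_d = d
                best_t = t
        if best_t >= 0:
            _apply_move(indptr, gidx, gcnt, cell_tot, assign, ccnt, ctot,
                        csize, active, apos, free, meta, c, s, best_t)
            dll += best_d
            n_moves += 1
    return n_moves, dll


@njit(cache=True)
def _pair_merge_ratio(ccnt, ctot, theta, theta_sum, table, a, b):
    """log P(a+b) - log P(a) - log P(b); only genes nonzero on both sides
    contribute (the others cancel exactly)."""
    r = (
        math.lgamma(theta_sum + ctot[a])
        + math.lgamma(theta_sum + ctot[b])
        - math.lgamma(theta_sum + ctot[a] + ctot[b])
        - math.lgamma(theta_sum)
    )
    G = ccnt.shape[1]
    for g in range(G):
        na = ccnt[a, g]
        nb = ccnt[b, g]
        if na > 0 and nb > 0:
            # table always has kmax >= 1, so table[g, 0] = lnG(theta_g)
            r += _lg(table, theta, g, na + nb) + table[g, 0]
            r -= _lg(table, theta, g, na) + _lg(table, theta, g, nb)
    return r


@njit(cache=True)
def merge_clusters_pass(assign, ccnt, ctot, csize, active, apos, free, meta,
                        theta, theta_sum, table):
    """One deterministic merge sweep: for each cluster pair in ascending slot
    order, merge when the pair's merge log-ratio is positive."""
    n_merges = 0
    dll = 0.0
    snapshot = np.sort(active[: meta[0]])
    for i in range(snapshot.size):
        a = snapshot[i]
        if csize[a] == 0:
            continue
        for j in range(i + 1, snapshot.size):
            b = snapshot[j]
            if csize[b] == 0 or csize[a] == 0:
                continue
            r = _pair_merge_ratio(ccnt, ctot, theta, theta_sum, table, a, b)
            if r > _EPS:
                # absorb b into a
                for g in range(ccnt.shape[1]):
                    if ccnt[b, g] > 0:
                        ccnt[a, g] += ccnt[b, g]
                        ccnt[b, g] = 0
                ctot[a] += ctot[b]
                ctot[b] = 0
                csize[a] += csize[b]
                csize[b] = 0
                for c in range(assign.size):
                    if assign[c] == b:
                        assign[c] = a
                pos = apos[b]
                last = meta[0] - 1
                active[pos] = active[last]
                apos[active[pos]] = pos
                meta[0] -= 1
                apos[b] = -1
                free[meta[1]] = b
                meta[1] += 1
                n_merges += 1
                dll += r
    return n_merges, dll
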