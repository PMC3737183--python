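"""Numba kernels for maxima acceptance and seeded watershed flooding.

Both kernels process pixels level by level in decreasing intensity, which is
what makes the results exactly reproducible: no randomness, no hash ordering,
ties resolved either by raster scan order (maxima union-find) or by
synchronous waves (watershed), as documented in the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PENDING = 0
ACCEPTED = 1
REJECTED = 2


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def resolve_maxima(values, order, h, w, tol, plateau_of, cand_value, cand_rank,
                   status, pend_next):
    """Classify every candidate plateau as accepted/rejected/pending.

    Pixels are activated in decreasing intensity (``order``); connected
    components of activated pixels are tracked with a union-find.  When a
    component whose summit is a candidate plateau of value v first touches a
    component holding a strictly higher value, the touch happens at the
    current level L (the saddle); the candidate is accepted iff
    L <= v - tol.  Equal-valued candidates whose components meet at a level
    L > v - tol are grouped and only the lowest-rank one kept pending.
    Candidates still pending at the end are global maxima (the caller applies
    the border-plateau rule to them).
    """
    n = h * w
    parent = np.full(n, -1, np.int64)
    comp_max = np.zeros(n, np.int64)
    pend_head = np.full(n, -1, np.int64)
    n_cand = cand_value.shape[0]
    cand_seen = np.zeros(n_cand, np.uint8)

    for idx in range(n):
        p = order[idx]
        v = values[p]
        parent[p] = p
        comp_max[p] = v
        k = plateau_of[p]
        if k >= 0 and cand_seen[k] == 0:
            cand_seen[k] = 1
            pend_head[p] = k
            pend_next[k] = -1
        else:
            pend_head[p] = -1
        r = p // w
        c = p % w
        for dr in range(-1, 2):
            rr = r + dr
            if rr < 0 or rr >= h:
                continue
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                cc = c + dc
                if cc < 0 or cc >= w:
                    continue
                q = rr * w + cc
                if parent[q] < 0:
                    continue
                ra = _find(parent, p)
                rb = _find(parent, q)
                if ra == rb:
                    continue
                ma = comp_max[ra]
                mb = comp_max[rb]
                if ma == mb:
                    hb = pend_head[rb]
                    if hb != -1:
                        ha = pend_head[ra]
                        if ha == -1:
                            pend_head[ra] = hb
                        elif v > ma - tol:
                            # mutually reachable above the tolerance floor:
                            # keep the best-ranked candidate, reject the rest
                            best = ha
                            j = pend_next[ha]
                            while j != -1:
                                if cand_rank[j] < cand_rank[best]:
                                    best = j
                                j = pend_next[j]
                            j = hb
                            while j != -1:
                                if cand_rank[j] < cand_rank[best]:
                                    best = j
                                j = pend_next[j]
                            j = ha
                            while j != -1:
                                nxt = pend_next[j]
                                if j != best:
                                    status[j] = REJECTED
                                j = nxt
                            j = hb
                            while j != -1:
                                nxt = pend_next[j]
                                if j != best:
                                    status[j] = REJECTED
                                j = nxt
                            pend_head[ra] = best
                            pend_next[best] = -1
                        else:
                            # connected only below the floor: keep both pending
                            j = ha
                            while pend_next[j] != -1:
                                j = pend_next[j]
                            pend_next[j] = hb
                else:
                    if ma > mb:
                        lo = pend_head[rb]
                    else:
                        lo = pend_head[ra]
                        pend_head[ra] = pend_head[rb]
                        comp_max[ra] = mb
                    j = lo
                    while j != -1:
                        if v <= cand_value[j] - tol:
                            status[j] = ACCEPTED
                        else:
                            status[j] = REJECTED
                        j = pend_next[j]
                parent[rb] = ra


@njit(cache=True)
def watershed_flood(values, labels, h, w):
    """Level-synchronous seeded flood; contested pixels become boundary (-1).

    ``labels`` holds positive seed labels, 0 for unassigned pixels.  Pixels
    are processed in waves: a wave is every queued pixel at the current
    highest intensity, decided *simultaneously* from the pre-wave label
    state.  A pixel 4-adjacent to exactly one basin joins it; adjacent to two
    or more distinct basins (or only to boundary pixels) it becomes boundary.
    Symmetric inputs therefore produce symmetric partitions.
    """
    n = h * w
    bucket_head = np.full(256, -1, np.int64)
    qnext = np.full(n, -1, np.int64)
    queued = np.zeros(n, np.uint8)
    decision = np.zeros(n, np.int64)
    wave = np.empty(n, np.int64)

    # seed the queue with unassigned 4-neighbors of the seeds
    top = -1
    for p in range(n):
        if labels[p] > 0:
            r = p // w
            c = p % w
            for k in range(4):
                if k == 0:
                    rr, cc = r - 1, c
                elif k == 1:
                    rr, cc = r + 1, c
                elif k == 2:
                    rr, cc = r, c - 1
                else:
                    rr, cc = r, c + 1
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                q = rr * w + cc
                if labels[q] == 0 and queued[q] == 0:
                    queued[q] = 1
                    v = values[q]
                    qnext[q] = bucket_head[v]
                    bucket_head[v] = q
                    if v > top:
                        top = v

    while top >= 0:
        if bucket_head[top] == -1:
            top -= 1
            continue
        # snapshot the current bucket as one wave
        m = 0
        p = bucket_head[top]
        bucket_head[top] = -1
        while p != -1:
            wave[m] = p
            m += 1
            p = qnext[p]
        # phase 1: decide from pre-wave state
        for i in range(m):
            p = wave[i]
            r = p // w
            c = p % w
            first = 0
            contested = False
            for k in range(4):
                if k == 0:
                    rr, cc = r - 1, c
                elif k == 1:
                    rr, cc = r + 1, c
                elif k == 2:
                    rr, cc = r, c - 1
                else:
                    rr, cc = r, c + 1
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                lab = labels[rr * w + cc]
                if lab > 0:
                    if first == 0:
                        first = lab
                    elif lab != first:
                        contested = True
            if contested or first == 0:
                decision[p] = -1
            else:
                decision[p] = first
        # phase 2: commit
        for i in range(m):
            labels[wave[i]] = decision[wave[i]]
        # phase 3: enqueue unassigned neighbors
        for i in range(m):
            p = wave[i]
            r = p // w
            c = p % w
            for k in range(4):
                if k == 0:
                    rr, cc = r - 1, c
                elif k == 1:
                    rr, cc = r + 1, c
                elif k == 2:
                    rr, cc = r, c - 1
                else:
                    rr, cc = r, c + 1
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                q = rr * w + cc
                if labels[q] == 0 and queued[q] == 0:
                    queued[q] = 1
                    v = values[q]
                    qnext[q] = bucket_head[v]
                    bucket_head[v] = q
                    if v > top:
                        top = v


@njit(cache=True)
def forest_predict(X, cleft, cright, feat, thresh, leaf_class, tree_offsets,
                   n_classes):
    """Majority vote over serialized decision trees (ties -> first class)."""
    n = X.shape[0]
    ntrees = tree_offsets.shape[0] - 1
    votes = np.zeros((n, n_classes), np.int32)
    for t in range(ntrees):
        base = tree_offsets[t]
        for i in range(n):
            node = base
            while cleft[node] != -1:
                if X[i, feat[node]] <= thresh[node]:
                    node = base + cleft[node]
                else:
                    node = base + cright[node]
            votes[i, leaf_class[node]] += 1
    out = np.empty(n, np.int64)
    for i in range(n):
        best = 0
        for c in range(1, n_classes):
            if votes[i, c] > votes[i, best]:
                best = c
        out[i] = best
    return out
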