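"""Exhaustive path-search oracle for noise-tolerance maxima detection.

Deliberately naive and structurally unrelated to the production detector
(per-plateau breadth-first path search instead of a global union-find), so
the two can check each other.  Only meant for tiny images.
"""

from collections import deque

import numpy as np


def _round_half_down(x: float) -> int:
    import math

    return math.ceil(x - 0.5)


def _plateaus(arr):
    """Connected components of summit pixels (no strictly greater 8-neighbor)."""
    h, w = arr.shape
    summit = np.ones((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and arr[rr, cc] > arr[r, c]:
                        summit[r, c] = False
    seen = np.zeros((h, w), dtype=bool)
    plateaus = []
    for r in range(h):
        for c in range(w):
            if summit[r, c] and not seen[r, c]:
                comp = []
                dq = deque([(r, c)])
                seen[r, c] = True
                while dq:
                    y, x = dq.popleft()
                    comp.append((y, x))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            yy, xx = y + dr, x + dc
                            if (
                                0 <= yy < h
                                and 0 <= xx < w
                                and summit[yy, xx]
                                and not seen[yy, xx]
                                and arr[yy, xx] == arr[r, c]
                            ):
                                seen[yy, xx] = True
                                dq.append((yy, xx))
                plateaus.append(comp)
    return plateaus


def _reach(arr, plateau, tol):
    """BFS from the plateau through pixels of value > v - tol.

    Returns (reached_higher, reached_pixel_set).
    """
    h, w = arr.shape
    v = arr[plateau[0]]
    floor = v - tol
    seen = set(plateau)
    dq = deque(plateau)
    reached = set()
    higher = False
    while dq:
        y, x = dq.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                yy, xx = y + dr, x + dc
                if not (0 <= yy < h and 0 <= xx < w) or (yy, xx) in seen:
                    continue
                if arr[yy, xx] > v:
                    higher = True
                    reached.add((yy, xx))
                    continue  # a higher pixel ends the path; no need to expand
                if arr[yy, xx] > floor:
                    seen.add((yy, xx))
                    reached.add((yy, xx))
                    dq.append((yy, xx))
    return higher, reached


def oracle_maxima(arr, tol):
    """Accepted maxima points per the literal path-search definition.

    A plateau of value v is accepted iff no 8-connected path through pixels
    of value > v - tol reaches a strictly higher pixel; among equal-valued
    accepted plateaus mutually reachable above the floor only the one with
    the smallest rounded centroid survives; a global-maximum plateau touching
    the border is suppressed.  Returns a sorted list of (row, col) points.
    """
    arr = np.asarray(arr, dtype=np.int64)
    h, w = arr.shape
    gmax = arr.max()
    plateaus = _plateaus(arr)
    cands = []
    for comp in plateaus:
        higher, reached = _reach(arr, [tuple(p) for p in comp], tol)
        if higher:
            continue
        rows = [p[0] for p in comp]
        cols = [p[1] for p in comp]
        cr, cc = sum(rows) / len(rows), sum(cols) / len(cols)
        pt = (_round_half_down(cr), _round_half_down(cc))
        touches_border = any(
            r == 0 or r == h - 1 or c == 0 or c == w - 1 for r, c in comp
        )
        if arr[comp[0]] == gmax and touches_border:
            continue
        cands.append(
            {
                "pixels": set(map(tuple, comp)),
                "value": int(arr[comp[0]]),
                "reached": reached,
                "point": pt,
                "key": (pt[0], pt[1], cr, cc),
            }
        )
    # group equal-valued candidates mutually reachable above the floor
    n = len(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if cands[i]["value"] != cands[j]["value"]:
                continue
            if cands[i]["reached"] & cands[j]["pixels"]:
                parent[find(i)] = find(j)
    best = {}
    for i in range(n):
        root = find(i)
        if root not in best or cands[i]["key"] < best[root]["key"]:
            best[root] = cands[i]
    return sorted({c["point"] for c in best.values()})
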