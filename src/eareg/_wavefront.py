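"""Numba kernels for wavefront (grid Dijkstra) distance propagation.

Two kernels:

* :func:`_wavefront_kernel` — multi-seed single-label Dijkstra; returns the
  shortest barrier-avoiding path distance from the seed set to every pixel.
* :func:`_knearest_kernel` — multi-label Dijkstra where every pixel may be
  settled up to K times, each time from a *distinct* source point; returns the
  K smallest per-source geodesic distances at every pixel.  Labels are pruned
  once a pixel holds K settled sources: any pruned label is dominated at every
  downstream pixel by K distinct closer sources, so the pruning is exact.

Both kernels use a hand-rolled array binary heap (distance key, two integer
payloads) with lazy deletion.  Heap capacity is bounded a priori: pushes only
happen when a label is settled (≤ degree pushes per settled label), so
``N * deg`` entries for the single-label kernel and ``K * N * deg`` for the
multi-label one.
"""

import numpy as np
from numba import njit

__all__ = ["wavefront", "k_nearest"]


@njit(cache=True)
def _heap_up(hd, ha, hb, n):
    i = n - 1
    while i > 0:
        p = (i - 1) >> 1
        if hd[i] < hd[p]:
            hd[i], hd[p] = hd[p], hd[i]
            ha[i], ha[p] = ha[p], ha[i]
            hb[i], hb[p] = hb[p], hb[i]
            i = p
        else:
            break


@njit(cache=True)
def _heap_pop(hd, ha, hb, n):
    d0 = hd[0]
    a0 = ha[0]
    b0 = hb[0]
    n -= 1
    hd[0] = hd[n]
    ha[0] = ha[n]
    hb[0] = hb[n]
    i = 0
    while True:
        left = 2 * i + 1
        right = left + 1
        m = i
        if left < n and hd[left] < hd[m]:
            m = left
        if right < n and hd[right] < hd[m]:
            m = right
        if m == i:
            break
        hd[i], hd[m] = hd[m], hd[i]
        ha[i], ha[m] = ha[m], ha[i]
        hb[i], hb[m] = hb[m], hb[i]
        i = m
    return d0, a0, b0, n


@njit(cache=True)
def wavefront(barrier, seed_flat, off_dr, off_dc, off_w):
    """Multi-seed shortest path distances; barrier pixels stay at +inf."""
    H, W = barrier.shape
    N = H * W
    deg = off_dr.size
    dist = np.full(N, np.inf, np.float64)
    cap = N * deg + seed_flat.size + 1
    hd = np.empty(cap, np.float64)
    ha = np.empty(cap, np.int64)
    hb = np.empty(cap, np.int64)
    n = 0
    for s in seed_flat:
        sr = s // W
        sc = s % W
        if not barrier[sr, sc] and dist[s] > 0.0:
            dist[s] = 0.0
            hd[n] = 0.0
            ha[n] = s
            hb[n] = 0
            n += 1
            _heap_up(hd, ha, hb, n)
    while n > 0:
        d, v, _, n = _heap_pop(hd, ha, hb, n)
        if d > dist[v]:
            continue
        vr = v // W
        vc = v % W
        for e in range(deg):
            ur = vr + off_dr[e]
            uc = vc + off_dc[e]
            if ur < 0 or ur >= H or uc < 0 or uc >= W:
                continue
            if barrier[ur, uc]:
                continue
            u = ur * W + uc
            nd = d + off_w[e]
            if nd < dist[u]:
                dist[u] = nd
                hd[n] = nd
                ha[n] = u
                hb[n] = 0
                n += 1
                _heap_up(hd, ha, hb, n)
    return dist


@njit(cache=True)
def k_nearest(barrier, src_flat, K, off_dr, off_dc, off_w):
    """Per-pixel K smallest geodesic distances to distinct source points.

    ``src_flat`` holds one flat pixel index per source point; coincident
    points are distinct sources.  Returns an (N, K) array sorted ascending
    along axis 1, +inf where fewer than K sources are reachable.
    """
    H, W = barrier.shape
    N = H * W
    deg = off_dr.size
    P = src_flat.size
    res = np.full((N, K), np.inf, np.float64)
    srcs = np.full((N, K), -1, np.int64)
    found = np.zeros(N, np.int64)
    cap = N * deg * K + P + 1
    hd = np.empty(cap, np.float64)
    ha = np.empty(cap, np.int64)
    hb = np.empty(cap, np.int64)
    n = 0
    for p in range(P):
        s = src_flat[p]
        sr = s // W
        sc = s % W
        if barrier[sr, sc]:
            continue
        hd[n] = 0.0
        ha[n] = s
        hb[n] = p
        n += 1
        _heap_up(hd, ha, hb, n)
    while n > 0:
        d, v, p, n = _heap_pop(hd, ha, hb, n)
        k = found[v]
        if k >= K:
            continue
        dup = False
        for j in range(k):
            if srcs[v, j] == p:
                dup = True
                break
        if dup:
            continue
        res[v, k] = d
        srcs[v, k] = p
        found[v] = k + 1
        vr = v // W
        vc = v % W
        for e in range(deg):
            ur = vr + off_dr[e]
            uc = vc + off_dc[e]
            if ur < 0 or ur >= H or uc < 0 or uc >= W:
                continue
            if barrier[ur, uc]:
                continue
            u = ur * W + uc
            if found[u] < K:
                hd[n] = d + off_w[e]
                ha[n] = u
                hb[n] = p
                n += 1
                _heap_up(hd, ha, hb, n)
    return res
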