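"""Seed-chain-extend alignment primitives used by the containment miner.

The extension aligner is a banded, query-global ("infix") edit-distance DP:
the whole region must be consumed, the read end-points are free.  It reports
the minimal edit distance plus, from the traceback, how many region positions
were aligned opposite an actual read base (the containment coverage).

The band is anchored on the diagonal suggested by the seed chain, and the
read window is padded with sentinel characters so that region overhangs are
charged one edit per base without special-casing window edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import SnrcmError

SENTINEL = 4  # never equal to an ACGT code

_DIAG, _VERT, _HORIZ = 0, 1, 2


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; windows containing sentinels yield -1."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    dtype = np.int64 if k > 15 else np.int32
    m = n - k + 1
    vals = np.bitwise_and(codes, 3).astype(dtype)  # sentinels masked separately below
    out = np.zeros(m, dtype=dtype)
    for j in range(k):
        np.left_shift(out, 2, out=out)
        np.add(out, vals[j : m + j], out=out)
    sentinels = np.nonzero(codes > 3)[0]
    for p in sentinels:  # few sentinels (read separators); mask spanning windows
        out[max(0, p - k + 1) : min(m, p + 1)] = -1
    return out


@dataclass
class Chain:
    """Best colinear anchor run for one (read, region, strand)."""

    n_anchors: int
    diag: int           # read_pos - region_pos (strand-oriented region coords)
    r_lo: int
    r_hi: int           # region span of the chain, half-open, includes k
    q_lo: int
    q_hi: int
    coverage: float     # union of k-mer hits on the region / region length


def best_chain(qpos: np.ndarray, rpos: np.ndarray, region_len: int, k: int,
               band: int, max_gap: int) -> Chain | None:
    """Pick the densest diagonal window, then the best gap-bounded run in it."""
    if qpos.size == 0:
        return None
    d = qpos.astype(np.int64) - rpos.astype(np.int64)
    order = np.argsort(d, kind="stable")
    ds = d[order]
    hi = np.searchsorted(ds, ds + 2 * band, side="right")
    counts = hi - np.arange(ds.size)
    best = int(np.argmax(counts))  # first maximum: deterministic
    sel = order[best : hi[best]]

    r = rpos[sel]
    q = qpos[sel]
    ro = np.argsort(r, kind="stable")
    r, q = r[ro], q[ro]
    # keep anchors monotone in read position as well
    keep = np.ones(r.size, dtype=bool)
    if r.size > 1:
        keep[1:] = q[1:] > np.maximum.accumulate(q)[:-1]
    r, q = r[keep], q[keep]
    if r.size == 0:
        return None

    # split into runs at region gaps > max_gap, keep the run with most coverage
    gaps = np.where(np.diff(r) > max_gap)[0]
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps + 1, [r.size]])
    best_cov, best_run = -1.0, (0, r.size)
    for s, e in zip(starts, ends):
        rr = r[s:e]
        cov = float(np.minimum(np.diff(rr), k).sum() + k) if rr.size else 0.0
        if cov > best_cov:
            best_cov, best_run = cov, (s, e)
    s, e = best_run
    r, q = r[s:e], q[s:e]
    return Chain(
        n_anchors=int(r.size),
        diag=int(np.median(q.astype(np.int64) - r.astype(np.int64))),
        r_lo=int(r[0]),
        r_hi=int(r[-1]) + k,
        q_lo=int(q[0]),
        q_hi=int(q[-1]) + k,
        coverage=min(1.0, best_cov / region_len),
    )


@dataclass
class InfixAlignment:
    distance: int
    covered: int          # region positions aligned opposite a real read base
    read_start: int       # on the window passed in
    read_end: int


def banded_infix_align(region: np.ndarray, window: np.ndarray, diag: int, band: int) -> InfixAlignment:
    """Banded query-global edit-distance alignment of `region` inside `window`.

    `diag` maps region position i to expected window position i + diag; the
    band explores +-band around it.  Returns the optimal distance within the
    band and traceback-derived coverage.
    """
    L = int(region.size)
    W = int(window.size)
    if L == 0:
        raise SnrcmError("empty region passed to aligner")
    w = 2 * band + 1
    # sentinel padding so every banded cell addresses a real array position
    pad_left = max(0, band - diag) + 1
    pad_right = max(0, (L + diag + band) - W) + 1
    T = np.concatenate([
        np.full(pad_left, SENTINEL, dtype=np.uint8),
        window.astype(np.uint8),
        np.full(pad_right, SENTINEL, dtype=np.uint8),
    ])
    base = diag + pad_left - band  # absolute window index of band column 0 at row 0
    if base < 0:
        T = np.concatenate([np.full(-base, SENTINEL, dtype=np.uint8), T])
        pad_left += -base
        base = 0

    INF = np.int32(1 << 29)
    ar = np.arange(w, dtype=np.int32)
    D = np.zeros(w, dtype=np.int32)  # row 0: free start anywhere
    moves = np.empty((L, w), dtype=np.uint8)
    diag_sc = np.empty(w, dtype=np.int32)
    vert_sc = np.empty(w, dtype=np.int32)
    M = np.empty(w, dtype=np.int32)
    for i in range(1, L + 1):
        s_i = base + i  # absolute index of band column 0 in row i
        tseg = T[s_i - 1 : s_i - 1 + w]
        np.add(D, tseg != region[i - 1], out=diag_sc, casting="unsafe")
        vert_sc[-1] = INF
        np.add(D[1:], 1, out=vert_sc[:-1])
        np.minimum(diag_sc, vert_sc, out=M)
        # horizontal closure: D[c] = min_{j<=c} M[j] + (c - j)
        np.subtract(M, ar, out=vert_sc)
        np.minimum.accumulate(vert_sc, out=vert_sc)
        Dn = np.add(vert_sc, ar, out=vert_sc)
        mv = moves[i - 1]
        np.not_equal(Dn, diag_sc, out=mv.view(bool))
        np.add(mv, Dn != M, out=mv, casting="unsafe")
        D, vert_sc = Dn.copy(), vert_sc  # Dn aliases vert_sc; detach for next row
    Dn = D

    c = int(np.argmin(D))
    dist = int(D[c])
    covered = 0
    real_lo, real_hi = pad_left, pad_left + W
    i = L
    end_abs = base + L + c  # one past the last consumed window position + 1 offset
    start_abs = end_abs
    while i > 0:
        mv = int(moves[i - 1][c])
        if mv == _HORIZ:
            c -= 1
        elif mv == _VERT:
            i -= 1
            c += 1
        else:  # diagonal
            j_abs = base + i + c - 1  # window char consumed at this step
            if real_lo <= j_abs < real_hi:
                covered += 1
            i -= 1
        start_abs = base + i + c
    return InfixAlignment(
        distance=dist,
        covered=covered,
        read_start=max(0, start_abs - pad_left),
        read_end=min(W, end_abs - pad_left),
    )
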