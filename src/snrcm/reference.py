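"""Brute-force reference implementations used to validate the fast paths.

Nothing here is called by the production code; tests and the reproduction
script compare against these routines.  The containment reference runs an
exhaustive infix alignment over the entire read (edlib) instead of
seed-chain-extend; the precursor reference enumerates every (ORF, split,
acceptor) combination literally; the tiling reference searches all clone
subsets.
"""

from __future__ import annotations

from itertools import combinations

import edlib

from .containment import ContainmentParams, ContainmentVerdict, make_call
from .util import revcomp


def _shared_kmer_anchors(region: str, read: str, k: int) -> tuple[int, int]:
    """Exact shared k-mer (position pair) counts for (forward, reverse) strands."""
    index: dict[str, int] = {}
    for i in range(len(region) - k + 1):
        kmer = region[i : i + k]
        index[kmer] = index.get(kmer, 0) + 1
    counts = []
    for oriented in (read, revcomp(read)):
        n = 0
        for j in range(len(oriented) - k + 1):
            n += index.get(oriented[j : j + k], 0)
        counts.append(n)
    return counts[0], counts[1]


def _edlib_metrics(region: str, read: str) -> tuple[float, float]:
    res = edlib.align(region, read, mode="HW", task="path")
    dist = res["editDistance"]
    covered = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            if ch in "=X":
                covered += int(num)
            num = ""
    L = len(region)
    return covered / L, max(0.0, 1.0 - dist / L)


def containment_reference(region: str, read: str,
                          params: ContainmentParams | None = None,
                          region_id: str = "region", read_id: str = "read") -> ContainmentVerdict:
    """Exhaustive single-pair containment verdict with the same thresholds."""
    params = params or ContainmentParams()
    n_fwd, n_rev = _shared_kmer_anchors(region, read, params.kmer_size)
    cov_f, id_f = _edlib_metrics(region, read)
    cov_r, id_r = _edlib_metrics(region, revcomp(read))
    if (cov_f, id_f) >= (cov_r, id_r):
        covered, identity, strand = cov_f, id_f, "+"
    else:
        covered, identity, strand = cov_r, id_r, "-"
    call = make_call(covered, identity, max(n_fwd, n_rev), params)
    return ContainmentVerdict(region_id=region_id, call=call, best_read_id=read_id,
                              covered_fraction=covered, identity=identity, strand=strand)


# ------------------------------------------------------------------ precursors

_STARTS = ("ATG", "GTG", "TTG")
_STOPS = ("TAA", "TAG", "TGA")

_CODONS = {}
for _i, _a in enumerate("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"):
    _c = "TCAG"[_i // 16] + "TCAG"[(_i // 4) % 4] + "TCAG"[_i % 4]
    _CODONS[_c] = _a


def translate(dna: str) -> str:
    return "".join(_CODONS.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3))


def scan_precursors_reference(dna: str, config) -> set[tuple]:
    """Literal rule enumeration over every (strand, start, split, acceptor).

    Returns hashable candidate keys
    (start, end, strand, split, acceptor_index) for set comparison with the
    production scanner.  `config` is a snrcm.lasso.PrecursorScanConfig.
    """
    donors = set(config.donor_residues())
    out = set()
    n = len(dna)
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        for start in range(0, n - 2):
            if seq[start : start + 3] not in _STARTS:
                continue
            stop = None
            p = start + 3
            while p + 3 <= n:
                if seq[p : p + 3] in _STOPS:
                    stop = p
                    break
                p += 3
            if stop is None:
                continue
            aa = "M" + translate(seq[start + 3 : stop])
            if not (config.min_orf_aa <= len(aa) <= config.max_orf_aa):
                continue
            for split in range(1, len(aa)):
                leader, core = aa[:split], aa[split:]
                if len(leader) < config.min_leader_aa:
                    continue
                if core[0] not in donors:
                    continue
                if leader[-2] not in config.minus2_residues:
                    continue
                for ring_pos in config.ring_positions:  # 1-based ring size
                    idx = ring_pos - 1
                    if idx >= len(core):
                        continue
                    if core[idx] not in config.acceptor_residues:
                        continue
                    tail = len(core) - idx - 1
                    if tail < config.min_tail_aa:
                        continue
                    if strand == "+":
                        s0, e0 = start, stop + 3
                    else:
                        s0, e0 = n - (stop + 3), n - start
                    out.add((s0, e0, strand, split, idx))
    return out


# --------------------------------------------------------------------- tiling

def min_cover_bruteforce(target: tuple[int, int], intervals: dict[str, tuple[int, int]],
                         min_overlap_bp: int) -> int | None:
    """Minimum number of intervals covering target with chained overlaps.

    Exhaustive over subsets (use only on small instances).  Returns None if
    no subset covers the target.
    """
    t0, t1 = target
    ids = sorted(intervals)
    for size in range(1, len(ids) + 1):
        for combo in combinations(ids, size):
            ivs = sorted((intervals[c] for c in combo), key=lambda iv: iv[0])
            if ivs[0][0] > t0 or ivs[0][1] <= t0:
                continue
            reach = ivs[0][1]
            ok = True
            for s, e in ivs[1:]:
                if s > reach - min_overlap_bp:
                    ok = False
                    break
                reach = max(reach, e)
            if ok and reach >= t1:
                return size
    return None


def find_sites_naive(seq: str, site: str) -> list[int]:
    """Every start position where site (or its reverse complement) occurs."""
    rc = revcomp(site)
    hits = set()
    for i in range(len(seq) - len(site) + 1):
        window = seq[i : i + len(site)]
        if window == site or window == rc:
            hits.add(i)
    return sorted(hits)
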