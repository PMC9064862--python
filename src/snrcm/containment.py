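"""Single-read cluster mining: decide whether a candidate BGC region is
completely captured on at least one long read.

A region is "complete on a single read" when one read carries the whole
region interval at sufficient alignment coverage and identity.  Because every
long read derives from a single clone molecule, a complete containment proves
the cluster sits on one insert.

The miner seeds with shared k-mers (both strands), chains them colinearly per
read, and extends the best chains with a banded edit-distance alignment.  The
exhaustive-alignment counterpart used to validate it lives in
:mod:`snrcm.reference`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import Chain, banded_infix_align, best_chain, kmer_codes
from .seqio import GffRecord, read_gff3
from .util import SnrcmError, encode, revcomp_codes

log = logging.getLogger(__name__)

CALL_COMPLETE = "complete_on_single_read"
CALL_PARTIAL = "partial"
CALL_ABSENT = "absent"


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class BGCRegion:
    """Candidate cluster interval on a contig, 0-based half-open."""

    region_id: str
    contig_id: str
    start: int
    end: int
    class_label: str = "unknown"
    on_contig_edge: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ContainmentParams:
    kmer_size: int = 15
    min_chain_coverage: float = 0.95
    min_identity: float = 0.80
    band_bp: int = 500
    max_gap_bp: int = 2000
    min_seed_anchors: int = 3     # below this: no evidence the region is on the read at all
    max_candidates_aligned: int = 8   # chains taken to full banded alignment per region

    def validate(self) -> None:
        if not (0.0 < self.min_chain_coverage <= 1.0):
            raise SnrcmError("min_chain_coverage must be in (0, 1]")
        if not (0.0 < self.min_identity <= 1.0):
            raise SnrcmError("min_identity must be in (0, 1]")
        if self.kmer_size < 8:
            raise SnrcmError("kmer_size must be >= 8")


@dataclass
class ContainmentVerdict:
    region_id: str
    call: str
    best_read_id: str | None = None
    covered_fraction: float = 0.0
    identity: float = 0.0
    strand: str = "+"
    supporting_reads: list[str] = field(default_factory=list)


def make_call(covered: float, identity: float, n_anchors: int, params: ContainmentParams) -> str:
    """Shared verdict rule; the reference oracle applies the identical logic."""
    if n_anchors < params.min_seed_anchors:
        return CALL_ABSENT
    if covered >= params.min_chain_coverage and identity >= params.min_identity:
        return CALL_COMPLETE
    return CALL_PARTIAL


# ------------------------------------------------------------------ filtering

def filter_contigs(contigs: list[Contig], min_len_bp: int) -> list[Contig]:
    """Keep contigs of length >= min_len_bp (inclusive), order preserved."""
    if min_len_bp < 0:
        raise SnrcmError("min_len_bp must be >= 0")
    return [c for c in contigs if c.length_bp >= min_len_bp]


def import_regions(gff_path, contigs: dict[str, str] | dict[str, Contig],
                   edge_margin_bp: int = 0) -> list[BGCRegion]:
    """Read candidate regions from GFF3 and validate them against contigs."""
    lengths = {k: (len(v.sequence) if isinstance(v, Contig) else len(v)) for k, v in contigs.items()}
    regions = []
    for rec in read_gff3(gff_path):
        if rec.type not in ("region", "biosynthetic_gene_cluster", "BGC_region"):
            continue
        rid = rec.attributes.get("ID", f"{rec.seqid}:{rec.start}-{rec.end}")
        if rec.seqid not in lengths:
            raise SnrcmError(f"region {rid}: unknown contig {rec.seqid!r}")
        clen = lengths[rec.seqid]
        if rec.end > clen:
            raise SnrcmError(f"region {rid}: interval {rec.start}..{rec.end} exceeds contig length {clen}")
        edge = rec.start <= edge_margin_bp or rec.end >= clen - edge_margin_bp
        regions.append(
            BGCRegion(region_id=rid, contig_id=rec.seqid, start=rec.start, end=rec.end,
                      class_label=rec.attributes.get("class", "unknown"), on_contig_edge=edge)
        )
    return regions


def regions_to_gff(regions: list[BGCRegion]) -> list[GffRecord]:
    return [
        GffRecord(seqid=r.contig_id, type="region", start=r.start, end=r.end, strand="+",
                  attributes={"ID": r.region_id, "class": r.class_label})
        for r in regions
    ]


# --------------------------------------------------------------------- mining

@dataclass
class _Candidate:
    read_idx: int
    strand: str
    chain: Chain


def _region_table(region_codes_by_strand: list[tuple[np.ndarray, np.ndarray]], k: int):
    """Sorted k-mer table over all regions (both strands).

    Returns (codes_sorted, region_idx, strand_idx, pos) parallel arrays.
    K-mers occurring more than 8 times in one region/strand are dropped as
    repeats.
    """
    codes_all, reg_all, strand_all, pos_all = [], [], [], []
    for ridx, strands in enumerate(region_codes_by_strand):
        for sidx, codes in enumerate(strands):
            kc = kmer_codes(codes, k)
            uniq, inv, cnt = np.unique(kc, return_inverse=True, return_counts=True)
            good = cnt[inv] <= 8
            kc = kc[good]
            pos = np.nonzero(good)[0]
            codes_all.append(kc)
            reg_all.append(np.full(kc.size, ridx, dtype=np.int32))
            strand_all.append(np.full(kc.size, sidx, dtype=np.int8))
            pos_all.append(pos.astype(np.int32))
    codes = np.concatenate(codes_all)
    order = np.argsort(codes, kind="stable")
    return (codes[order], np.concatenate(reg_all)[order],
            np.concatenate(strand_all)[order], np.concatenate(pos_all)[order])


def mine_regions(regions: list[BGCRegion], contigs: dict[str, str],
                 reads: list[tuple[str, str]],
                 params: ContainmentParams | None = None) -> list[ContainmentVerdict]:
    """Run containment mining for many regions over one read set in one pass."""
    params = params or ContainmentParams()
    params.validate()
    k = params.kmer_size
    region_seqs = []
    for r in regions:
        if r.contig_id not in contigs:
            raise SnrcmError(f"region {r.region_id}: contig {r.contig_id!r} not provided")
        seq = contigs[r.contig_id][r.start:r.end]
        if len(seq) < k:
            raise SnrcmError(f"region {r.region_id}: shorter than kmer_size {k}")
        region_seqs.append(seq)

    if not reads:
        warnings.warn("empty read set: all regions called absent")
        return [ContainmentVerdict(region_id=r.region_id, call=CALL_ABSENT) for r in regions]

    region_codes = [(encode(s), revcomp_codes(encode(s))) for s in region_seqs]
    table_codes, table_reg, table_strand, table_pos = _region_table(region_codes, k)

    # bit filter over the 4^k code space: O(1) membership test before the
    # exact (and costlier) sorted-table lookup
    bitfilter = np.zeros((4**k + 7) // 8, dtype=np.uint8) if k <= 15 else None
    if bitfilter is not None:
        tc = np.unique(table_codes).astype(np.int64)  # sorted unique codes
        byte_idx = tc >> 3
        bitv = np.left_shift(np.uint8(1), (tc & 7).astype(np.uint8))
        starts = np.nonzero(np.concatenate([[True], np.diff(byte_idx) > 0]))[0]
        bitfilter[byte_idx[starts]] = np.bitwise_or.reduceat(bitv, starts)

    candidates: list[list[_Candidate]] = [[] for _ in regions]
    read_codes_cache: dict[int, np.ndarray] = {}

    chunk, offsets, ids_in_chunk = [], [0], []
    CHUNK_BASES = 32_000_000

    def flush():
        if not ids_in_chunk:
            return
        concat = np.concatenate(chunk)
        kc = kmer_codes(concat, k)
        if bitfilter is not None:
            kc32 = kc.astype(np.int32, copy=False)
            byte = bitfilter[np.right_shift(kc32, np.int32(3))]
            bit = np.bitwise_and(kc32, np.int32(7)).astype(np.uint8)
            hitbit = np.bitwise_and(np.right_shift(byte, bit), np.uint8(1))
            maybe = np.nonzero((kc32 >= 0) & hitbit.astype(bool))[0]
        else:
            maybe = np.arange(kc.size)
        lo = np.searchsorted(table_codes, kc[maybe], side="left")
        hi = np.searchsorted(table_codes, kc[maybe], side="right")
        nhit = hi - lo
        hit_sel = np.nonzero(nhit)[0]
        hit_q = maybe[hit_sel]
        if hit_q.size:
            reps = nhit[hit_sel]
            lo = lo[hit_sel]
            qpos_flat = np.repeat(hit_q, reps)
            cum = np.cumsum(reps)
            within = np.arange(int(cum[-1])) - np.repeat(cum - reps, reps)
            tidx = np.repeat(lo, reps) + within
            off = np.asarray(offsets[:-1])
            read_of = np.searchsorted(np.asarray(offsets), qpos_flat, side="right") - 1
            qpos_local = qpos_flat - off[read_of]
            regs = table_reg[tidx]
            strands = table_strand[tidx]
            rposs = table_pos[tidx]
            # group by (read, region, strand)
            key = (read_of.astype(np.int64) * len(regions) + regs) * 2 + strands
            order = np.argsort(key, kind="stable")
            key_s = key[order]
            bounds = np.nonzero(np.diff(key_s))[0] + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [key_s.size]])
            for s, e in zip(starts, ends):
                if e - s < params.min_seed_anchors:
                    continue
                sel = order[s:e]
                ridx = int(regs[sel[0]])
                sidx = int(strands[sel[0]])
                local_read = int(read_of[sel[0]])
                L = len(region_seqs[ridx])
                ch = best_chain(qpos_local[sel], rposs[sel], L, k, params.band_bp, params.max_gap_bp)
                if ch is None or ch.n_anchors < params.min_seed_anchors:
                    continue
                gid = ids_in_chunk[local_read]
                candidates[ridx].append(_Candidate(read_idx=gid, strand="+-"[sidx], chain=ch))
        chunk.clear()
        ids_in_chunk.clear()
        offsets.clear()
        offsets.append(0)

    sep = np.full(1, 4, dtype=np.uint8)
    for gid, (_rid, seq) in enumerate(reads):
        codes = encode(seq)
        read_codes_cache[gid] = codes
        chunk.append(codes)
        chunk.append(sep)
        offsets.append(offsets[-1] + codes.size + 1)
        ids_in_chunk.append(gid)
        if offsets[-1] > CHUNK_BASES:
            flush()
    flush()

    verdicts = []
    for ridx, region in enumerate(regions):
        cands = candidates[ridx]
        if not cands:
            verdicts.append(ContainmentVerdict(region_id=region.region_id, call=CALL_ABSENT))
            continue
        cands.sort(key=lambda c: (-c.chain.coverage, -c.chain.n_anchors, reads[c.read_idx][0], c.strand))
        L = len(region_seqs[ridx])
        evaluated = []
        best_cov_so_far = -1.0
        for cand in cands[: params.max_candidates_aligned]:
            # chain coverage underestimates true coverage by a bounded margin;
            # stop once no remaining chain can improve on the current best
            if evaluated and cand.chain.coverage + 0.35 < best_cov_so_far:
                break
            rcodes = region_codes[ridx][0 if cand.strand == "+" else 1]
            read_arr = read_codes_cache[cand.read_idx]
            ch = cand.chain
            qa = max(0, ch.q_lo - ch.r_lo - params.band_bp)
            qb = min(read_arr.size, ch.q_hi + (L - ch.r_hi) + params.band_bp)
            window = read_arr[qa:qb]
            aln = banded_infix_align(rcodes, window, diag=(ch.q_lo - ch.r_lo) - qa, band=params.band_bp)
            covered = aln.covered / L
            identity = max(0.0, 1.0 - aln.distance / L)
            evaluated.append((covered, identity, cand))
            best_cov_so_far = max(best_cov_so_far, covered)
        evaluated.sort(key=lambda t: (-t[0], -t[1], reads[t[2].read_idx][0]))
        covered, identity, best = evaluated[0]
        call = make_call(covered, identity, best.chain.n_anchors, params)
        supporting = [
            reads[c.read_idx][0] for cov, idn, c in evaluated
            if cov >= params.min_chain_coverage and idn >= params.min_identity
        ]
        verdicts.append(
            ContainmentVerdict(
                region_id=region.region_id, call=call, best_read_id=reads[best.read_idx][0],
                covered_fraction=round(covered, 6), identity=round(identity, 6),
                strand=best.strand, supporting_reads=supporting,
            )
        )
    return verdicts


def mine_single_read_containment(region, reads, params: ContainmentParams | None = None,
                                 contigs: dict[str, str] | None = None) -> ContainmentVerdict:
    """Containment verdict for one region.

    `region` may be a raw sequence string or a :class:`BGCRegion` (then
    `contigs` must supply its contig sequence).  `reads` is a list of
    (read_id, sequence) pairs.
    """
    if isinstance(region, BGCRegion):
        if contigs is None:
            raise SnrcmError("contigs mapping required when passing a BGCRegion")
        regs, ctgs = [region], contigs
    else:
        regs = [BGCRegion(region_id="region", contig_id="_seq", start=0, end=len(region))]
        ctgs = {"_seq": region}
    return mine_regions(regs, ctgs, list(reads), params)[0]


def summarize_by_class(verdicts: list[ContainmentVerdict], regions: list[BGCRegion]) -> dict[str, int]:
    """Per-class counts of complete_on_single_read calls."""
    by_id = {r.region_id: r for r in regions}
    counts: dict[str, int] = {}
    for v in verdicts:
        if v.region_id not in by_id:
            raise SnrcmError(f"verdict references unknown region {v.region_id!r}")
        if v.call == CALL_COMPLETE:
            label = by_id[v.region_id].class_label
            counts[label] = counts.get(label, 0) + 1
    return counts
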