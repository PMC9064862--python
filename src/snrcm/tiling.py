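"""Planning the recovery of a cluster larger than one insert: minimal tiling
path over end-sequenced fosmid alignments, restriction-digest prediction for
the assembled construct, and read-based verification of the assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .containment import CALL_COMPLETE, ContainmentParams, mine_single_read_containment
from .util import SnrcmError, revcomp

# real 8-bp rare cutters used to release the cluster from an assembled construct
RARE_CUTTERS = {
    "SwaI": "ATTTAAAT",
    "PmeI": "GTTTAAAC",
    "PacI": "TTAATTAA",
    "NotI": "GCGGCCGC",
    "AscI": "GGCGCGCC",
    "SbfI": "CCTGCAGG",
    "FseI": "GGCCGGCC",
    "AsiSI": "GCGATCGC",
    "SrfI": "GCCCGGGC",
}


class TilingGapError(SnrcmError):
    """No clone set covers the target; carries the first uncovered interval."""

    def __init__(self, gap: tuple[int, int]):
        self.gap = gap
        super().__init__(f"coverage gap over reference interval {gap[0]}..{gap[1]}")


@dataclass
class FosmidAlignment:
    clone_id: str
    ref_interval: tuple[int, int]  # 0-based half-open on the reference contig
    strand: str = "+"


@dataclass
class TilingPath:
    clone_ids: list[str]
    intervals: list[tuple[int, int]]
    pairwise_overlaps_bp: list[int]
    covered_interval: tuple[int, int]


@dataclass
class DigestResult:
    enzyme: str | None
    site: str | None
    site_positions: list[int]
    fragment_lengths_bp: list[int]
    topology: str  # circular | linear


@dataclass
class FragmentVerdict:
    fragment_id: str
    covered: bool
    covered_fraction: float
    identity: float
    best_read_id: str | None


@dataclass
class AssemblyVerification:
    passed: bool
    fragments: list[FragmentVerdict] = field(default_factory=list)


# --------------------------------------------------------------------- tiling

def find_tiling_path(target_interval: tuple[int, int], alignments: list[FosmidAlignment],
                     min_overlap_bp: int = 500, allow_strand_discordant: bool = False) -> TilingPath:
    """Minimum-cardinality cover of the target by greedy furthest reach.

    Classical interval covering: at reach r, among clones starting at or
    before r - min_overlap (or covering the target start for the first pick),
    choose the one reaching furthest.  Ties break to the larger overlap then
    the smaller clone_id.  Raises :class:`TilingGapError` naming the first
    uncovered coordinate when no cover exists.
    """
    t0, t1 = target_interval
    if t1 <= t0:
        raise SnrcmError("empty target interval")
    usable = [a for a in alignments if allow_strand_discordant or a.strand == "+"]
    chosen: list[FosmidAlignment] = []
    reach = t0
    while reach < t1:
        threshold = t0 if not chosen else reach - min_overlap_bp
        candidates = [a for a in usable
                      if a.ref_interval[0] <= threshold and a.ref_interval[1] > reach
                      and a not in chosen]
        if not candidates:
            raise TilingGapError((reach, t1))
        best = max(candidates, key=lambda a: (a.ref_interval[1], -a.ref_interval[0],
                                              [-ord(ch) for ch in a.clone_id]))
        chosen.append(best)
        reach = best.ref_interval[1]
    overlaps = [chosen[i].ref_interval[1] - chosen[i + 1].ref_interval[0]
                for i in range(len(chosen) - 1)]
    return TilingPath(
        clone_ids=[a.clone_id for a in chosen],
        intervals=[a.ref_interval for a in chosen],
        pairwise_overlaps_bp=overlaps,
        covered_interval=(min(a.ref_interval[0] for a in chosen),
                          max(a.ref_interval[1] for a in chosen)),
    )


# --------------------------------------------------------------------- digest

def find_sites(sequence: str, recognition_site: str) -> list[int]:
    """Start positions of the recognition site on either strand (palindromes
    counted once)."""
    if len(recognition_site) < 4:
        raise SnrcmError("recognition site must be at least 4 bp")
    site = recognition_site.upper()
    rc = revcomp(site)
    hits = set()
    for probe in ({site} if site == rc else {site, rc}):
        idx = sequence.find(probe)
        while idx != -1:
            hits.add(idx)
            idx = sequence.find(probe, idx + 1)
    return sorted(hits)


def fragments_from_sites(molecule_len: int, cut_positions: list[int], topology: str) -> list[int]:
    cuts = sorted(cut_positions)
    if topology == "circular":
        if not cuts:
            return []
        return [(cuts[(i + 1) % len(cuts)] - cuts[i]) % molecule_len or molecule_len
                for i in range(len(cuts))]
    if topology == "linear":
        bounds = [0] + cuts + [molecule_len]
        return [b - a for a, b in zip(bounds[:-1], bounds[1:])]
    raise SnrcmError(f"unknown topology {topology!r}")


def predict_digest_fragments(molecule: str | int, recognition_site: str | None = None,
                             topology: str = "circular",
                             site_positions: list[int] | None = None,
                             cut_offset: int | None = None,
                             enzyme: str | None = None) -> DigestResult:
    """Predict restriction fragments of a molecule.

    `molecule` is either the sequence (sites located by search) or a length
    (then `site_positions` must be given).  Cuts fall at site start +
    cut_offset (default: middle of the site, blunt-cutter convention).
    """
    if isinstance(molecule, int):
        if site_positions is None:
            raise SnrcmError("site_positions required when only a length is given")
        molecule_len = molecule
        sites = sorted(site_positions)
        offset = cut_offset or 0
    else:
        if recognition_site is None:
            raise SnrcmError("recognition_site required when a sequence is given")
        molecule_len = len(molecule)
        sites = find_sites(molecule, recognition_site)
        offset = (len(recognition_site) // 2) if cut_offset is None else cut_offset
    cuts = [(s + offset) % molecule_len for s in sites]
    if topology == "circular" and not sites:
        warnings.warn("no recognition sites on circular molecule: zero fragments")
    fragments = fragments_from_sites(molecule_len, cuts, topology)
    return DigestResult(enzyme=enzyme, site=recognition_site, site_positions=sites,
                        fragment_lengths_bp=fragments, topology=topology)


def choose_release_enzyme(construct: str, min_fragment_bp: int = 5000,
                          panel: dict[str, str] | None = None) -> DigestResult:
    """Pick a rare cutter that releases the construct into exactly two
    fragments (preferring both >= min_fragment_bp); fall back to the enzyme
    whose digest is closest to two fragments."""
    panel = panel or RARE_CUTTERS
    results = []
    for enzyme, site in sorted(panel.items()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-cutters are expected during panel scan
            res = predict_digest_fragments(construct, site, topology="circular", enzyme=enzyme)
        n = len(res.fragment_lengths_bp)
        ok_size = bool(res.fragment_lengths_bp) and min(res.fragment_lengths_bp) >= min_fragment_bp
        results.append(((n != 2, not ok_size, abs(n - 2), enzyme), res))
    results.sort(key=lambda t: t[0])
    best = results[0][1]
    if not best.site_positions:
        raise SnrcmError("no enzyme in the panel cuts the construct")
    return best


# --------------------------------------------------------------- verification

def size_filter_reads(reads: list[tuple[str, str]], expected_sizes_bp: list[int],
                      rel_tol: float = 0.1) -> dict[int, list[tuple[str, str]]]:
    """Group reads by expected fragment size: assigned iff
    |len - size| <= rel_tol * size; ambiguous reads go to the nearer size,
    ties to the smaller size."""
    if not (0.0 <= rel_tol < 0.5):
        raise SnrcmError("rel_tol must be in [0, 0.5)")
    groups: dict[int, list[tuple[str, str]]] = {s: [] for s in expected_sizes_bp}
    for rid, seq in reads:
        n = len(seq)
        ok = [s for s in expected_sizes_bp if abs(n - s) <= rel_tol * s]
        if not ok:
            continue
        ok.sort(key=lambda s: (abs(n - s), s))
        groups[ok[0]].append((rid, seq))
    return groups


def verify_assembly(read_groups: dict[int, list[tuple[str, str]]],
                    reference_fragments: dict[int, str],
                    params: ContainmentParams | None = None) -> AssemblyVerification:
    """Call each reference fragment covered iff some size-matched read
    contains it completely (same containment criterion as the miner)."""
    params = params or ContainmentParams()
    verdicts = []
    for size, ref_seq in sorted(reference_fragments.items()):
        reads = read_groups.get(size, [])
        if not reads:
            verdicts.append(FragmentVerdict(fragment_id=f"fragment_{size}", covered=False,
                                            covered_fraction=0.0, identity=0.0, best_read_id=None))
            continue
        v = mine_single_read_containment(ref_seq, reads, params)
        verdicts.append(FragmentVerdict(
            fragment_id=f"fragment_{size}", covered=v.call == CALL_COMPLETE,
            covered_fraction=v.covered_fraction, identity=v.identity, best_read_id=v.best_read_id,
        ))
    return AssemblyVerification(passed=all(v.covered for v in verdicts), fragments=verdicts)
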