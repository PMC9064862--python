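"""Synthetic study system: metagenome fragments with planted BGCs, a pooled
fosmid library, and simulated long/short reads with full ground truth.

The generator emulates the sampling regime of a real soil-metagenome fosmid
library at desk scale: a small community of large DNA fragments, clones of
30-45 kb inserts in an ~8 kb vector stored in pools, long reads whose length
is capped by the clone molecule, and planted clusters of known class and
coordinates.  One deliberately oversized (~58 kb) NRPS-like cluster cannot
fit a single insert; its host fragment is sampled only by three designated
overlapping clones, emulating the sparse per-locus clone coverage of a real
library and guaranteeing the cluster is split across three inserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .util import SnrcmError, decode, derive_seed, encode, random_dna, revcomp

# single-codon encoding used when synthesizing ORFs from designed proteins
_AA_CODON = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAG",
    "E": "GAA", "G": "GGC", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTC", "P": "CCG", "S": "AGC", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTC",
}
_NEUTRAL_AA = "NQHIKFWYRV"  # avoids donor/acceptor/minus-2 residues
_SAFE_CODONS = [c for a, c in _AA_CODON.items()]

SINGLE_INSERT_CLASSES = ("lasso", "bacteriocin", "betalactone", "LAP", "lanthipeptide", "terpene")


class GeometryError(SnrcmError):
    """A requested cluster cannot be placed in its host fragment."""


@dataclass
class BGCSpec:
    class_label: str
    length_bp: int
    a_gene_route: str = "domain"  # lasso only: "domain" or "scan" evidence for the A gene
    with_transporter: bool = False


@dataclass
class GeneRecord:
    label: str
    strand: str
    length_bp: int
    start: int  # relative to the BGC region, 0-based half-open
    end: int


@dataclass
class PlantedBGC:
    bgc_id: str
    class_label: str
    fragment_id: str
    start: int
    end: int
    gene_layout: list[GeneRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulationConfig:
    n_fragments: int = 6
    fragment_len_bp: tuple[int, int] = (70_000, 100_000)
    gc_frac: float = 0.60
    n_clones: int = 500
    pool_size: int = 2000
    insert_len_bp: tuple[int, int] = (30_000, 45_000)
    vector_len_bp: int = 8139
    long_read_error: dict = field(default_factory=lambda: {"sub": 0.03, "ins": 0.01, "del": 0.01})
    long_read_len: dict = field(default_factory=lambda: {"median_bp": 12_000, "sigma": 0.55, "min_bp": 1_000})
    long_read_coverage: float = 20.0
    short_read_len: int = 150
    short_read_coverage: float = 0.0
    short_insert_mean: float = 400.0
    short_insert_sd: float = 40.0
    short_read_error: dict = field(default_factory=lambda: {"sub": 0.001, "ins": 0.0, "del": 0.0})
    seed: int = 7
    bgc_plan: list[BGCSpec] = field(default_factory=lambda: [
        BGCSpec("lasso", 4_200, a_gene_route="domain", with_transporter=True),
        BGCSpec("lasso", 5_000, a_gene_route="scan"),
        BGCSpec("bacteriocin", 6_000),
        BGCSpec("terpene", 9_000),
        BGCSpec("lanthipeptide", 12_000),
        BGCSpec("NRPS-like", 58_000),
    ])

    def validate(self) -> None:
        for name, rates in (("long_read_error", self.long_read_error),
                            ("short_read_error", self.short_read_error)):
            for key in ("sub", "ins", "del"):
                r = rates.get(key, 0.0)
                if not (0.0 <= r < 1.0):
                    raise SnrcmError(f"{name}[{key}]={r} outside [0, 1)")
        if self.insert_len_bp[0] < 1_000:
            raise SnrcmError("minimum insert length must be >= 1 kb")
        if self.insert_len_bp[0] > self.insert_len_bp[1]:
            raise SnrcmError("insert_len_bp range inverted")
        if self.pool_size < 1:
            raise SnrcmError("pool_size must be >= 1")
        if self.n_fragments < len(self.bgc_plan):
            raise SnrcmError("need at least one fragment per planted BGC")
        if not (0.0 < self.gc_frac < 1.0):
            raise SnrcmError("gc_frac must be in (0, 1)")


@dataclass
class FosmidClone:
    clone_id: str
    pool_id: int
    fragment_id: str
    insert_interval: tuple[int, int]
    insert_strand: str
    full_sequence: str
    designated_for: str | None = None  # bgc_id when planted deliberately

    @property
    def insert_length(self) -> int:
        return self.insert_interval[1] - self.insert_interval[0]


@dataclass
class LongRead:
    read_id: str
    clone_id: str
    true_interval: tuple[int, int]  # on the clone's circular full_sequence; end>len means wrap
    strand: str
    sequence: str
    errors_applied: dict
    truncated: bool = False
    wraps_junction: bool = False


@dataclass
class Community:
    config: SimulationConfig
    fragments: dict[str, str]
    bgcs: list[PlantedBGC]
    evidence: pd.DataFrame  # gene evidence rows for lasso clusters


# --------------------------------------------------------------- gene builders

def _random_orf(rng: np.random.Generator, size_bp: int) -> str:
    if size_bp % 3 or size_bp < 9:
        raise SnrcmError("ORF size must be a positive multiple of 3 (>=9)")
    n_codons = size_bp // 3 - 2
    body = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


def _precursor_orf(rng: np.random.Generator) -> str:
    """141 bp ORF encoding a textbook lasso precursor: 24-aa leader with Thr
    at -2, Gly ring donor, Asp acceptor at ring position 8, 14-aa tail."""
    rand = lambda n: "".join(rng.choice(list(_NEUTRAL_AA)) for _ in range(n))
    leader = "M" + rand(21) + "T" + rand(1)
    core = "G" + rand(6) + "D" + rand(14)
    aa = leader + core
    return "".join(_AA_CODON[a] for a in aa) + "TAA"


def _lasso_cassette(rng: np.random.Generator, a_route: str, with_d: bool,
                    gc: float) -> tuple[str, list[GeneRecord], list[dict]]:
    genes = [
        ("A", _precursor_orf(rng)),
        ("B1", _random_orf(rng, 294)),
        ("B2", _random_orf(rng, 423)),
        ("C", _random_orf(rng, 1905)),
    ]
    if with_d:
        genes.append(("D", _random_orf(rng, 822)))
    seq_parts, layout, evidence = [], [], []
    pos = 0
    for label, dna in genes:
        spacer = random_dna(rng, int(rng.integers(25, 61)), gc)
        seq_parts.append(spacer)
        pos += len(spacer)
        layout.append(GeneRecord(label=label, strand="+", length_bp=len(dna), start=pos, end=pos + len(dna)))
        seq_parts.append(dna)
        pos += len(dna)
        desc, dom = {
            "A": ("Hypothetical protein", "Predicted lasso peptide" if a_route == "domain" else "-"),
            "B1": ("PqqD family peptide modification chaperone", "PF05402"),
            "B2": ("Lasso peptide biosynthesis B2 protein", "PF13471"),
            "C": ("Asparagine synthetase B", "Asn_synthase"),
            "D": ("ABC transporter permease", "-"),
        }[label]
        evidence.append({"gene_id": label.lower(), "size_bp": len(dna),
                         "description": desc, "domain_tag": dom, "label_truth": label})
    return "".join(seq_parts), layout, evidence


def _generic_layout(rng: np.random.Generator, class_label: str, region_len: int) -> list[GeneRecord]:
    if class_label == "NRPS-like":
        sizes = [15_000, 18_000, 12_000, 6_000]
    else:
        sizes = [int(rng.integers(600, 2400)) for _ in range(max(2, region_len // 2500))]
    layout, pos = [], 100
    for i, s in enumerate(sizes):
        if pos + s > region_len - 100:
            break
        layout.append(GeneRecord(label=f"orf{i + 1}", strand="+" if rng.random() < 0.7 else "-",
                                 length_bp=s, start=pos, end=pos + s))
        pos += s + int(rng.integers(50, 200))
    return layout


# ------------------------------------------------------------------ community

def generate_community(config: SimulationConfig) -> Community:
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "community"))
    lo, hi = config.fragment_len_bp
    frag_lens = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_fragments)]
    fragments = {f"fragment_{i:03d}": random_dna(rng, fl, config.gc_frac)
                 for i, fl in enumerate(frag_lens)}

    # largest cluster to largest fragment, one dedicated fragment per BGC
    frag_ids_by_len = sorted(fragments, key=lambda f: -len(fragments[f]))
    plan_order = sorted(range(len(config.bgc_plan)), key=lambda i: -config.bgc_plan[i].length_bp)

    bgcs: list[PlantedBGC] = []
    evidence_rows: list[dict] = []
    oversized_margin = 8_000
    for rank, plan_idx in enumerate(plan_order):
        spec = config.bgc_plan[plan_idx]
        frag_id = frag_ids_by_len[rank]
        frag = fragments[frag_id]
        margin = oversized_margin if spec.length_bp > config.insert_len_bp[1] else 4_000
        if spec.length_bp + 2 * margin > len(frag):
            raise GeometryError(
                f"BGC bgc_{plan_idx:02d} ({spec.class_label}, {spec.length_bp} bp) does not fit "
                f"fragment {frag_id} ({len(frag)} bp) with {margin} bp margins"
            )
        start = int(rng.integers(margin, len(frag) - spec.length_bp - margin + 1))
        bgc_id = f"bgc_{plan_idx:02d}_{spec.class_label}"
        if spec.class_label == "lasso":
            cassette, layout, ev = _lasso_cassette(rng, spec.a_gene_route, spec.with_transporter,
                                                  config.gc_frac)
            if len(cassette) > spec.length_bp:
                raise GeometryError(f"{bgc_id}: requested length {spec.length_bp} smaller than gene cassette")
            region = cassette + random_dna(rng, spec.length_bp - len(cassette), config.gc_frac)
            fragments[frag_id] = frag[:start] + region + frag[start + spec.length_bp:]
            for row in ev:
                row.update(bgc_id=bgc_id, gene_id=f"{bgc_id}:{row['gene_id']}")
            evidence_rows.extend(ev)
        else:
            layout = _generic_layout(rng, spec.class_label, spec.length_bp)
        bgcs.append(PlantedBGC(bgc_id=bgc_id, class_label=spec.class_label, fragment_id=frag_id,
                               start=start, end=start + spec.length_bp, gene_layout=layout))
    bgcs.sort(key=lambda b: b.bgc_id)
    evidence = pd.DataFrame(evidence_rows,
                            columns=["bgc_id", "gene_id", "size_bp", "description",
                                     "domain_tag", "label_truth"])
    return Community(config=config, fragments=fragments, bgcs=bgcs, evidence=evidence)


# -------------------------------------------------------------------- library

def load_vector() -> str:
    text = resources.files("snrcm").joinpath("data/vector_backbone_synthetic.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def fits_single_insert(bgc: PlantedBGC, config: SimulationConfig) -> bool:
    return bgc.length <= config.insert_len_bp[1]


def _trio_intervals(rng: np.random.Generator, bgc: PlantedBGC, frag_len: int,
                    insert_min: int) -> list[tuple[int, int]]:
    """Three inserts tiling an oversized cluster such that no two cover it."""
    s, e = bgc.start, bgc.end
    L = e - s
    reach1 = s + int(0.42 * L) + int(rng.integers(-800, 801))
    start3 = s + int(0.58 * L) + int(rng.integers(-800, 801))
    c1 = (reach1 - insert_min, reach1)
    c2_start = reach1 - 3_000
    c2 = (c2_start, c2_start + insert_min)
    c3 = (start3, start3 + insert_min)
    for lo_, hi_ in (c1, c2, c3):
        if lo_ < 0 or hi_ > frag_len:
            raise GeometryError(f"{bgc.bgc_id}: fragment too short for a 3-clone tiling")
    if c1[0] > s or c3[1] < e or not (c1[1] < c3[0] and s < c2[0] and c2[1] < e):
        raise GeometryError(f"{bgc.bgc_id}: insert length range cannot yield a 3-clone-minimum tiling")
    return [c1, c2, c3]


def build_fosmid_library(community: Community, config: SimulationConfig | None = None) -> list[FosmidClone]:
    config = config or community.config
    rng = np.random.default_rng(derive_seed(config.seed, "library"))
    vector = load_vector() if config.vector_len_bp == 8139 else random_dna(
        np.random.default_rng(derive_seed(config.seed, "vector")), config.vector_len_bp, 0.5)

    imin, imax = config.insert_len_bp
    oversized = [b for b in community.bgcs if not fits_single_insert(b, config)]
    oversized_frags = {b.fragment_id for b in oversized}
    eligible = [f for f in community.fragments
                if f not in oversized_frags and len(community.fragments[f]) >= imin]

    planned: list[tuple[str, tuple[int, int], str]] = []  # (fragment, interval, bgc_id)
    for b in oversized:
        for iv in _trio_intervals(rng, b, len(community.fragments[b.fragment_id]), imin):
            planned.append((b.fragment_id, iv, b.bgc_id))
    for b in community.bgcs:
        if b in oversized:
            continue
        frag_len = len(community.fragments[b.fragment_id])
        ilen = int(rng.integers(imin, min(imax, frag_len) + 1))
        lo_ = max(0, b.end - ilen)
        hi_ = min(frag_len - ilen, b.start)
        start = int(rng.integers(lo_, hi_ + 1))
        planned.append((b.fragment_id, (start, start + ilen), b.bgc_id))

    if len(planned) > config.n_clones:
        raise SnrcmError("n_clones too small for the planted-clone plan")
    if config.n_clones > len(planned) and not eligible:
        raise SnrcmError("insert length range exceeds every available fragment")

    weights = np.array([len(community.fragments[f]) for f in eligible], dtype=float)
    if eligible:
        weights /= weights.sum()
    clones: list[FosmidClone] = []
    for i in range(config.n_clones):
        if i < len(planned):
            frag_id, (start, end), designated = planned[i]
            ilen = end - start
        else:
            frag_id = eligible[int(rng.choice(len(eligible), p=weights))]
            frag_len = len(community.fragments[frag_id])
            ilen = int(rng.integers(imin, min(imax, frag_len) + 1))
            start = int(rng.integers(0, frag_len - ilen + 1))
            end = start + ilen
            designated = None
        strand = "+" if rng.random() < 0.5 else "-"
        insert = community.fragments[frag_id][start:end]
        if strand == "-":
            insert = revcomp(insert)
        clones.append(FosmidClone(
            clone_id=f"clone_{i:05d}", pool_id=i // config.pool_size, fragment_id=frag_id,
            insert_interval=(start, end), insert_strand=strand,
            full_sequence=vector + insert, designated_for=designated,
        ))
    return clones


# ---------------------------------------------------------------------- reads

def _apply_errors(codes: np.ndarray, rates: dict, rng: np.random.Generator):
    """Substitutions first, then deletions, then insertions (documented order
    so oracles can replay); positions drawn without replacement per category."""
    n = codes.size
    out = codes.copy()
    n_sub = int(rng.binomial(n, rates.get("sub", 0.0))) if rates.get("sub", 0.0) > 0 else 0
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_sub)) % 4
    n_del = int(rng.binomial(n, rates.get("del", 0.0))) if rates.get("del", 0.0) > 0 else 0
    if n_del:
        pos = rng.choice(n, size=n_del, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[pos] = False
        out = out[keep]
    n_ins = int(rng.binomial(n, rates.get("ins", 0.0))) if rates.get("ins", 0.0) > 0 else 0
    if n_ins:
        pos = np.sort(rng.choice(out.size + 1, size=n_ins, replace=True))
        out = np.insert(out, pos, rng.integers(0, 4, size=n_ins).astype(np.uint8))
    return out, {"sub": n_sub, "ins": n_ins, "del": n_del}


def simulate_long_reads(clones: list[FosmidClone], config: SimulationConfig,
                        seed: int | None = None) -> tuple[list[LongRead], pd.DataFrame]:
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed if seed is None else seed, "long_reads"))
    lr = config.long_read_len
    mu = np.log(lr["median_bp"])
    reads: list[LongRead] = []
    rows = []
    for clone in clones:
        mol = encode(clone.full_sequence)
        mol_len = mol.size
        target = config.long_read_coverage * mol_len
        drawn = 0.0
        while drawn < target:
            raw = int(rng.lognormal(mean=mu, sigma=lr["sigma"]))
            truncated = raw > mol_len
            length = min(max(raw, lr["min_bp"]), mol_len)
            start = int(rng.integers(0, mol_len))
            strand = "+" if rng.random() < 0.5 else "-"
            idx = (start + np.arange(length)) % mol_len
            true_codes = mol[idx]
            if strand == "-":
                true_codes = (3 - true_codes)[::-1]
            obs, counts = _apply_errors(true_codes, config.long_read_error, rng)
            rid = f"read_{len(reads):06d}"
            reads.append(LongRead(
                read_id=rid, clone_id=clone.clone_id, true_interval=(start, start + length),
                strand=strand, sequence=decode(obs), errors_applied=counts,
                truncated=truncated, wraps_junction=start + length > mol_len,
            ))
            rows.append((rid, clone.clone_id, start, start + length, strand,
                         counts["sub"], counts["ins"], counts["del"],
                         truncated, start + length > mol_len))
            drawn += length
    truth = pd.DataFrame(rows, columns=["read_id", "clone_id", "start", "end", "strand",
                                        "n_sub", "n_ins", "n_del", "truncated", "wraps_junction"])
    return reads, truth


def long_reads_to_fastq_records(reads: list[LongRead]):
    q = chr(33 + 13)
    for r in reads:
        yield r.read_id, r.sequence, q * len(r.sequence)


def simulate_short_reads(clones: list[FosmidClone], config: SimulationConfig,
                         seed: int | None = None) -> tuple[list[tuple], pd.DataFrame]:
    """Paired short reads; returns (records, truth).  Records are
    (read_id, r1_seq, r1_qual, r2_seq, r2_qual); pair counts are the
    deterministic coverage formula round(cov * len / (2 * read_len))."""
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed if seed is None else seed, "short_reads"))
    rl = config.short_read_len
    recs, rows = [], []
    q = "I" * rl
    for clone in clones:
        mol = encode(clone.full_sequence)
        mol_len = mol.size
        n_pairs = int(round(config.short_read_coverage * mol_len / (2 * rl)))
        for _ in range(n_pairs):
            ins = int(np.clip(rng.normal(config.short_insert_mean, config.short_insert_sd),
                              rl + 10, mol_len))
            start = int(rng.integers(0, mol_len))
            idx = (start + np.arange(ins)) % mol_len
            frag = mol[idx]
            r1, c1 = _apply_errors(frag[:rl], config.short_read_error, rng)
            r2, c2 = _apply_errors((3 - frag[-rl:])[::-1], config.short_read_error, rng)
            rid = f"pair_{len(recs):06d}"
            recs.append((rid, decode(r1), q[: r1.size].ljust(r1.size, "I"),
                         decode(r2), q[: r2.size].ljust(r2.size, "I")))
            rows.append((rid, clone.clone_id, start, start + ins,
                         c1["sub"] + c2["sub"], c1["ins"] + c2["ins"], c1["del"] + c2["del"]))
    truth = pd.DataFrame(rows, columns=["pair_id", "clone_id", "start", "end",
                                        "n_sub", "n_ins", "n_del"])
    return recs, truth
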