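"""Rule-based lasso peptide BGC annotation.

Lasso peptide clusters carry a small, characteristic gene set: the precursor
peptide (A), the leader-recognition/protease pair (B1, PqqD-like/PF05402 and
B2, PF13471), the macrolactam-forming asparagine-synthetase homolog (C), and
often an ABC-transporter (D) linked to self-resistance.  This module
classifies tabular gene evidence (BLAST-style description, gene size, domain
tag) into those labels, scans DNA for precursor-peptide ORFs with lasso
hallmarks (Gly-1 ring donor, Asp/Glu acceptor 7-9 residues downstream, a
cleavable leader with a Thr-like residue at position -2), and checks the
minimal-set completeness A + B + C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio.Seq import Seq

from .util import SnrcmError, revcomp

LABELS = ("B2", "B1", "C", "D", "A")  # precedence order on multi-match


@dataclass
class GeneEvidence:
    gene_id: str
    size_bp: int
    description_text: str = ""
    domain_tag: str = ""
    precursor_pass: bool = False  # result of a precursor scan over the gene, if run

    def __post_init__(self):
        if self.size_bp <= 0:
            raise SnrcmError(f"gene {self.gene_id}: size_bp must be positive")


@dataclass
class LassoLabel:
    gene_id: str
    label: str  # A, B1, B2, C, D or none
    rationale_codes: list[str] = field(default_factory=list)


@dataclass
class LassoCompleteness:
    present_labels: set[str]
    status: str  # complete | incomplete
    missing: set[str]
    has_transporter: bool


# ------------------------------------------------------------- classification

def load_rules(path=None) -> dict:
    """Keyword/size rule table; packaged default unless a YAML path is given."""
    if path is None:
        text = resources.files("snrcm").joinpath("data/lasso_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = yaml.safe_load(text)
    return rules["labels"]


_DEFAULT_RULES: dict | None = None


def _default_rules() -> dict:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def classify_gene(evidence: GeneEvidence, rules: dict | None = None) -> LassoLabel:
    """Assign one lasso gene label; ties resolved by B2 > B1 > C > D > A."""
    rules = rules or _default_rules()
    desc = evidence.description_text.lower()
    domain = evidence.domain_tag.lower()
    fired: list[str] = []
    for label in LABELS:
        rule = rules[label]
        lo, hi = rule["size_bp"]
        if not (lo <= evidence.size_bp <= hi):
            continue
        dom_hit = any(re.search(p.lower(), domain) for p in rule.get("domain_patterns", []))
        desc_hit = any(re.search(p.lower(), desc) for p in rule.get("desc_patterns", []))
        if dom_hit or desc_hit:
            fired.append(f"{label}:{'domain' if dom_hit else 'description'}")
        elif label == "A" and rule.get("allow_precursor_scan") and evidence.precursor_pass:
            fired.append("A:size+precursor_scan")
    if not fired:
        return LassoLabel(gene_id=evidence.gene_id, label="none", rationale_codes=[])
    return LassoLabel(gene_id=evidence.gene_id, label=fired[0].split(":")[0], rationale_codes=fired)


def assess_completeness(labels: list[LassoLabel]) -> LassoCompleteness:
    """Minimal-set check: complete iff A, C and B (B1+B2 or a fused B) present."""
    present = {l.label for l in labels if l.label != "none"}
    fused_b = any(
        {"B1", "B2"} <= {code.split(":")[0] for code in l.rationale_codes} for l in labels
    )
    have_b = ({"B1", "B2"} <= present) or fused_b
    missing = set()
    if "A" not in present:
        missing.add("A")
    if "C" not in present:
        missing.add("C")
    if not have_b:
        missing |= {"B1", "B2"} - present
    status = "complete" if not missing else "incomplete"
    return LassoCompleteness(present_labels=present, status=status, missing=missing,
                             has_transporter="D" in present)


# ------------------------------------------------------------ precursor scan

@dataclass
class PrecursorScanConfig:
    strict_donor: bool = True
    strict_donor_set: str = "G"
    relaxed_donor_set: str = "GASC"
    acceptor_residues: str = "DE"
    ring_positions: tuple[int, ...] = (7, 8, 9)  # 1-based acceptor position in core
    min_tail_aa: int = 3
    min_leader_aa: int = 8
    minus2_residues: str = "TSLACVI"
    min_orf_aa: int = 20
    max_orf_aa: int = 70

    def donor_residues(self) -> str:
        return self.strict_donor_set if self.strict_donor else self.relaxed_donor_set


@dataclass
class PrecursorCandidate:
    orf_interval: tuple[int, int]  # 0-based half-open on the scanned region
    strand: str
    aa_sequence: str
    leader_seq: str
    core_seq: str
    ring_donor_pos: int  # index in core; always 0
    ring_acceptor_pos: int  # index in core
    tail_len_aa: int
    minus2_residue: str

    def sort_key(self) -> tuple:
        return (
            self.core_seq[0] != "G",
            self.core_seq[self.ring_acceptor_pos] != "D",
            self.minus2_residue != "T",
            self.tail_len_aa,
            self.orf_interval,
            self.strand,
            self.ring_acceptor_pos,
        )

    def key(self) -> tuple:
        return (*self.orf_interval, self.strand, len(self.leader_seq), self.ring_acceptor_pos)


_START = ("ATG", "GTG", "TTG")
_STOP = ("TAA", "TAG", "TGA")


def _orfs(dna: str, min_aa: int, max_aa: int):
    """Yield (start, end, strand, protein) for every start codon paired with
    its first in-frame stop, both strands, 0-based half-open on `dna`."""
    n = len(dna)
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
        for p in range(0, n - 2):
            if seq[p : p + 3] in _STOP:
                stops_by_frame[p % 3].append(p)
        for p in range(0, n - 2):
            if seq[p : p + 3] not in _START:
                continue
            frame_stops = stops_by_frame[p % 3]
            stop = next((s for s in frame_stops if s > p), None)
            if stop is None:
                continue
            aa_len = (stop - p) // 3
            if not (min_aa <= aa_len <= max_aa):
                continue
            protein = "M" + str(Seq(seq[p + 3 : stop]).translate())
            if strand == "+":
                yield p, stop + 3, strand, protein
            else:
                yield n - (stop + 3), n - p, strand, protein


def scan_precursors(dna_region: str, config: PrecursorScanConfig | None = None) -> list[PrecursorCandidate]:
    """Enumerate precursor-peptide candidates in a DNA region.

    All (leader/core split, ring acceptor) combinations satisfying the rules
    are reported, ranked by (strict Gly donor, Asp over Glu acceptor, Thr at
    -2, shorter tail); nothing is silently discarded.
    """
    config = config or PrecursorScanConfig()
    if len(dna_region) < 60:
        raise SnrcmError("region shorter than 60 bp cannot hold a precursor ORF")
    donors = set(config.donor_residues())
    out = []
    for s0, e0, strand, aa in _orfs(dna_region, config.min_orf_aa, config.max_orf_aa):
        for split in range(config.min_leader_aa, len(aa)):
            leader, core = aa[:split], aa[split:]
            if core[0] not in donors or leader[-2] not in config.minus2_residues:
                continue
            for ring_pos in config.ring_positions:
                idx = ring_pos - 1
                if idx >= len(core) or core[idx] not in config.acceptor_residues:
                    continue
                tail = len(core) - idx - 1
                if tail < config.min_tail_aa:
                    continue
                out.append(
                    PrecursorCandidate(
                        orf_interval=(s0, e0), strand=strand, aa_sequence=aa,
                        leader_seq=leader, core_seq=core, ring_donor_pos=0,
                        ring_acceptor_pos=idx, tail_len_aa=tail, minus2_residue=leader[-2],
                    )
                )
    out.sort(key=PrecursorCandidate.sort_key)
    return out
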