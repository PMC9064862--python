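"""End-to-end driver: simulate -> mine -> annotate -> plan recovery -> plan
tiling assembly -> verify, with a run manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containment import (CALL_COMPLETE, Contig, ContainmentParams, filter_contigs,
                          import_regions, mine_regions, summarize_by_class)
from .dilution import DilutionParams, default_protocol, simulate_recovery
from .lasso import GeneEvidence, PrecursorScanConfig, assess_completeness, classify_gene, scan_precursors
from .seqio import GffRecord, write_fasta, write_fastq, write_gff3, write_tsv
from .simulate import (Community, SimulationConfig, build_fosmid_library, fits_single_insert,
                       generate_community, long_reads_to_fastq_records, simulate_long_reads,
                       simulate_short_reads, _apply_errors)
from .tiling import (FosmidAlignment, choose_release_enzyme, find_tiling_path, size_filter_reads,
                     verify_assembly)
from .util import SnrcmError, decode, derive_seed, encode, random_dna, sha256_file

STAGES = ("simulate", "mine", "annotate", "plan_dilution", "plan_tar", "verify")
_DEPS = {
    "mine": ("simulate",),
    "annotate": ("simulate",),
    "plan_dilution": ("simulate", "mine"),
    "plan_tar": ("simulate", "mine"),
    "verify": ("simulate", "plan_tar"),
}


@dataclass
class PipelineConfig:
    out_dir: str = "snrcm_run"
    seed: int = 7
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    containment: ContainmentParams = field(default_factory=ContainmentParams)
    dilution: DilutionParams = field(default_factory=DilutionParams)
    min_contig_len_bp: int = 40_000
    n_tubes: int = 16
    min_overlap_bp: int = 500
    size_filter_tol: float = 0.10
    tar_vector_len_bp: int = 15_061
    verify_reads_per_fragment: int = 80
    write_long_reads: bool = False
    write_short_reads: bool = False

    def __post_init__(self):
        # the pipeline seed overrides the simulation seed so one knob controls a run
        self.sim.seed = self.seed

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        nested = {"sim": SimulationConfig, "containment": ContainmentParams, "dilution": DilutionParams}
        top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
        for key, value in data.items():
            if key not in top_fields:
                raise SnrcmError(f"unknown config key {key!r}")
            if key in nested and isinstance(value, dict):
                sub_fields = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(value) - sub_fields
                if bad:
                    raise SnrcmError(f"unknown config key {key}.{sorted(bad)[0]}")
                if key == "sim" and "bgc_plan" in value:
                    from .simulate import BGCSpec
                    value = dict(value)
                    value["bgc_plan"] = [BGCSpec(**b) for b in value["bgc_plan"]]
                if key == "sim":
                    for tup in ("fragment_len_bp", "insert_len_bp"):
                        if tup in value:
                            value[tup] = tuple(value[tup])
                kwargs[key] = nested[key](**value)
            elif key == "stages":
                bad = set(value) - set(STAGES)
                if bad:
                    raise SnrcmError(f"unknown stage {sorted(bad)[0]!r}")
                stages = {s: True for s in STAGES}
                stages.update(value)
                kwargs[key] = stages
            else:
                kwargs[key] = value
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def demo_config(out_dir: str = "snrcm_demo", seed: int = 7) -> PipelineConfig:
    """The packaged demo: ~500 clones, 20x long-read coverage, 5% error,
    six planted BGCs of which five fit a single insert and one (~58 kb
    NRPS-like) spans three inserts."""
    return PipelineConfig(out_dir=out_dir, seed=seed)


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {status, outputs{path: sha256}, ...}
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    community: Community | None = None
    clones: list | None = None
    long_reads: list | None = None
    read_truth: pd.DataFrame | None = None
    regions: list | None = None
    verdicts: list | None = None
    summary: dict | None = None
    lasso_reports: list | None = None
    recovery: dict | None = None
    tiling: dict | None = None
    digest: dict | None = None
    verification: dict | None = None


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _truth_gff(community: Community) -> list[GffRecord]:
    records = []
    for b in community.bgcs:
        records.append(GffRecord(seqid=b.fragment_id, type="region", start=b.start, end=b.end,
                                 strand="+", attributes={"ID": b.bgc_id, "class": b.class_label}))
        for g in b.gene_layout:
            records.append(GffRecord(seqid=b.fragment_id, type="gene",
                                     start=b.start + g.start, end=b.start + g.end, strand=g.strand,
                                     attributes={"ID": f"{b.bgc_id}:{g.label}", "Parent": b.bgc_id,
                                                 "label": g.label}))
    return records


def preflight(config: PipelineConfig) -> None:
    for stage, deps in _DEPS.items():
        if config.stages.get(stage):
            for dep in deps:
                if not config.stages.get(dep):
                    raise SnrcmError(
                        f"stage {stage!r} is enabled but its input stage {dep!r} is disabled "
                        "and no precomputed inputs are supported for it")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool_version=__version__, config_hash=_config_hash(config),
                           seed=config.seed, started=time.time())
    result = PipelineResult(manifest=manifest)

    def record(stage: str, files: list[Path], **extra):
        manifest.stages[stage] = {
            "status": "ok",
            "outputs": {str(p.relative_to(out)): sha256_file(p) for p in files},
            **extra,
        }

    def fail(stage: str, exc: Exception):
        manifest.stages[stage] = {"status": "failed", "error": str(exc)}
        manifest.finished = time.time()
        (out / "manifest.json").write_text(manifest.to_json())

    try:
        if config.stages.get("simulate"):
            _stage_simulate(config, out, result, record)
        if config.stages.get("mine"):
            _stage_mine(config, out, result, record)
        if config.stages.get("annotate"):
            _stage_annotate(config, out, result, record)
        if config.stages.get("plan_dilution"):
            _stage_plan_dilution(config, out, result, record)
        if config.stages.get("plan_tar"):
            _stage_plan_tar(config, out, result, record)
        if config.stages.get("verify"):
            _stage_verify(config, out, result, record)
    except Exception as exc:  # noqa: BLE001 - stage failures are reported, not swallowed
        running = next((s for s in STAGES if s not in manifest.stages and config.stages.get(s)),
                       "unknown")
        fail(running, exc)
        raise
    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return result


# ------------------------------------------------------------------- stages

def _stage_simulate(config, out, result, record):
    community = generate_community(config.sim)
    clones = build_fosmid_library(community, config.sim)
    reads, truth = simulate_long_reads(clones, config.sim)
    result.community, result.clones = community, clones
    result.long_reads, result.read_truth = reads, truth

    files = []
    p = out / "fragments.fasta"
    write_fasta(p, community.fragments)
    files.append(p)
    p = out / "truth_regions.gff3"
    write_gff3(p, _truth_gff(community))
    files.append(p)
    p = out / "clones.tsv"
    write_tsv(p, pd.DataFrame(
        [(c.clone_id, c.pool_id, c.fragment_id, *c.insert_interval, c.insert_strand,
          c.designated_for or "") for c in clones],
        columns=["clone_id", "pool_id", "fragment_id", "insert_start", "insert_end",
                 "insert_strand", "designated_for"]),
        comment=f"snrcm {__version__} fosmid clone table")
    files.append(p)
    p = out / "long_read_truth.tsv"
    write_tsv(p, truth, comment=f"snrcm {__version__} long-read ground truth")
    files.append(p)
    if not community.evidence.empty:
        p = out / "gene_evidence.tsv"
        write_tsv(p, community.evidence, comment=f"snrcm {__version__} planted lasso gene evidence")
        files.append(p)
    if config.write_long_reads:
        p = out / "long_reads.fastq"
        write_fastq(p, long_reads_to_fastq_records(reads))
        files.append(p)
    if config.write_short_reads and config.sim.short_read_coverage > 0:
        pairs, _ = simulate_short_reads(clones, config.sim)
        p1, p2 = out / "short_reads_R1.fastq", out / "short_reads_R2.fastq"
        write_fastq(p1, ((rid + "/1", s1, q1) for rid, s1, q1, _s2, _q2 in pairs))
        write_fastq(p2, ((rid + "/2", s2, q2) for rid, _s1, _q1, s2, q2 in pairs))
        files += [p1, p2]
    record("simulate", files, n_clones=len(clones), n_long_reads=len(reads))


def _stage_mine(config, out, result, record):
    community = result.community
    contigs = [Contig(contig_id=k, sequence=v) for k, v in community.fragments.items()]
    kept = filter_contigs(contigs, config.min_contig_len_bp)
    contig_map = {c.contig_id: c.sequence for c in kept}
    regions = import_regions(out / "truth_regions.gff3", contig_map)
    read_pairs = [(r.read_id, r.sequence) for r in result.long_reads]
    verdicts = mine_regions(regions, contig_map, read_pairs, config.containment)
    summary_counts = summarize_by_class(verdicts, regions)

    single = [b.bgc_id for b in community.bgcs if fits_single_insert(b, config.sim)]
    complete_ids = {v.region_id for v in verdicts if v.call == CALL_COMPLETE}
    recall = sum(1 for b in single if b in complete_ids) / len(single) if single else float("nan")
    summary = {
        "complete_by_class": summary_counts,
        "n_regions": len(regions),
        "n_complete": len(complete_ids),
        "single_insert_bgcs": len(single),
        "single_insert_recall": recall,
    }
    result.regions, result.verdicts, result.summary = regions, verdicts, summary

    p1 = out / "verdicts.tsv"
    write_tsv(p1, pd.DataFrame(
        [(v.region_id, v.call, v.best_read_id or "", v.covered_fraction, v.identity, v.strand,
          ",".join(v.supporting_reads)) for v in verdicts],
        columns=["region_id", "call", "best_read_id", "covered_fraction", "identity",
                 "strand", "supporting_reads"]),
        comment=f"snrcm {__version__} containment verdicts")
    p2 = out / "mine_summary.json"
    p2.write_text(json.dumps(summary, indent=2, sort_keys=True))
    record("mine", [p1, p2], **{k: v for k, v in summary.items() if k != "complete_by_class"})


def _stage_annotate(config, out, result, record):
    community = result.community
    scan_cfg = PrecursorScanConfig()
    reports = []
    for b in community.bgcs:
        if b.class_label != "lasso":
            continue
        frag = community.fragments[b.fragment_id]
        region_seq = frag[b.start:b.end]
        rows = community.evidence[community.evidence.bgc_id == b.bgc_id]
        labels = []
        for _, row in rows.iterrows():
            scan_pass = False
            gene = next(g for g in b.gene_layout if f":{g.label.lower()}" in row.gene_id
                        or g.label == row.label_truth)
            if row.domain_tag in ("-", "") and row.size_bp <= 210:
                gene_dna = region_seq[max(0, gene.start - 30): gene.end + 30]
                scan_pass = bool(scan_precursors(gene_dna, scan_cfg))
            ev = GeneEvidence(gene_id=row.gene_id, size_bp=int(row.size_bp),
                              description_text=row.description, domain_tag=row.domain_tag,
                              precursor_pass=scan_pass)
            labels.append(classify_gene(ev))
        completeness = assess_completeness(labels)
        candidates = scan_precursors(region_seq, scan_cfg)
        reports.append({
            "bgc_id": b.bgc_id,
            "labels": {l.gene_id: l.label for l in labels},
            "status": completeness.status,
            "missing": sorted(completeness.missing),
            "has_transporter": completeness.has_transporter,
            "n_precursor_candidates": len(candidates),
        })
    result.lasso_reports = reports
    p = out / "lasso_annotation.json"
    p.write_text(json.dumps(reports, indent=2, sort_keys=True))
    record("annotate", [p], n_lasso_bgcs=len(reports))


def _stage_plan_dilution(config, out, result, record):
    # pick the pool holding the clone behind the first complete single-read call
    target_pool = 0
    by_read = {r.read_id: r.clone_id for r in result.long_reads}
    clone_by_id = {c.clone_id: c for c in result.clones}
    for v in result.verdicts:
        if v.call == CALL_COMPLETE and v.best_read_id in by_read:
            target_pool = clone_by_id[by_read[v.best_read_id]].pool_id
            break
    plans = default_protocol(config.dilution, n_tubes=config.n_tubes)
    outcome = simulate_recovery(config.dilution, plans, seed=derive_seed(config.seed, "dilution"))
    table = pd.DataFrame(
        [(i, p.cells_per_ml, p.inoculum_volume_ml, p.n_tubes, p.expected_cells_per_tube,
          p.target_frequency, p.p_tube_positive, p.p_round_success, p.plating)
         for i, p in enumerate(plans)],
        columns=["round", "cells_per_ml", "volume_ml", "n_tubes", "expected_cells_per_tube",
                 "target_frequency", "p_tube_positive", "p_round_success", "plating"])
    result.recovery = {"target_pool": target_pool, "isolated": outcome.isolated,
                       "rounds_executed": outcome.rounds_executed,
                       "trajectory": outcome.trajectory}
    p1 = out / "dilution_plan.tsv"
    write_tsv(p1, table, comment=f"snrcm {__version__} serial-dilution plan")
    p2 = out / "recovery_simulation.json"
    p2.write_text(json.dumps(result.recovery, indent=2, sort_keys=True))
    record("plan_dilution", [p1, p2], isolated=outcome.isolated)


def _stage_plan_tar(config, out, result, record):
    community = result.community
    oversized = [b for b in community.bgcs if not fits_single_insert(b, config.sim)]
    if not oversized:
        raise SnrcmError("plan_tar enabled but no multi-insert cluster was planted")
    bgc = oversized[0]
    alignments = [
        FosmidAlignment(clone_id=c.clone_id, ref_interval=c.insert_interval, strand="+")
        for c in result.clones
        if c.fragment_id == bgc.fragment_id
        and c.insert_interval[1] > bgc.start and c.insert_interval[0] < bgc.end
    ]
    path = find_tiling_path((bgc.start, bgc.end), alignments, config.min_overlap_bp)

    frag = community.fragments[bgc.fragment_id]
    cluster_seq = frag[bgc.start:bgc.end]
    vec_rng = np.random.default_rng(derive_seed(config.seed, "tar_vector"))
    vector = random_dna(vec_rng, config.tar_vector_len_bp, 0.5)
    construct = vector + cluster_seq  # circular assembled TAR product
    digest = choose_release_enzyme(construct)
    result.tiling = {
        "bgc_id": bgc.bgc_id,
        "clone_ids": path.clone_ids,
        "intervals": path.intervals,
        "overlaps_bp": path.pairwise_overlaps_bp,
        "n_candidate_clones": len(alignments),
    }
    result.digest = {
        "enzyme": digest.enzyme, "site": digest.site,
        "site_positions": digest.site_positions,
        "fragment_lengths_bp": digest.fragment_lengths_bp,
        "construct_len_bp": len(construct),
    }
    result._construct = construct  # type: ignore[attr-defined]
    result._digest_obj = digest  # type: ignore[attr-defined]
    p1 = out / "tiling_path.tsv"
    write_tsv(p1, pd.DataFrame(
        [(cid, *iv) for cid, iv in zip(path.clone_ids, path.intervals)],
        columns=["clone_id", "ref_start", "ref_end"]),
        comment=f"snrcm {__version__} tiling path for {bgc.bgc_id}")
    p2 = out / "digest_plan.json"
    p2.write_text(json.dumps(result.digest, indent=2, sort_keys=True))
    record("plan_tar", [p1, p2], n_clones=len(path.clone_ids), enzyme=digest.enzyme)


def _cut_sequences(construct: str, digest) -> list[str]:
    offset = len(digest.site) // 2
    cuts = sorted((s + offset) % len(construct) for s in digest.site_positions)
    doubled = construct + construct
    return [doubled[cuts[i]: cuts[i] + ((cuts[(i + 1) % len(cuts)] - cuts[i]) % len(construct)
                                        or len(construct))]
            for i in range(len(cuts))]


def _stage_verify(config, out, result, record):
    construct = result._construct  # type: ignore[attr-defined]
    digest = result._digest_obj  # type: ignore[attr-defined]
    fragments = _cut_sequences(construct, digest)
    rng = np.random.default_rng(derive_seed(config.seed, "verify_reads"))
    reads = []
    for fi, frag_seq in enumerate(fragments):
        codes = encode(frag_seq)
        for j in range(config.verify_reads_per_fragment):
            length = int(len(frag_seq) * rng.uniform(0.55, 1.0))
            start = int(rng.integers(0, len(frag_seq) - length + 1))
            obs, _ = _apply_errors(codes[start:start + length], config.sim.long_read_error, rng)
            reads.append((f"vread_{fi}_{j:03d}", decode(obs)))
    sizes = [len(f) for f in fragments]
    groups = size_filter_reads(reads, sizes, rel_tol=config.size_filter_tol)
    verification = verify_assembly(groups, {len(f): f for f in fragments}, config.containment)
    result.verification = {
        "passed": verification.passed,
        "fragments": [dataclasses.asdict(v) for v in verification.fragments],
        "n_reads_simulated": len(reads),
        "reads_per_group": {str(k): len(v) for k, v in groups.items()},
    }
    p = out / "verification.json"
    p.write_text(json.dumps(result.verification, indent=2, sort_keys=True))
    record("verify", [p], passed=verification.passed)
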