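"""File I/O: FASTA/FASTQ (Biopython-backed), GFF3 and TSV helpers.

Coordinates are 0-based half-open everywhere in memory; GFF3 is written and
read 1-based inclusive, converted only at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import SnrcmError


class ParseError(SnrcmError):
    """Malformed input file; message carries file name and line/record."""


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Return (id, sequence, quality-string) triples, byte-preserving quality."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTQ near record {len(out) + 1}: {exc}") from exc
    return out


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------- GFF3

@dataclass
class GffRecord:
    """One GFF3 feature with 0-based half-open coordinates in memory."""

    seqid: str
    type: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."
    source: str = "snrcm"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def attr_string(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def read_gff3(path: str | Path) -> list[GffRecord]:
    records: list[GffRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            seqid, source, ftype, start, end, score, strand, _phase, attrs = fields
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates {start!r}..{end!r}") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}: line {lineno}: invalid 1-based interval {start1}..{end1}")
            attributes = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"{path}: line {lineno}: malformed attribute {item!r}")
                k, v = item.split("=", 1)
                attributes[k] = v
            records.append(
                GffRecord(seqid=seqid, source=source, type=ftype, start=start1 - 1, end=end1,
                          strand=strand, score=score, attributes=attributes)
            )
    return records


def write_gff3(path: str | Path, records: Iterable[GffRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                "\t".join([r.seqid, r.source, r.type, str(r.start + 1), str(r.end),
                           r.score, r.strand, ".", r.attr_string or "."]) + "\n"
            )


# ---------------------------------------------------------------------- TSV

def write_tsv(path: str | Path, frame: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
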