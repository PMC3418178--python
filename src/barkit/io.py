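"""File-format plumbing: FASTA/FASTQ, GFF3, BED-like element maps, TSV.

All user-facing coordinates are written 1-based inclusive (GFF3/report
convention); everything in memory is 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import NucSequence, Topology

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "Feature",
    "write_gff3",
    "read_gff3",
    "write_element_map",
    "write_manifest",
]


def read_fasta(path: str | Path, topology: Topology = Topology.linear) -> list[NucSequence]:
    return [
        NucSequence(rec.id, str(rec.seq).upper(), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60 columns


def read_fastq(path: str | Path) -> list[NucSequence]:
    return [
        NucSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
    ]


@dataclass(frozen=True)
class Feature:
    """A genome annotation feature; start/end are 0-based half-open."""

    contig: str
    start: int
    end: int
    type: str  # "gene" (protein-coding ORF) or "ncRNA_gene"
    id: str
    strand: str = "+"


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tbarkit\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for f in db.all_features():
        out.append(
            Feature(f.seqid, f.start - 1, f.end, f.featuretype, f.id, f.strand or "+")
        )
    return out


def write_element_map(elements: Mapping[str, tuple[int, int]], seq_id: str, path: str | Path) -> None:
    """BED-like TSV of named cassette elements (0-based half-open, BED style)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("#seq_id\telement\tstart\tend\n")
        for name, (s, e) in sorted(elements.items(), key=lambda kv: kv[1]):
            fh.write(f"{seq_id}\t{name}\t{s}\t{e}\n")


def write_manifest(config: Mapping, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
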