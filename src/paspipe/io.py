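"""Plain-text readers and writers for the pipeline's interchange formats:
FASTA genomes, FASTQ reads, BED6 tags/annotations, and TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readproc import AlignedTag
from .simulate import GenomeAnnotation, PASite


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_tags_bed(tags: Iterable[AlignedTag], path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.read_id}\t0\t{t.strand}\n")


def read_tags_bed(path) -> list[AlignedTag]:
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, _, strand = line.rstrip("\n").split("\t")[:6]
            tags.append(AlignedTag(name, c, int(s), int(e), strand))
    return tags


def write_pas_bed(sites: Iterable[PASite], path) -> None:
    """Master PAS annotation as BED6 with name 'id|class'."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.position}\t{s.position + 1}\t"
                f"{s.pas_id}|{s.pas_class}\t0\t{s.strand}\n"
            )


def read_pas_bed(path) -> list[PASite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, _e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            pas_id, cls = name.rsplit("|", 1)
            gene_id = pas_id.split(":")[0] if ":" in pas_id else None
            sites.append(PASite(pas_id, c, strand, int(s), gene_id, cls))
    return sites


def write_rejections(rejections, path) -> None:
    pd.DataFrame(
        [(r.read_id, r.reason) for r in rejections], columns=["read_id", "reason"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
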