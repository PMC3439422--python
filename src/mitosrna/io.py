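"""Readers and writers for the formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; annotation tracks are GFF3 (1-based
closed on disk, 0-based half-open in memory); tables are plain TSV.
Clean tags are written as FASTA with ``>tagN_xCOUNT`` headers, the common
small-RNA convention of encoding the read count in the header.
"""

from __future__ import annotations

import re

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Feature
from .preprocess import RawRead, ReadTag

__all__ = [
    "write_fasta", "read_fasta", "write_fastq", "read_fastq",
    "write_tags_fasta", "read_tags_fasta", "write_gff3", "read_gff3",
    "write_alignments_tsv", "write_candidates_tsv",
]


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")


def read_fastq(path) -> list[RawRead]:
    out = []
    for r in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
        out.append(RawRead(r.id, str(r.seq).upper(), qual))
    return out


_TAG_HEADER = re.compile(r"^(\S+)_x(\d+)$")


def write_tags_fasta(tags, path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.id}_x{t.count}\n{t.sequence}\n")


def read_tags_fasta(path) -> list[ReadTag]:
    out = []
    for r in SeqIO.parse(str(path), "fasta"):
        m = _TAG_HEADER.match(r.id)
        if not m:
            raise ValueError(f"tag header {r.id!r} lacks the _xCOUNT suffix")
        out.append(ReadTag(str(r.seq).upper(), int(m.group(2)), m.group(1)))
    return out


def write_gff3(tracks: dict[str, list[Feature]], path) -> None:
    """Tracks to GFF3: type = category, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cat in sorted(tracks):
            for f in tracks[cat]:
                attrs = f"ID={f.feature_id}"
                if f.cls:
                    attrs += f";class={f.cls}"
                fh.write("\t".join([
                    f.contig, f.source or ".", cat, str(f.start + 1),
                    str(f.end), ".", f.strand, ".", attrs]) + "\n")


def read_gff3(path) -> dict[str, list[Feature]]:
    tracks: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, source, cat, start, end, _, strand, _, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            tracks.setdefault(cat, []).append(Feature(
                contig, int(start) - 1, int(end), strand,
                fields.get("ID", ""), "" if source == "." else source,
                fields.get("class", "")))
    return tracks


def write_alignments_tsv(alignments, path) -> None:
    """1-based closed alignment table."""
    rows = [(a.tag_id, a.contig, a.start + 1, a.end, a.strand,
             a.mismatches, a.n_hits_total) for a in alignments]
    pd.DataFrame(rows, columns=["tag", "contig", "start", "end", "strand",
                                "mismatches", "n_hits"]).to_csv(
        path, sep="\t", index=False)


def write_candidates_tsv(candidates, path) -> None:
    """Candidate table in the supplementary-table layout
    (id, location, strand, MFE, read count, sequence)."""
    rows = [(c.id or ".", f"{c.contig}:{c.start + 1}-{c.end}", c.strand,
             round(c.mfe, 2), c.read_count, c.mature_seq,
             "accept" if c.accepted else ";".join(c.failure_reasons))
            for c in candidates]
    pd.DataFrame(rows, columns=["id", "location", "strand", "mfe",
                                "read_count", "mature_seq", "verdict"]).to_csv(
        path, sep="\t", index=False)
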