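"""Seed-and-extend mapping of collapsed tags, allowing at most one mismatch.

A k-mer hash index over the forward strand of every contig serves as the
seed table (k = 9 by default).  For a tag of length >= 18 and k <= 9, the
first and last k-mers never overlap, so by pigeonhole any placement with
<= 1 substitution matches at least one of the two seeds exactly; every
candidate placement is then verified base-by-base.  Reverse-strand hits
are found by seeding the reverse complement of the tag; no indels, per
small-RNA practice.  All hits are reported and each alignment carries the
tag's genome-wide hit multiplicity for downstream copy-number filtering.

Coordinates are 0-based half-open internally; writers emit 1-based closed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp

__all__ = ["GenomeIndex", "Alignment", "build_index", "map_tag",
           "map_library", "chromosome_distribution"]


@dataclass(frozen=True)
class Alignment:
    tag_id: str
    contig: str
    start: int           # 0-based
    end: int             # exclusive; end - start == tag length
    strand: str          # '+' or '-'
    mismatches: int
    n_hits_total: int = 1


class GenomeIndex:
    """k-mer position index over a set of contigs."""

    def __init__(self, contigs: dict[str, str], seed_len: int = 9):
        if not contigs:
            raise ValueError("no contigs to index")
        if not 4 <= seed_len <= 14:
            raise ValueError("seed_len must be in [4, 14]")
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.contigs.items():
            if len(seq) < seed_len:
                import warnings
                warnings.warn(f"contig {name} shorter than seed length; skipped")
                continue
            for i in range(len(seq) - seed_len + 1):
                self.index[seq[i:i + seed_len]].append((name, i))
        self.index = dict(self.index)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def build_index(contigs: dict[str, str], seed_len: int = 9) -> GenomeIndex:
    return GenomeIndex(contigs, seed_len)


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                break
    return mm


def map_tag(index: GenomeIndex, tag, max_mismatch: int = 1) -> list[Alignment]:
    """All placements of a tag with <= max_mismatch substitutions, both strands."""
    seq = tag.sequence if hasattr(tag, "sequence") else str(tag)
    tag_id = getattr(tag, "id", "") or seq
    k = index.seed_len
    L = len(seq)
    if L < 2 * k:
        raise ValueError(f"tag length {L} too short for two non-overlapping "
                         f"{k}-mer seeds; need >= {2 * k}")
    hits: dict[tuple[str, int, str], int] = {}
    for strand in "+-":
        q = seq if strand == "+" else revcomp(seq)
        for offset in (0, L - k):
            for contig, pos in index.lookup(q[offset:offset + k]):
                start = pos - offset
                if start < 0:
                    continue
                ref = index.contigs[contig]
                if start + L > len(ref):
                    continue
                key = (contig, start, strand)
                if key in hits:
                    continue
                mm = _mismatches(q, ref[start:start + L], max_mismatch)
                if mm <= max_mismatch:
                    hits[key] = mm
    n = len(hits)
    return [
        Alignment(tag_id, c, s, s + L, st, mm, n)
        for (c, s, st), mm in sorted(hits.items())
    ]


def map_library(index: GenomeIndex, tags, max_mismatch: int = 1):
    """Map every tag; returns (alignments, unmapped_tags).

    Every tag lands in exactly one of the two outputs; the fraction mapped
    is in ``alignments_summary``-style attrs on the unmapped list caller
    side (len(tags) partitions exactly).
    """
    alignments: list[Alignment] = []
    unmapped = []
    for tag in tags:
        hits = map_tag(index, tag, max_mismatch)
        if hits:
            alignments.extend(hits)
        else:
            unmapped.append(tag)
    return alignments, unmapped


def chromosome_distribution(alignments: list[Alignment], tags=None):
    """Per-(contig, strand) unique-tag and read counts.

    Returns ``(all_hits, best_hit)`` DataFrames.  In the all-hits view a
    multi-mapping tag contributes to every location it hits (flagged by
    ``multi``); in the best-hit view each tag is counted once, at its
    lexicographically first hit, so counts sum to the number of mapped tags.
    """
    counts = {t.id: t.count for t in tags} if tags else {}

    def _table(alns):
        rows = defaultdict(lambda: [0, 0, 0])
        for a in alns:
            r = rows[(a.contig, a.strand)]
            r[0] += 1
            r[1] += counts.get(a.tag_id, 1)
            r[2] += a.n_hits_total > 1
        return pd.DataFrame(
            [(c, s, u, t, m) for (c, s), (u, t, m) in sorted(rows.items())],
            columns=["contig", "strand", "unique_tags", "total_reads", "multi"],
        )

    first = {}
    for a in sorted(alignments, key=lambda a: (a.tag_id, a.contig, a.start, a.strand)):
        first.setdefault(a.tag_id, a)
    return _table(alignments), _table(first.values())
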