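"""Alignment of tags and candidate miRNAs to the circular mitochondrial genome.

The mitochondrial genome is circular, so the reference is extended by its
own first L-1 bases before indexing; hits are de-duplicated modulo the
genome length and reported in 1-based closed coordinates (the convention
of the mitochondrial reference sequence).  An origin-spanning hit has
``end < start``.  Two modes:

* ``full``      — the mapper's <=1-mismatch rule on the circularised sequence;
* ``prefix11``  — exact placement of a candidate's first 11 bases, the
  screen used for putative novel miRNAs (an 11-mer expects ~2 * 16569 /
  4^11 ≈ 0.008 chance hits on a mitochondrial-sized genome, so shorter
  prefixes are refused as uninformative).

Hits are annotated with every overlapping gene-map feature (>= 1 base,
wrap-around features supported) or "non-coding".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp
from .mapping import GenomeIndex, map_tag

__all__ = ["MtGeneMap", "MtHit", "map_to_mtdna", "prefix_align",
           "annotate_mt_positions"]

MIN_PREFIX = 8


@dataclass(frozen=True)
class MtFeature:
    gene: str
    start: int        # 1-based closed; start > end means origin-spanning
    end: int
    strand: str
    cls: str          # protein | tRNA | rRNA | noncoding


@dataclass
class MtGeneMap:
    length: int
    features: list[MtFeature]

    def __post_init__(self):
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise ValueError(f"feature {f.gene} outside [1, {self.length}]")

    def segments(self, f: MtFeature) -> list[tuple[int, int]]:
        """Linear (start, end) 1-based closed segments; two if wrapping."""
        if f.start <= f.end:
            return [(f.start, f.end)]
        return [(f.start, self.length), (1, f.end)]


@dataclass
class MtHit:
    query_id: str
    start: int        # 1-based closed, wrapped into [1, length]
    end: int          # end < start for origin-spanning hits
    strand: str
    mismatches: int
    mode: str         # full | prefix11
    gene_assignment: tuple = ()

    def segments(self, length: int) -> list[tuple[int, int]]:
        if self.start <= self.end:
            return [(self.start, self.end)]
        return [(self.start, length), (1, self.end)]


def _wrap(start0: int, qlen: int, L: int) -> tuple[int, int]:
    """0-based start on the extended sequence -> 1-based closed circular."""
    s = start0 % L
    e0 = s + qlen - 1
    return s + 1, (e0 % L) + 1


def map_to_mtdna(tags, mt_genome: str, circular: bool = True,
                 max_mismatch: int = 1, seed_len: int = 9) -> list[MtHit]:
    """Map tags to the (circular) mitochondrial genome, mode ``full``.

    The genome is extended by its first L-1 bases, mapped with the
    standard seed-and-extend rules, and hits are de-duplicated modulo L.
    With ``circular=False`` a plain linear mapping is performed (with a
    warning, since the reference is normally circular).
    """
    mt = mt_genome.upper()
    L = len(mt)
    if not circular:
        import warnings
        warnings.warn("mapping a mitochondrial reference as linear sequence")
        ref = mt
    else:
        ref = mt + mt[:L - 1]
    index = GenomeIndex({"MT": ref}, seed_len=seed_len)
    out: list[MtHit] = []
    for tag in tags:
        seen = set()
        for a in map_tag(index, tag, max_mismatch):
            qlen = a.end - a.start
            s1, e1 = _wrap(a.start, qlen, L) if circular else (a.start + 1, a.end)
            key = (s1, a.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(MtHit(a.tag_id, s1, e1, a.strand, a.mismatches, "full"))
    return out


def prefix_align(candidates, mt_genome: str, prefix_len: int = 11) -> list[MtHit]:
    """Exact-match placement of each candidate's first ``prefix_len`` bases.

    Both strands of the circular genome are searched; all positions are
    reported with zero mismatches.  ``prefix_len`` below 8 is refused:
    such prefixes match by chance on a mitochondrial-sized genome.
    """
    if prefix_len < MIN_PREFIX:
        raise ValueError(
            f"prefix_len {prefix_len} < {MIN_PREFIX}: chance matches make "
            "shorter prefixes uninformative")
    mt = mt_genome.upper()
    L = len(mt)
    ext = mt + mt[:prefix_len - 1]
    out: list[MtHit] = []
    for cand in candidates:
        seq = (cand.mature_seq if hasattr(cand, "mature_seq") else str(cand))
        seq = seq.upper().replace("U", "T")
        qid = getattr(cand, "id", "") or seq
        if len(seq) < prefix_len:
            continue
        prefix = seq[:prefix_len]
        for strand, query in (("+", prefix), ("-", revcomp(prefix))):
            i = ext.find(query)
            while i >= 0:
                if i < L:
                    s1, e1 = _wrap(i, prefix_len, L)
                    out.append(MtHit(qid, s1, e1, strand, 0, "prefix11"))
                i = ext.find(query, i + 1)
    return out


def annotate_mt_positions(hits: list[MtHit], gene_map: MtGeneMap):
    """Label hits with overlapping gene-map features (>= 1 base overlap).

    Returns ``(hits, per_gene_summary)``; hits without any overlap are
    assigned ``("non-coding",)``.
    """
    for h in hits:
        genes = []
        for f in gene_map.features:
            if any(s1 <= e2 and s2 <= e1
                   for (s1, e1) in h.segments(gene_map.length)
                   for (s2, e2) in gene_map.segments(f)):
                genes.append(f.gene)
        h.gene_assignment = tuple(genes) if genes else ("non-coding",)
    counts = defaultdict(int)
    for h in hits:
        for g in h.gene_assignment:
            counts[g] += 1
    summary = pd.DataFrame(sorted(counts.items()), columns=["gene", "n_hits"])
    return hits, summary
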