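"""Priority-cascade annotation of clean tags and known-miRNA matching.

Every clean tag receives exactly one category.  Feature overlaps are
collected across *all* of a tag's genomic hits (an overlap requires at
least 50% of the tag length inside the feature, on the feature's strand
unless the feature is unstranded), miRNA identity is sequence-based
against miRBase-style mature / star / precursor sets, piRNA identity is
exact-sequence against a supplied set, and the single assigned category
is the highest-priority one under

    rRNA > tRNA > snRNA > snoRNA > srpRNA > scRNA
         > known miRNA > piRNA > repeat > exon > intron > unannotated

with Genbank preferred over Rfam as the rRNA source when both match.
The order is configurable but total.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Feature", "MiRNAMatch", "AnnotationRecord", "match_known_mirna",
    "classify_tags", "summarize_categories", "compare_libraries",
    "DEFAULT_PRIORITY",
]

DEFAULT_PRIORITY = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "srpRNA", "scRNA",
    "miRNA", "piRNA", "repeat", "exon", "intron",
)

#: source ranking inside the rRNA class
_SOURCE_RANK = {"Genbank": 0, "Rfam": 1}


@dataclass(frozen=True)
class Feature:
    """One annotated interval (0-based half-open internally)."""
    contig: str
    start: int
    end: int
    strand: str          # '+', '-' or '.' (unstranded)
    feature_id: str
    source: str = ""     # e.g. Genbank / Rfam for rRNA
    cls: str = ""        # repeat class (LINE, SINE/Alu, ...)


@dataclass(frozen=True)
class MiRNAMatch:
    tag_id: str
    mirna_id: str
    match_type: str      # mature | star | precursor_only
    offset5: int         # tag 5' end minus reference 5' end
    mismatches: int
    primary: bool = False


@dataclass(frozen=True)
class AnnotationRecord:
    tag_id: str
    category: str        # cascade category; repeats as "repeat:<class>"
    source: str = ""
    feature_id: str = ""


# ---------------------------------------------------------------------------
# known-miRNA matching (sequence-based)
# ---------------------------------------------------------------------------

_SEED = 8


def _kmer_map(refs: dict[str, str]) -> dict[str, list[tuple[str, int]]]:
    out = defaultdict(list)
    for name, seq in refs.items():
        for i in range(len(seq) - _SEED + 1):
            out[seq[i:i + _SEED]].append((name, i))
    return out


def _align_at(tag: str, ref: str, offset: int, limit: int = 1):
    """Compare tag against ref with the tag 5' end at ref position offset.

    Mismatches are counted over the overlapping region only (a tag may
    overhang the reference into precursor flank).  Returns the mismatch
    count or None if over limit / no overlap.
    """
    lo = max(0, offset)
    hi = min(len(ref), offset + len(tag))
    if hi - lo < _SEED:
        return None
    mm = 0
    for p in range(lo, hi):
        if ref[p] != tag[p - offset]:
            mm += 1
            if mm > limit:
                return None
    return mm


def match_known_mirna(tags, mature_ref: dict[str, str], star_ref: dict[str, str],
                      precursor_ref: dict[str, str],
                      max_offset: int = 2) -> list[MiRNAMatch]:
    """Match collapsed tags to reference mature / star / precursor sets.

    A tag is called mature (resp. star) when it aligns to the reference
    sequence with <= 1 mismatch and its 5' end within +-``max_offset`` of
    the reference 5' end (isomiR tolerance).  Tags matching only a
    precursor body are ``precursor_only``.  All matches are reported; the
    primary call per tag is the best match type (mature > star >
    precursor_only) with the lexicographically smallest mirna_id.
    """
    for refs, label in ((mature_ref, "mature"), (star_ref, "star")):
        for name, seq in refs.items():
            if not any(seq in p for p in precursor_ref.values()):
                raise ValueError(
                    f"{label} sequence {name} absent from every precursor")

    mature_k = _kmer_map(mature_ref)
    star_k = _kmer_map(star_ref)
    pre_k = _kmer_map(precursor_ref)
    type_rank = {"mature": 0, "star": 1, "precursor_only": 2}
    matches: list[MiRNAMatch] = []

    for tag in tags:
        seq = tag.sequence
        found: dict[tuple[str, str], tuple[int, int]] = {}
        for refs, kmap, mtype in ((mature_ref, mature_k, "mature"),
                                  (star_ref, star_k, "star")):
            cands = set()
            for q in (0, _SEED):
                if q + _SEED > len(seq):
                    continue
                for name, pos in kmap.get(seq[q:q + _SEED], ()):
                    off = pos - q
                    if abs(off) <= max_offset:
                        cands.add((name, off))
            for name, off in cands:
                mm = _align_at(seq, refs[name], off)
                if mm is not None:
                    key = (name, mtype)
                    if key not in found or mm < found[key][1]:
                        found[key] = (off, mm)
        if not found:
            cands = set()
            for q in (0, _SEED):
                if q + _SEED > len(seq):
                    continue
                for name, pos in pre_k.get(seq[q:q + _SEED], ()):
                    cands.add((name, pos - q))
            for name, off in cands:
                ref = precursor_ref[name]
                if off < 0 or off + len(seq) > len(ref):
                    continue
                mm = _align_at(seq, ref, off)
                if mm is not None:
                    key = (name, "precursor_only")
                    if key not in found or mm < found[key][1]:
                        found[key] = (off, mm)
        if not found:
            continue
        ordered = sorted(found.items(),
                         key=lambda kv: (type_rank[kv[0][1]], kv[0][0]))
        for rank, ((name, mtype), (off, mm)) in enumerate(ordered):
            matches.append(MiRNAMatch(tag.id, name, mtype, off, mm,
                                      primary=(rank == 0)))
    return matches


# ---------------------------------------------------------------------------
# cascade classification
# ---------------------------------------------------------------------------

def _build_trees(tracks: dict[str, list[Feature]], contigs: dict[str, str] | None):
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for cat, feats in tracks.items():
        for f in feats:
            if contigs is not None:
                if f.contig not in contigs or not (0 <= f.start < f.end <= len(contigs[f.contig])):
                    raise ValueError(
                        f"{cat} feature {f.feature_id} outside contig {f.contig}")
            trees[(cat, f.contig)].addi(f.start, f.end, f)
    return trees


def classify_tags(tags, alignments, tracks: dict[str, list[Feature]],
                  mirna_matches: list[MiRNAMatch] | None = None,
                  pirna_seqs: set[str] | None = None,
                  priority=DEFAULT_PRIORITY,
                  contigs: dict[str, str] | None = None,
                  min_overlap: float = 0.5) -> list[AnnotationRecord]:
    """Assign each tag its single cascade category.

    Track categories are decided positionally from all of the tag's hits;
    miRNA from sequence matches (mature -> miRNA, star -> miRNA_star,
    precursor_only -> miRNA); piRNA from exact sequence membership.  Tags
    with no evidence anywhere are ``unannotated``.
    """
    trees = _build_trees(tracks, contigs)
    by_tag_aln = defaultdict(list)
    for a in alignments:
        by_tag_aln[a.tag_id].append(a)
    mirna_by_tag: dict[str, MiRNAMatch] = {}
    for m in mirna_matches or ():
        if m.primary:
            mirna_by_tag[m.tag_id] = m
    pirna_seqs = pirna_seqs or set()

    records = []
    for tag in tags:
        L = len(tag.sequence)
        hits: dict[str, Feature] = {}
        for a in by_tag_aln.get(tag.id, ()):
            for cat in tracks:
                tree = trees.get((cat, a.contig))
                if not tree:
                    continue
                for iv in tree.overlap(a.start, a.end):
                    f: Feature = iv.data
                    if f.strand != "." and f.strand != a.strand:
                        continue
                    if min(a.end, f.end) - max(a.start, f.start) < min_overlap * L:
                        continue
                    prev = hits.get(cat)
                    if prev is None or (
                            _SOURCE_RANK.get(f.source, 9) <
                            _SOURCE_RANK.get(prev.source, 9)):
                        hits[cat] = f
        category, source, feature_id = "unannotated", "", ""
        for cat in priority:
            if cat == "miRNA":
                m = mirna_by_tag.get(tag.id)
                if m is not None:
                    category = "miRNA_star" if m.match_type == "star" else "miRNA"
                    source, feature_id = "miRBase-like", m.mirna_id
                    break
            elif cat == "piRNA" and tag.sequence in pirna_seqs:
                category, source, feature_id = "piRNA", "piRNA-set", tag.sequence
                break
            elif cat in hits:
                f = hits[cat]
                if cat == "repeat":
                    category = f"repeat:{f.cls or 'unknown'}"
                else:
                    category = cat
                source, feature_id = f.source or cat, f.feature_id
                break
        records.append(AnnotationRecord(tag.id, category, source, feature_id))
    return records


def summarize_categories(records: list[AnnotationRecord], tags) -> pd.DataFrame:
    """Unique-tag and read-weighted category table with percentages.

    Repeat classes are sub-tabulated as their own ``repeat:<class>`` rows;
    both percentage columns each sum to 100.
    """
    counts = {t.id: t.count for t in tags}
    if len(records) != len(tags):
        raise ValueError("records must partition the tag set")
    rows = defaultdict(lambda: [0, 0])
    for r in records:
        rows[r.category][0] += 1
        rows[r.category][1] += counts[r.tag_id]
    df = pd.DataFrame(
        [(cat, u, t) for cat, (u, t) in sorted(rows.items())],
        columns=["category", "unique_tags", "total_reads"],
    )
    df["unique_percent"] = 100.0 * df["unique_tags"] / df["unique_tags"].sum()
    df["total_percent"] = 100.0 * df["total_reads"] / df["total_reads"].sum()
    return df.sort_values("total_reads", ascending=False).reset_index(drop=True)


def compare_libraries(tags_a, tags_b) -> pd.DataFrame:
    """Common / A-specific / B-specific partition of two collapsed libraries.

    Partition is by exact insert sequence; reports unique-tag counts and
    summed read counts per cell (the Venn-style table).
    """
    a = {t.sequence: t.count for t in tags_a}
    b = {t.sequence: t.count for t in tags_b}
    common = set(a) & set(b)
    only_a = set(a) - common
    only_b = set(b) - common
    rows = [
        ("common", len(common),
         sum(a[s] for s in common), sum(b[s] for s in common)),
        ("A_specific", len(only_a), sum(a[s] for s in only_a), 0),
        ("B_specific", len(only_b), 0, sum(b[s] for s in only_b)),
    ]
    return pd.DataFrame(rows, columns=["partition", "unique_tags",
                                       "reads_A", "reads_B"])
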