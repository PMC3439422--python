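"""End-to-end orchestration: raw reads -> clean tags -> alignments ->
annotation -> known-miRNA table -> novel-miRNA candidates.

`run_library` wires the per-module operations together in the order the
analysis defines and returns everything in one result object so examples,
tests and the acceptance script share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import (classify_tags, match_known_mirna, summarize_categories)
from .discovery import (HairpinCriteria, cluster_unannotated,
                        predict_novel_mirnas)
from .mapping import build_index, map_library
from .preprocess import clean_reads
from .simulate import LibraryProfile, SyntheticReference, TruthSet, simulate_library

__all__ = ["LibraryResult", "run_library", "simulate_and_run", "mirna_counts"]


@dataclass
class LibraryResult:
    tags: list
    stats: object
    length_table: pd.DataFrame
    alignments: list
    unmapped: list
    mirna_matches: list
    records: list
    category_summary: pd.DataFrame
    novel_accepted: list
    novel_rejected: list
    clusters: list = field(default_factory=list)

    @property
    def records_by_tag(self) -> dict:
        return {r.tag_id: r for r in self.records}


def run_library(reads, reference: SyntheticReference,
                adapter3: str, adapter5: str = "",
                max_mismatch: int = 1,
                criteria: HairpinCriteria = HairpinCriteria(),
                lib_label: str = "synm",
                discover: bool = True) -> LibraryResult:
    """Run the full analysis of one raw library against a reference."""
    tags, stats, length_table = clean_reads(reads, adapter3, adapter5)
    index = build_index(reference.contigs)
    alignments, unmapped = map_library(index, tags, max_mismatch)
    matches = match_known_mirna(tags, reference.mature_refs,
                                reference.star_refs, reference.precursor_refs)
    records = classify_tags(tags, alignments, reference.tracks, matches,
                            reference.pirna_seqs, contigs=reference.contigs)
    summary = summarize_categories(records, tags)

    accepted, rejected, clusters = [], [], []
    if discover:
        unann = {r.tag_id for r in records if r.category == "unannotated"}
        sub = [a for a in alignments if a.tag_id in unann]
        counts = {t.id: t.count for t in tags}
        clusters = cluster_unannotated(sub, counts)
        accepted, rejected = predict_novel_mirnas(
            reference.contigs, clusters, criteria=criteria,
            lib_label=lib_label)
    return LibraryResult(tags, stats, length_table, alignments, unmapped,
                         matches, records, summary, accepted, rejected,
                         clusters)


def simulate_and_run(reference: SyntheticReference, truth: TruthSet | None,
                     profile: LibraryProfile | None = None, seed: int = 0,
                     **kw):
    """Simulate a library and analyse it; returns (result, reads, truth_table)."""
    profile = profile or LibraryProfile()
    reads, truth_table = simulate_library(reference, truth, profile, seed)
    result = run_library(reads, reference, profile.adapter3, profile.adapter5,
                         **kw)
    return result, reads, truth_table


def mirna_counts(result: LibraryResult) -> dict[str, int]:
    """Read counts per known miRNA (primary mature matches only)."""
    counts = {t.id: t.count for t in result.tags}
    out: dict[str, int] = {}
    for m in result.mirna_matches:
        if m.primary and m.match_type == "mature":
            out[m.mirna_id] = out.get(m.mirna_id, 0) + counts[m.tag_id]
    return out
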