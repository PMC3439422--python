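"""Raw read cleaning: adapter trimming, filtering, tag collapsing.

Raw reads are fixed-length sequencer tags (50 nt by default) consisting of
an 18-30 nt insert followed by the 3' adapter (and padding).  Cleaning:

1. reads containing the 5' adapter (<=1 mismatch anywhere) are discarded
   as ligation contamination;
2. the 3' adapter is located as the best prefix-of-adapter match at the
   insert/adapter junction (>=6 exact bases, or >=10 bases with <=1
   mismatch); everything from the match onward is removed.  Reads with no
   locatable 3' adapter are discarded — without the junction the insert
   has no defined 3' boundary;
3. inserts shorter than 18 nt or longer than 30 nt, inserts containing N,
   and poly-A degradation products (A fraction >= 0.75 or a 3' run of
   >= 8 A) are removed;
4. surviving inserts are collapsed to unique tags with read counts.

Accounting is exact at every stage: reads in = reads out + reads removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RawRead", "ReadTag", "CleanStats", "trim_adapters", "filter_clean",
    "collapse_tags", "length_distribution", "clean_reads",
]

MIN_LEN = 18
MAX_LEN = 30


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str = ""


@dataclass(frozen=True)
class ReadTag:
    """A collapsed unique insert sequence with its supporting read count."""
    sequence: str
    count: int
    id: str = ""

    def __len__(self):
        return len(self.sequence)


@dataclass
class CleanStats:
    """Exact accounting of the cleaning pipeline.

    ``n_long_removed`` (inserts > 30 nt) is kept separate from
    ``n_short_removed`` so both length bounds reconcile exactly.
    """
    n_raw: int = 0
    n_adapter_removed: int = 0      # 5' contamination + no locatable 3' adapter
    n_short_removed: int = 0
    n_long_removed: int = 0
    n_polyA_removed: int = 0
    n_low_quality_removed: int = 0  # N-containing inserts
    n_clean: int = 0

    def check(self) -> None:
        removed = (self.n_adapter_removed + self.n_short_removed
                   + self.n_long_removed + self.n_polyA_removed
                   + self.n_low_quality_removed)
        if self.n_clean != self.n_raw - removed:
            raise AssertionError("clean-read accounting does not reconcile")


def _best_junction(read: str, adapter3: str, min_exact: int = 6,
                   min_mm: int = 10) -> int:
    """Offset of the best insert/adapter junction, or -1 if none.

    Scores each offset by (matching bases - mismatches) over the overlap of
    the read suffix with the adapter prefix; a junction is valid with >=
    ``min_exact`` exact bases, or >= ``min_mm`` bases with one mismatch.
    Ties go to the leftmost offset.
    """
    # fast path: full adapter present verbatim (optimal: maximal overlap,
    # zero mismatches; find() returns the leftmost such offset)
    i = read.find(adapter3)
    if i >= 0 and len(read) - i >= len(adapter3):
        return i
    best, best_off = -1, -1
    la = len(adapter3)
    for off in range(0, len(read) - min_exact + 1):
        m = min(la, len(read) - off)
        mm = 0
        for a, b in zip(read[off:off + m], adapter3[:m]):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        if mm > 1:
            continue
        if (mm == 0 and m >= min_exact) or (mm <= 1 and m >= min_mm):
            score = (m - mm) - mm
            if score > best:
                best, best_off = score, off
    return best_off


def _contains_approx(read: str, pattern: str) -> bool:
    """True if pattern occurs in read with at most one substitution."""
    if pattern in read:
        return True
    # pigeonhole prefilter: one exact half must be present
    h = len(pattern) // 2
    if pattern[:h] not in read and pattern[h:] not in read:
        return False
    lp = len(pattern)
    for off in range(0, len(read) - lp + 1):
        mm = 0
        for a, b in zip(read[off:off + lp], pattern):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        if mm <= 1:
            return True
    return False


def trim_adapters(reads, adapter3: str, adapter5: str = ""):
    """Locate the 3' adapter junction and strip adapter sequence.

    Returns ``(inserts, n_contaminated, n_no_adapter)`` where ``inserts``
    is the list of adapter-free insert sequences.  Reads carrying the 5'
    adapter anywhere (<=1 mismatch) are 5'-ligation contamination and are
    discarded, as are reads in which no 3' junction can be located.
    """
    if len(adapter3) < 6:
        raise ValueError("3' adapter must be at least 6 nt")
    inserts = []
    n_contam = 0
    n_no_adapter = 0
    for read in reads:
        seq = read.sequence if isinstance(read, RawRead) else str(read)
        if adapter5 and _contains_approx(seq, adapter5):
            n_contam += 1
            continue
        off = _best_junction(seq, adapter3)
        if off < 0:
            n_no_adapter += 1
            continue
        inserts.append(seq[:off])
    return inserts, n_contam, n_no_adapter


def _is_polyA(seq: str) -> bool:
    if not seq:
        return False
    if seq.count("A") / len(seq) >= 0.75:
        return True
    run = len(seq) - len(seq.rstrip("A"))
    return run >= 8


def filter_clean(inserts, stats: CleanStats | None = None):
    """Length / N / poly-A filtering of adapter-free inserts.

    Returns ``(clean_inserts, stats)``; counters accumulate into ``stats``
    if given (so the caller can combine with trimming counts).
    """
    stats = stats or CleanStats()
    clean = []
    for seq in inserts:
        if len(seq) < MIN_LEN:
            stats.n_short_removed += 1
        elif len(seq) > MAX_LEN:
            stats.n_long_removed += 1
        elif "N" in seq:
            stats.n_low_quality_removed += 1
        elif _is_polyA(seq):
            stats.n_polyA_removed += 1
        else:
            clean.append(seq)
    stats.n_clean += len(clean)
    return clean, stats


def collapse_tags(clean_inserts) -> list[ReadTag]:
    """Collapse identical inserts into unique tags.

    Output is sorted by descending count, then lexicographic sequence, and
    tags are assigned stable ids t1, t2, ...  The sum of counts equals the
    number of input inserts.
    """
    counts = Counter(clean_inserts)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [ReadTag(seq, n, f"t{i + 1}") for i, (seq, n) in enumerate(ordered)]


def length_distribution(tags: list[ReadTag]) -> pd.DataFrame:
    """Per-length tag/read counts and read percentages (the Fig-2C-style table).

    Returns a DataFrame indexed by length with columns tag_count,
    read_count, percent_of_reads; ``df.attrs["mode"]`` holds the length
    with the most reads (None for empty input).
    """
    if not tags:
        df = pd.DataFrame(columns=["tag_count", "read_count", "percent_of_reads"])
        df.attrs["mode"] = None
        return df
    rows = {}
    for t in tags:
        L = len(t.sequence)
        tc, rc = rows.get(L, (0, 0))
        rows[L] = (tc + 1, rc + t.count)
    df = pd.DataFrame(
        [(L, tc, rc) for L, (tc, rc) in sorted(rows.items())],
        columns=["length", "tag_count", "read_count"],
    ).set_index("length")
    total = df["read_count"].sum()
    df["percent_of_reads"] = 100.0 * df["read_count"] / total
    df.attrs["mode"] = int(df["read_count"].idxmax())
    return df


def clean_reads(reads, adapter3: str, adapter5: str = ""):
    """Full cleaning pipeline: trim, filter, collapse.

    Returns ``(tags, stats, length_table)``.
    """
    reads = list(reads)
    inserts, n_contam, n_no_adapter = trim_adapters(reads, adapter3, adapter5)
    stats = CleanStats(n_raw=len(reads), n_adapter_removed=n_contam + n_no_adapter)
    clean, stats = filter_clean(inserts, stats)
    stats.check()
    tags = collapse_tags(clean)
    return tags, stats, length_distribution(tags)
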