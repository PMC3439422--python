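"""Novel miRNA prediction from unannotated read stacks.

The Mireap-style procedure: same-strand alignments of unannotated tags
within 30 nt of each other are merged into clusters; each cluster's
dominant 5' position (the putative Drosha/Dicer cut site, weighted by
read count) anchors a candidate mature sequence; two precursor windows
(cluster as 5' arm, cluster as 3' arm; 10 nt flanks) are folded under the
reduced energy model; and nine acceptance criteria are evaluated on the
MFE structure:

==================  =========================================  =======
criterion           quantity                                   default
==================  =========================================  =======
mature_length       mature sequence length                     18-26 nt
min_read_depth      summed count at the dominant 5' position   >= 3
max_genome_copies   exact genomic copies of the mature         <= 20
max_free_energy     precursor model MFE                        <= -18
max_loop_space      gap between mature 3' and star 5' end      <= 35
min_duplex_pairs    paired bases in the mature/star duplex     >= 14
max_bulge           largest one-sided unpaired run in duplex   <= 4
max_asymmetry       |unpaired mature - unpaired star| in duplex<= 5
single_hairpin      exactly one terminal loop in the precursor (bool)
==================  =========================================  =======

Rejection is a verdict, never an error; every failed criterion is
recorded.  Candidate ids follow the library-label convention
(``<label>-miR<N>``, e.g. ``293m8-miR1``).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._seq import count_occurrences, revcomp, to_rna
from .energy import EnergyModel, default_model
from .fold import fold_mfe, pair_table

__all__ = [
    "TagCluster", "HairpinCriteria", "HairpinCandidate",
    "cluster_unannotated", "extract_precursor", "evaluate_hairpin",
    "predict_novel_mirnas", "first_base_bias", "genome_copy_number",
]

MAX_MATURE = 26
MAX_LOOP = 35
FLANK = 10
#: longest precursor window: mature + loop + star + two flanks
WINDOW = MAX_MATURE + MAX_LOOP + MAX_MATURE + 2 * FLANK  # = 107


@dataclass(frozen=True)
class HairpinCriteria:
    """The nine acceptance thresholds (defaults as in the Methods)."""
    mature_min: int = 18
    mature_max: int = 26
    min_depth: int = 3
    max_copies: int = 20
    max_mfe: float = -18.0
    max_space: int = 35
    min_pairs: int = 14
    max_bulge: int = 4
    max_asymmetry: int = 5


@dataclass
class TagCluster:
    contig: str
    strand: str
    start: int                      # 0-based genomic span
    end: int
    members: list = field(default_factory=list)  # (tag_id, start, end, count)
    dominant_5p: int = -1           # genomic position of max summed 5' depth
    depth_at_dominant: int = 0
    mature_len: int = 0             # length of the top tag at the dominant 5'


@dataclass
class HairpinCandidate:
    id: str
    contig: str
    start: int                      # precursor window, 0-based half-open
    end: int
    strand: str
    precursor_seq: str              # RNA sense (5'->3')
    structure: str
    mfe: float
    mature_seq: str
    star_seq: str
    duplex_pairs: int
    duplex_bulge_max: int
    duplex_asymmetry: int
    loop_space: int
    genome_copies: int
    depth_at_cut: int
    accepted: bool
    failure_reasons: tuple = ()
    read_count: int = 0
    cut_site: int = -1        # genomic position of the dominant mature 5' end


def cluster_unannotated(alignments, tag_counts: dict[str, int],
                        max_gap: int = 30) -> list[TagCluster]:
    """Merge same-strand alignments whose spans lie within ``max_gap`` nt.

    Merging is transitive (a chain of stacks closer than the gap becomes
    one cluster).  The dominant 5' position is the transcription-sense 5'
    end with the greatest summed read count (leftmost on ties); the
    cluster's mature length is the length of the highest-count member tag
    anchored there (shortest, then lexicographic tag id on ties).
    """
    by_key = defaultdict(list)
    for a in alignments:
        by_key[(a.contig, a.strand)].append(a)
    clusters: list[TagCluster] = []
    for (contig, strand), alns in sorted(by_key.items()):
        alns.sort(key=lambda a: (a.start, a.end))
        current: list = []
        cur_end = None
        for a in alns:
            if current and a.start - cur_end > max_gap:
                clusters.append(_finish_cluster(contig, strand, current, tag_counts))
                current = []
                cur_end = None
            current.append(a)
            cur_end = a.end if cur_end is None else max(cur_end, a.end)
        if current:
            clusters.append(_finish_cluster(contig, strand, current, tag_counts))
    return clusters


def _finish_cluster(contig, strand, alns, tag_counts) -> TagCluster:
    depth = defaultdict(int)
    for a in alns:
        five = a.start if strand == "+" else a.end - 1
        depth[five] += tag_counts.get(a.tag_id, 1)
    dom = min((p for p in depth if depth[p] == max(depth.values())))
    at_dom = [a for a in alns
              if (a.start if strand == "+" else a.end - 1) == dom]
    top = sorted(at_dom, key=lambda a: (-tag_counts.get(a.tag_id, 1),
                                        a.end - a.start, a.tag_id))[0]
    return TagCluster(
        contig=contig, strand=strand,
        start=min(a.start for a in alns), end=max(a.end for a in alns),
        members=[(a.tag_id, a.start, a.end, tag_counts.get(a.tag_id, 1))
                 for a in alns],
        dominant_5p=dom, depth_at_dominant=depth[dom],
        mature_len=top.end - top.start,
    )


@dataclass(frozen=True)
class PrecursorWindow:
    contig: str
    start: int
    end: int
    strand: str
    seq: str        # transcription sense (reverse-complemented for '-')

    def to_local(self, genome_pos: int) -> int:
        if self.strand == "+":
            return genome_pos - self.start
        return self.end - 1 - genome_pos


def extract_precursor(contigs: dict[str, str], cluster: TagCluster,
                      flank: int = FLANK) -> list[PrecursorWindow]:
    """The two candidate precursor windows for a cluster.

    One window treats the cluster as the 5' arm (extends downstream), the
    other as the 3' arm (extends upstream); both are at most 107 nt
    (26 + 35 + 26 + 2 x 10) and are clipped at contig bounds.  Identical
    windows collapse to one.
    """
    seq = contigs[cluster.contig]
    L = len(seq)
    if cluster.strand == "+":
        spans = [(cluster.start - flank, cluster.start - flank + WINDOW),
                 (cluster.end + flank - WINDOW, cluster.end + flank)]
    else:
        spans = [(cluster.end + flank - WINDOW, cluster.end + flank),
                 (cluster.start - flank, cluster.start - flank + WINDOW)]
    out = []
    seen = set()
    for s, e in spans:
        s, e = max(0, s), min(L, e)
        if e - s < 2 * flank or (s, e) in seen:
            continue
        seen.add((s, e))
        sub = seq[s:e]
        if cluster.strand == "-":
            sub = revcomp(sub)
        out.append(PrecursorWindow(cluster.contig, s, e, cluster.strand, sub))
    return out


def _duplex_stats(pairs: dict[int, int], m0: int, m1: int):
    """Duplex statistics for mature span [m0, m1) given the pair table.

    Returns (n_pairs, bulge_max, asymmetry, partners) computed between the
    first and last paired mature base; unpaired mature ends outside the
    duplex do not count.  A one-sided gap is a bulge; a two-sided gap is
    an internal loop contributing to the asymmetry balance only.
    """
    paired = [(i, pairs[i]) for i in range(m0, m1) if i in pairs]
    if not paired:
        return 0, 0, 0, []
    bulge_max = 0
    asym_m = asym_s = 0
    for (i, p), (i2, p2) in zip(paired, paired[1:]):
        gap_m = i2 - i - 1
        gap_s = abs(p - p2) - 1
        if (gap_m > 0) != (gap_s > 0):
            bulge_max = max(bulge_max, gap_m, gap_s)
        asym_m += gap_m
        asym_s += gap_s
    return len(paired), bulge_max, abs(asym_m - asym_s), [p for _, p in paired]


def evaluate_hairpin(window: PrecursorWindow, cluster: TagCluster,
                     genome_copies: int,
                     model: EnergyModel | None = None,
                     criteria: HairpinCriteria = HairpinCriteria()) -> HairpinCandidate:
    """Fold one precursor window and evaluate all nine criteria.

    The mature arm is anchored at the cluster's dominant 5' position; the
    star arm is the pairing partner of the mature, reported with the
    canonical 2 nt 3' overhang.  All failed criteria are recorded;
    acceptance requires every criterion to pass.
    """
    model = model or default_model()
    rna = to_rna(window.seq)
    structure, mfe = fold_mfe(rna, model)
    pairs = pair_table(structure)

    lm = window.to_local(cluster.dominant_5p)
    ml = cluster.mature_len
    lm_end = min(lm + ml, len(rna))
    mature = rna[max(0, lm):lm_end]

    npairs, bulge, asym, partners = _duplex_stats(pairs, max(0, lm), lm_end)
    reasons = []
    if not (criteria.mature_min <= ml <= criteria.mature_max):
        reasons.append("mature_length")
    if cluster.depth_at_dominant < criteria.min_depth:
        reasons.append("min_read_depth")
    if genome_copies > criteria.max_copies:
        reasons.append("max_genome_copies")
    if mfe > criteria.max_mfe:
        reasons.append("max_free_energy")
    if npairs < criteria.min_pairs:
        reasons.append("min_duplex_pairs")

    star = ""
    space = 0
    if partners:
        p_lo, p_hi = min(partners), max(partners)
        star = rna[p_lo:min(len(rna), p_hi + 3)]
        if p_lo > lm_end - 1:            # mature is the 5' arm
            space = max(0, p_lo - lm_end)
        else:                            # mature is the 3' arm
            space = max(0, max(0, lm) - p_hi - 1)
        if space > criteria.max_space:
            reasons.append("max_loop_space")
        if bulge > criteria.max_bulge:
            reasons.append("max_bulge")
        if asym > criteria.max_asymmetry:
            reasons.append("max_asymmetry")
        span_lo = min(max(0, lm), p_lo)
        span_hi = max(lm_end - 1, p_hi)
        terminal = 0
        for i, j in pairs.items():
            if i < j and span_lo <= i and j <= span_hi:
                if not any(i < q < j for q in pairs):
                    terminal += 1
        if terminal != 1:
            reasons.append("single_hairpin")

    return HairpinCandidate(
        id="", contig=window.contig, start=window.start, end=window.end,
        strand=window.strand, precursor_seq=rna, structure=structure,
        mfe=mfe, mature_seq=mature, star_seq=star, duplex_pairs=npairs,
        duplex_bulge_max=bulge, duplex_asymmetry=asym, loop_space=space,
        genome_copies=genome_copies, depth_at_cut=cluster.depth_at_dominant,
        accepted=not reasons, failure_reasons=tuple(reasons),
        read_count=sum(m[3] for m in cluster.members),
        cut_site=cluster.dominant_5p,
    )


def genome_copy_number(contigs: dict[str, str], seq: str) -> int:
    """Exact occurrences of ``seq`` on both strands of the genome."""
    dna = seq.upper().replace("U", "T")
    rc = revcomp(dna)
    return sum(count_occurrences(c, dna) + count_occurrences(c, rc)
               for c in contigs.values())


def predict_novel_mirnas(contigs: dict[str, str], clusters: list[TagCluster],
                         model: EnergyModel | None = None,
                         criteria: HairpinCriteria = HairpinCriteria(),
                         lib_label: str = "synm",
                         flank: int = FLANK):
    """Run the full prediction over clusters.

    Both windows of every cluster are evaluated; when both are accepted the
    lower-MFE one is reported (window start breaks ties).  Returns
    ``(accepted, rejected)`` candidate lists; accepted candidates are named
    ``<lib_label>-miR<N>`` in genomic order.
    """
    model = model or default_model()
    accepted, rejected = [], []
    for cluster in clusters:
        mature_start = (cluster.dominant_5p if cluster.strand == "+"
                        else cluster.dominant_5p - cluster.mature_len + 1)
        mature_dna = contigs[cluster.contig][
            max(0, mature_start):mature_start + cluster.mature_len]
        if cluster.strand == "-":
            mature_dna = revcomp(mature_dna)
        copies = genome_copy_number(contigs, mature_dna)
        cands = [evaluate_hairpin(w, cluster, copies, model, criteria)
                 for w in extract_precursor(contigs, cluster, flank)]
        if not cands:
            continue
        ok = [c for c in cands if c.accepted]
        if ok:
            accepted.append(min(ok, key=lambda c: (c.mfe, c.start)))
            rejected.extend(c for c in cands if not c.accepted)
        else:
            rejected.extend(cands)
    accepted.sort(key=lambda c: (c.contig, c.start, c.strand))
    named = []
    for i, c in enumerate(accepted, start=1):
        c.id = f"{lib_label}-miR{i}"
        named.append(c)
    return named, rejected


def first_base_bias(sequences, counts=None) -> pd.DataFrame:
    """Per-length first-base composition (A/C/G/U fractions).

    ``counts`` weights each sequence (read-weighted bias); rows normalise
    to 1.  Lengths outside 18-30 are still tabulated if present.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    if counts is None:
        counts = [1] * len(seqs)
    acc = defaultdict(lambda: dict.fromkeys("ACGU", 0.0))
    for seq, w in zip(seqs, counts):
        base = to_rna(seq[0])
        if base in "ACGU":
            acc[len(seq)][base] += w
    df = pd.DataFrame.from_dict(acc, orient="index").sort_index()
    df.index.name = "length"
    return df.div(df.sum(axis=1), axis=0)
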