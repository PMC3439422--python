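"""Synthetic reference, planted hairpin loci, and library simulation.

This module builds the ground truth every downstream stage is tested
against: a desk-scale genome (two nuclear-like contigs plus a small
circular mitochondrial contig), non-overlapping annotation tracks
(rRNA/tRNA/sn/sno/srp/scRNA/piRNA/repeat/exon/intron), miRBase-style
known-miRNA reference sets planted into the genome, and — via
:func:`plant_hairpin_loci` — novel-miRNA loci that provably satisfy all
nine hairpin acceptance criteria, together with decoy loci that each
violate exactly one named criterion.  Planting is verified at
construction time by running the real extraction/folding/criteria engine
on the written genome, redrawing until the verdict matches the design,
so TruthSet invariants hold by construction.

:func:`simulate_library` then emulates the sequencing protocol: 18-30 nt
inserts drawn from the tracks according to a category mix dominated by
rRNA, a length distribution with its mode at 25 nt, miRNA read stacks
with homogeneous 5' ends (every planted locus is guaranteed its minimum
cut-site depth) and lower-abundance star reads, poly-A degradation
products, 5'-adapter contamination, uniform substitution errors, and
fixed-length 50 nt reads of the form insert + 3' adapter + padding.
Every read is recorded in a truth table (source category, locus,
coordinates, expected annotation).

All randomness flows through one ``numpy.random.default_rng(seed)`` per
operation; identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp
from .annotate import Feature
from .discovery import (HairpinCriteria, TagCluster, evaluate_hairpin,
                        extract_precursor, genome_copy_number)
from .mito import MtFeature, MtGeneMap
from .preprocess import MIN_LEN, RawRead

__all__ = [
    "ReferenceConfig", "SyntheticReference", "PlantedLocus", "TruthSet",
    "LibraryProfile", "build_reference", "plant_hairpin_loci",
    "simulate_library", "ConfigurationError", "PlacementError", "DECOY_KINDS",
]


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceConfig:
    """Generation parameters for the toy reference (~120 kb total)."""
    contig_lengths: dict = field(default_factory=lambda: {
        "chr1": 50_000, "chr2": 50_000})
    mt_name: str = "chrM"
    mt_length: int = 16_500
    #: category -> (feature count, feature length)
    feature_plan: dict = field(default_factory=lambda: {
        "rRNA": (24, 120), "tRNA": (30, 75), "snRNA": (12, 100),
        "snoRNA": (12, 80), "srpRNA": (6, 90), "scRNA": (6, 110),
        "piRNA": (20, 28), "exon": (15, 150), "intron": (10, 300)})
    #: repeat class -> (count, length)
    repeat_plan: dict = field(default_factory=lambda: {
        "LINE": (8, 200), "SINE/Alu": (8, 150), "LTR/ERVL": (4, 180)})
    n_mirna_loci: int = 20
    mirna_mature_len: int = 22
    mirna_u5_fraction: float = 0.9   # fraction of mature refs starting with U
    feature_pad: int = 20            # minimum spacing between planted items
    locus_pad: int = 40              # exclusion margin around hairpin loci


@dataclass
class PlantedLocus:
    locus_id: str
    contig: str
    start: int                 # planted segment, 0-based half-open
    end: int
    strand: str
    mature_seq: str            # transcription sense, DNA alphabet
    star_seq: str
    precursor_seq: str
    mature_start: int          # genomic 0-based start of the mature
    kind: str                  # "true" or a decoy kind
    expected_reason: str = ""  # decoy: the single criterion it violates
    planned_depth: int = 3     # mature reads guaranteed by the simulator
    planned_star: int = 1


@dataclass
class TruthSet:
    true_hairpins: list = field(default_factory=list)
    decoys: list = field(default_factory=list)

    @property
    def all_loci(self):
        return self.true_hairpins + self.decoys


@dataclass
class SyntheticReference:
    contigs: dict                       # name -> sequence (mt included)
    mt_contig: str
    tracks: dict                        # category -> [Feature]; repeats under "repeat"
    mature_refs: dict
    star_refs: dict
    precursor_refs: dict
    known_loci: list                    # PlantedLocus for the known miRNAs
    mt_gene_map: MtGeneMap
    config: ReferenceConfig
    occupied: dict = field(default_factory=dict)  # contig -> IntervalTree

    @property
    def nuclear_contigs(self):
        return {n: s for n, s in self.contigs.items() if n != self.mt_contig}

    @property
    def pirna_seqs(self) -> set:
        out = set()
        for f in self.tracks.get("piRNA", ()):
            seg = self.contigs[f.contig][f.start:f.end]
            out.add(seg if f.strand == "+" else revcomp(seg))
        return out

    def reserve(self, contig: str, start: int, end: int, pad: int) -> None:
        self.occupied[contig].addi(max(0, start - pad), end + pad)

    def is_free(self, contig: str, start: int, end: int) -> bool:
        return not self.occupied[contig].overlap(start, end)

    def free_intervals(self, min_len: int = 35):
        """Unoccupied nuclear intervals (for unannotated-read sampling)."""
        out = []
        for name, seq in self.nuclear_contigs.items():
            tree = IntervalTree(self.occupied[name])
            tree.merge_overlaps()
            pos = 0
            for iv in sorted(tree):
                if iv.begin - pos >= min_len:
                    out.append((name, pos, iv.begin))
                pos = max(pos, iv.end)
            if len(seq) - pos >= min_len:
                out.append((name, pos, len(seq)))
        return out

    def validate(self) -> None:
        if len(self.contigs[self.mt_contig]) < 1000:
            raise ConfigurationError("mitochondrial contig shorter than 1 kb")
        for cat, feats in self.tracks.items():
            ivs = sorted((f.contig, f.start, f.end) for f in feats)
            for f in feats:
                if not (0 <= f.start < f.end <= len(self.contigs[f.contig])):
                    raise ConfigurationError(
                        f"{cat} feature {f.feature_id} outside {f.contig}")
            for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
                if c1 == c2 and s2 < e1:
                    raise ConfigurationError(f"overlapping features in {cat}")
        for name, seq in self.star_refs.items():
            if not any(seq in p for p in self.precursor_refs.values()):
                raise ConfigurationError(f"star {name} not in any precursor")
        for name, seq in self.mature_refs.items():
            if not any(seq in p for p in self.precursor_refs.values()):
                raise ConfigurationError(f"mature {name} not in any precursor")

    def write(self, outdir) -> None:
        from pathlib import Path
        from .io import write_fasta, write_gff3
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "genome.fa")
        write_gff3(self.tracks, outdir / "tracks.gff3")
        write_fasta(self.mature_refs, outdir / "mature.fa")
        write_fasta(self.star_refs, outdir / "star.fa")
        write_fasta(self.precursor_refs, outdir / "precursor.fa")


def _rand_seq(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _place(ref: SyntheticReference, rng, length: int, pad: int,
           what: str, tries: int = 2000) -> tuple[str, int]:
    names = list(ref.nuclear_contigs)
    lens = np.array([len(ref.contigs[n]) for n in names], dtype=float)
    if length + 2 * pad > lens.max():
        raise ConfigurationError(
            f"cannot place a {length} nt {what} feature on contigs of "
            f"lengths {dict(zip(names, lens.astype(int)))}")
    for _ in range(tries):
        contig = names[rng.choice(len(names), p=lens / lens.sum())]
        start = int(rng.integers(pad, len(ref.contigs[contig]) - length - pad))
        if ref.is_free(contig, start, start + length):
            return contig, start
    raise PlacementError(f"no free space for {what} after {tries} tries")


def _write_segment(ref: SyntheticReference, contig: str, start: int,
                   segment: str) -> None:
    c = ref.contigs[contig]
    ref.contigs[contig] = c[:start] + segment + c[start + len(segment):]


def _mt_gene_map(length: int) -> MtGeneMap:
    """A deterministic gene layout echoing the human mitochondrial map:
    a wrap-around D-loop, two rRNAs, interspersed tRNAs, 13 protein genes."""
    feats = [MtFeature("D-loop", length - max(200, length // 80), 300, "+",
                       "noncoding")]
    cursor = 350
    unit = max(1, (length - 700) // 1200)

    def add(gene, size, cls, strand="+"):
        nonlocal cursor
        end = min(cursor + size, length - 300)
        if end > cursor:
            feats.append(MtFeature(gene, cursor + 1, end, strand, cls))
            cursor = end + 25
    add("12S-rRNA", 70 * unit, "rRNA")
    add("16S-rRNA", 110 * unit, "rRNA")
    for i, (gene, size) in enumerate([
            ("ND1", 70), ("ND2", 75), ("COX1", 110), ("COX2", 50),
            ("ATP8", 15), ("ATP6", 50), ("COX3", 55), ("ND3", 25),
            ("ND4L", 20), ("ND4", 100), ("ND5", 130), ("ND6", 40),
            ("CYTB", 80)]):
        add(f"tRNA-{i + 1}", 5 * unit, "tRNA", "+" if i % 2 else "-")
        add(gene, size * unit, "protein", "-" if gene == "ND6" else "+")
    return MtGeneMap(length, feats)


def build_reference(config: ReferenceConfig | None = None,
                    seed: int = 0) -> SyntheticReference:
    """Generate the synthetic reference: contigs, tracks, miRNA sets.

    Deterministic for fixed (config, seed).  Raises
    :class:`ConfigurationError` when the requested geometry cannot fit
    (e.g. a feature longer than every contig).
    """
    config = config or ReferenceConfig()
    rng = np.random.default_rng(seed)
    contigs = {name: _rand_seq(rng, n)
               for name, n in config.contig_lengths.items()}
    contigs[config.mt_name] = _rand_seq(rng, config.mt_length)
    ref = SyntheticReference(
        contigs=contigs, mt_contig=config.mt_name, tracks={},
        mature_refs={}, star_refs={}, precursor_refs={}, known_loci=[],
        mt_gene_map=_mt_gene_map(config.mt_length), config=config,
        occupied={n: IntervalTree() for n in contigs},
    )
    pad = config.feature_pad
    for cat, (count, length) in config.feature_plan.items():
        feats = []
        for i in range(count):
            contig, start = _place(ref, rng, length, pad, cat)
            strand = "+-"[rng.integers(2)]
            source = ("Genbank" if i % 2 == 0 else "Rfam") if cat == "rRNA" else ""
            feats.append(Feature(contig, start, start + length, strand,
                                 f"{cat}_{i + 1}", source))
            ref.reserve(contig, start, start + length, pad)
        ref.tracks[cat] = feats
    repeats = []
    for cls, (count, length) in config.repeat_plan.items():
        for i in range(count):
            contig, start = _place(ref, rng, length, pad, f"repeat:{cls}")
            strand = "+-"[rng.integers(2)]
            repeats.append(Feature(contig, start, start + length, strand,
                                   f"rep_{cls.replace('/', '_')}_{i + 1}",
                                   "", cls))
            ref.reserve(contig, start, start + length, pad)
    ref.tracks["repeat"] = repeats

    # known miRNA loci: hairpin-shaped, mature length fixed, exact U-start
    # quota so the read-weighted first-base bias matches the configured
    # fraction up to sampling noise
    n = config.n_mirna_loci
    n_u = int(round(config.mirna_u5_fraction * n))
    u_flags = np.array([True] * n_u + [False] * (n - n_u))
    rng.shuffle(u_flags)
    for i in range(n):
        name = f"syn-miR-{i + 1}"
        locus = _plant_verified(ref, rng, _design_true, name,
                                kind="known", verify=False,
                                mature_len=config.mirna_mature_len,
                                u_start=bool(u_flags[i]))
        ref.known_loci.append(locus)
        ref.mature_refs[name] = locus.mature_seq
        ref.star_refs[name + "*"] = locus.star_seq
        ref.precursor_refs[name + "-pre"] = locus.precursor_seq
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# hairpin designers
# ---------------------------------------------------------------------------
# Designs are written in transcription sense over the DNA alphabet; the
# planted genomic segment is spacer5 + precursor + spacer3 (reverse-
# complemented for '-' strand loci).  Designers choose alphabets so the
# intended duplex is the only strong pairing; construction-time
# verification (real fold + criteria) rejects unlucky draws.

@dataclass
class _Design:
    mature: str
    loop: str
    star: str
    spacer: str
    expected_reason: str = ""
    planned_depth: int = 3

    @property
    def precursor(self) -> str:
        return self.mature + self.loop + self.star

    @property
    def segment(self) -> str:
        return self.spacer + self.precursor + self.spacer


def _choice_str(rng, alphabet: str, n: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(len(alphabet), size=n)])


def _design_true(rng, mature_len: int | None = None,
                 u_start: bool | None = None) -> _Design:
    ml = int(mature_len or rng.choice([20, 21, 22, 22, 22, 23, 24]))
    first = "T" if (u_start if u_start is not None
                    else rng.random() < 0.9) else str(rng.choice(list("ACG")))
    mature = first + _rand_seq(rng, ml - 1, gc=0.55)
    loop = _choice_str(rng, "AC", int(rng.integers(8, 16)))
    # G.U-wobble two or three interior pairs (real duplexes are imperfect;
    # a perfectly complementary stem would also fold as a hairpin on the
    # reverse strand and duplicate every locus in strand-aware analyses)
    star = list(revcomp(mature))
    g_positions = [i for i, b in enumerate(star) if b == "C"
                   and 3 <= i < len(star) - 3]
    rng.shuffle(g_positions)
    for i in g_positions[:3]:
        star[i] = "T"     # mature G : star U wobble
    return _Design(mature, loop, "".join(star), "AAAAA")


def _design_mfe(rng, **_) -> _Design:
    # weak all-A/T stem: >=14 pairs but far above -18 kcal/mol; C-only
    # filler is inert (no G anywhere, C pairs nothing present)
    stem = _choice_str(rng, "AT", 15)
    return _Design(stem + "CCC", "C" * 8, revcomp(stem), "CCCCC",
                   expected_reason="max_free_energy")


def _design_duplex13(rng, **_) -> _Design:
    # strong GC stem of exactly 13 pairs; the unpaired mature 5' tail is
    # A-only and pairs nothing (no T/U outside it)
    stem = _choice_str(rng, "GC", 13)
    return _Design("A" * 9 + stem, "A" * 8, revcomp(stem), "AAAAA",
                   expected_reason="min_duplex_pairs")


def _design_depth2(rng, **_) -> _Design:
    d = _design_true(rng)
    return replace(d, expected_reason="min_read_depth", planned_depth=2)


def _design_copies21(rng, **_) -> _Design:
    d = _design_true(rng)
    return replace(d, expected_reason="max_genome_copies")


def _design_mature27(rng, **_) -> _Design:
    d = _design_true(rng, mature_len=27)
    return replace(d, expected_reason="mature_length")


def _design_loop40(rng, **_) -> _Design:
    d = _design_true(rng, mature_len=22)
    return replace(d, loop=_choice_str(rng, "AC", 40),
                   expected_reason="max_loop_space")


def _design_bulge5(rng, **_) -> _Design:
    seg1, seg2 = _choice_str(rng, "GC", 9), _choice_str(rng, "GC", 8)
    mature = seg1 + "A" * 5 + seg2
    return _Design(mature, "A" * 8, revcomp(seg2) + revcomp(seg1), "AAAAA",
                   expected_reason="max_bulge")


def _design_asym6(rng, **_) -> _Design:
    seg1, seg2 = _choice_str(rng, "GC", 9), _choice_str(rng, "GC", 8)
    mature = seg1 + "A" + seg2
    star = revcomp(seg2) + "A" * 7 + revcomp(seg1)
    return _Design(mature, "A" * 8, star, "AAAAA",
                   expected_reason="max_asymmetry")


DECOY_KINDS = {
    "mfe": _design_mfe,
    "duplex_13bp": _design_duplex13,
    "depth_2": _design_depth2,
    "copies_21": _design_copies21,
    "mature_27nt": _design_mature27,
    "loop_40": _design_loop40,
    "bulge_5": _design_bulge5,
    "asymmetry_6": _design_asym6,
}


def _locus_cluster(locus: PlantedLocus) -> TagCluster:
    """The read stack the simulator guarantees for a planted locus."""
    ml = len(locus.mature_seq)
    sl = len(locus.star_seq)
    m0 = locus.mature_start
    # star genomic span from the precursor layout (mature is always the
    # precursor's 5' arm in the planted designs)
    off_star = len(locus.precursor_seq) - sl
    if locus.strand == "+":
        pre0 = m0                      # mature sits at precursor offset 0
        star_span = (pre0 + off_star, pre0 + off_star + sl)
        dom = m0
    else:
        pre_end = m0 + ml              # mature is at the segment's 3' side
        star_span = (pre_end - off_star - sl, pre_end - off_star)
        dom = m0 + ml - 1
    members = [("mat", m0, m0 + ml, locus.planned_depth)]
    # the pipeline merges the star stack into the mature cluster only when
    # their spans are within the 30 nt adjacency gap; mirror that here so
    # verification sees exactly the cluster the pipeline will build
    gap = max(star_span[0] - (m0 + ml), m0 - star_span[1])
    if locus.planned_star and gap <= 30:
        members.append(("star", *star_span, locus.planned_star))
    start = min(m[1] for m in members)
    end = max(m[2] for m in members)
    return TagCluster(locus.contig, locus.strand, start, end, members,
                      dominant_5p=dom, depth_at_dominant=locus.planned_depth,
                      mature_len=ml)


def _verify_locus(ref: SyntheticReference, locus: PlantedLocus,
                  criteria: HairpinCriteria) -> tuple[bool, set]:
    """Run the real extraction + fold + criteria engine on a planted locus.

    Returns (any_window_accepted, reasons of the cleanest window)."""
    cluster = _locus_cluster(locus)
    copies = genome_copy_number(ref.contigs, locus.mature_seq)
    cands = [evaluate_hairpin(w, cluster, copies, criteria=criteria)
             for w in extract_precursor(ref.contigs, cluster)]
    if not cands:
        return False, {"no_window"}
    if any(c.accepted for c in cands):
        return True, set()
    return False, set(min((c.failure_reasons for c in cands), key=len))


def _plant_verified(ref, rng, designer, locus_id, kind, verify=True,
                    criteria=HairpinCriteria(), strand=None, tries=60,
                    **design_kw) -> PlantedLocus:
    pad = ref.config.locus_pad
    for _ in range(tries):
        d = designer(rng, **design_kw)
        seg = d.segment
        strand_i = strand or "+-"[rng.integers(2)]
        contig, start = _place(ref, rng, len(seg), pad, kind)
        genomic = seg if strand_i == "+" else revcomp(seg)
        original = ref.contigs[contig][start:start + len(seg)]
        _write_segment(ref, contig, start, genomic)
        # reserve immediately so further placements (mature copies, later
        # loci) cannot collide; drop the reservation again on retry
        reserved = [(contig, max(0, start - pad), start + len(seg) + pad)]
        ref.occupied[contig].addi(*reserved[0][1:])
        sp = len(d.spacer)
        ml = len(d.mature)
        if strand_i == "+":
            mature_start = start + sp
        else:
            mature_start = start + len(seg) - sp - ml
        locus = PlantedLocus(
            locus_id, contig, start, start + len(seg), strand_i,
            d.mature, d.star, d.precursor, mature_start, kind,
            expected_reason=d.expected_reason, planned_depth=d.planned_depth,
            # a star shorter than the insert minimum would be length-
            # filtered; omit its read so the verified cluster geometry is
            # exactly what the pipeline will see
            planned_star=1 if len(d.star) >= MIN_LEN else 0)
        extra_spans = []
        if d.expected_reason == "max_genome_copies":
            for _c in range(20):
                ccontig, cstart = _place(ref, rng, ml, 25, "mature-copy")
                _write_segment(ref, ccontig, cstart, d.mature)
                extra_spans.append((ccontig, cstart, cstart + ml))
                reserved.append((ccontig, max(0, cstart - 25), cstart + ml + 25))
                ref.occupied[ccontig].addi(*reserved[-1][1:])
        if not verify:
            return locus
        ok, reasons = _verify_locus(ref, locus, criteria)
        good = (ok if not d.expected_reason
                else (not ok and reasons == {d.expected_reason}))
        if good:
            return locus
        # revert and redraw
        _write_segment(ref, contig, start, original)
        for ccontig, cstart, cend in extra_spans:
            _write_segment(ref, ccontig, cstart, _rand_seq(rng, cend - cstart))
        for rcontig, rs, re_ in reserved:
            ref.occupied[rcontig].removei(rs, re_)
    raise PlacementError(f"could not plant a verified {kind} locus "
                         f"({locus_id}) in {tries} attempts")


def plant_hairpin_loci(reference: SyntheticReference, n_true: int,
                       n_decoy: int, seed: int = 0,
                       criteria: HairpinCriteria = HairpinCriteria()) -> TruthSet:
    """Plant ``n_true`` criteria-compliant hairpin loci and ``n_decoy``
    single-violation decoys into unannotated genomic space.

    Every locus is verified in place with the real criteria engine; true
    loci fold to an accepted hairpin, each decoy fails with exactly its
    designed criterion.  Raises :class:`PlacementError` when space or
    retries run out.
    """
    rng = np.random.default_rng(seed)
    truth = TruthSet()
    for i in range(n_true):
        truth.true_hairpins.append(_plant_verified(
            reference, rng, _design_true, f"true-{i + 1}", "true",
            criteria=criteria))
    kinds = list(DECOY_KINDS)
    for i in range(n_decoy):
        kind = kinds[i % len(kinds)]
        truth.decoys.append(_plant_verified(
            reference, rng, DECOY_KINDS[kind], f"decoy-{kind}-{i + 1}", kind,
            criteria=criteria, strand="+"))
    return truth


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

DEFAULT_MIX = {
    "rRNA": 0.65, "tRNA": 0.04, "snRNA": 0.015, "snoRNA": 0.01,
    "srpRNA": 0.005, "piRNA": 0.01, "repeat": 0.03, "exon": 0.02,
    "intron": 0.01, "miRNA": 0.08, "novel": 0.03, "unannotated": 0.07,
    "random": 0.03,
}

DEFAULT_LENGTHS = {
    18: 0.02, 19: 0.03, 20: 0.04, 21: 0.05, 22: 0.07, 23: 0.09, 24: 0.13,
    25: 0.22, 26: 0.13, 27: 0.09, 28: 0.06, 29: 0.04, 30: 0.03,
}


@dataclass(frozen=True)
class LibraryProfile:
    """Study conditions of one simulated library."""
    n_reads: int = 100_000
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    length_distribution: dict = field(default_factory=lambda: dict(DEFAULT_LENGTHS))
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_length: int = 50
    error_rate: float = 0.001
    polyA_fraction: float = 0.002
    adapter5_fraction: float = 0.01
    mature_star_ratio: float = 0.9

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        for name, probs in (("category_mix", self.category_mix),
                            ("length_distribution", self.length_distribution)):
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} sums to {s}, not 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ConfigurationError("error_rate must be in [0, 0.05]")


_EXPECTED = {
    "rRNA": "rRNA", "tRNA": "tRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
    "srpRNA": "srpRNA", "scRNA": "scRNA", "piRNA": "piRNA", "exon": "exon",
    "intron": "intron", "novel": "unannotated", "unannotated": "unannotated",
    "random": "unannotated",
}

_BASES = np.array(list("ACGT"))


def _mutate(rng, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(3)]
    return "".join(chars), int(hits.size)


def simulate_library(reference: SyntheticReference, truth: TruthSet | None,
                     profile: LibraryProfile | None = None, seed: int = 0):
    """Simulate one raw library; returns (reads, truth_table).

    ``reads`` is a list of :class:`RawRead` (length == profile.n_reads,
    order shuffled); ``truth_table`` is a DataFrame with one row per read
    recording its source category, locus, genomic coordinates and the
    annotation the pipeline is expected to assign.  Planted hairpin loci
    are guaranteed their designed mature-read depth with a homogeneous 5'
    end; remaining reads follow the category mix.
    """
    profile = profile or LibraryProfile()
    profile.validate()
    rng = np.random.default_rng(seed)
    truth = truth or TruthSet()

    lengths = np.array(sorted(profile.length_distribution))
    lprobs = np.array([profile.length_distribution[l] for l in lengths])
    lprobs = lprobs / lprobs.sum()

    def draw_len() -> int:
        return int(rng.choice(lengths, p=lprobs))

    rows = []  # (category, expected, insert, contig, start, end, strand, locus)

    def feature_insert(cat: str):
        feats = reference.tracks[cat if cat != "repeat" else "repeat"]
        f = feats[rng.integers(len(feats))]
        if cat == "piRNA":
            s, e = f.start, f.end
        else:
            L = min(draw_len(), f.end - f.start)
            s = int(rng.integers(f.start, f.end - L + 1))
            e = s + L
        seg = reference.contigs[f.contig][s:e]
        insert = seg if f.strand == "+" else revcomp(seg)
        expected = f"repeat:{f.cls}" if cat == "repeat" else _EXPECTED[cat]
        return expected, insert, f.contig, s, e, f.strand, f.feature_id

    def locus_read(locus: PlantedLocus, which: str):
        if which == "mature":
            insert = locus.mature_seq
            s = locus.mature_start
            e = s + len(insert)
        else:
            insert = locus.star_seq
            off = len(locus.precursor_seq) - len(locus.star_seq)
            if locus.strand == "+":
                s = locus.mature_start + off
            else:
                s = locus.mature_start + len(locus.mature_seq) - off - len(insert)
            e = s + len(insert)
        return insert, locus.contig, s, e, locus.strand

    # guaranteed read stacks for planted loci (homogeneous 5' ends)
    for locus in truth.all_loci:
        for _ in range(locus.planned_depth):
            ins, c, s, e, st = locus_read(locus, "mature")
            rows.append(("novel", "unannotated", ins, c, s, e, st,
                         locus.locus_id))
        for _ in range(locus.planned_star):
            ins, c, s, e, st = locus_read(locus, "star")
            rows.append(("novel", "unannotated", ins, c, s, e, st,
                         locus.locus_id))

    n_polyA = int(round(profile.polyA_fraction * profile.n_reads))
    n_contam = int(round(profile.adapter5_fraction * profile.n_reads))
    n_rest = profile.n_reads - n_polyA - n_contam - len(rows)
    if n_rest < 0:
        raise ConfigurationError(
            "n_reads too small for the guaranteed locus read stacks")

    mix = dict(profile.category_mix)
    if not truth.all_loci:
        mix["unannotated"] = mix.get("unannotated", 0) + mix.pop("novel", 0)
    cats = sorted(mix)
    probs = np.array([mix[c] for c in cats])
    counts = rng.multinomial(n_rest, probs / probs.sum())

    free = reference.free_intervals()
    free_w = np.array([e - s for _, s, e in free], dtype=float)
    free_w /= free_w.sum()

    for cat, n in zip(cats, counts):
        for _ in range(n):
            if cat == "miRNA":
                loci = reference.known_loci
                locus = loci[rng.integers(len(loci))]
                which = ("mature" if rng.random() < profile.mature_star_ratio
                         else "star")
                ins, c, s, e, st = locus_read(locus, which)
                rows.append(("miRNA" if which == "mature" else "miRNA_star",
                             "miRNA" if which == "mature" else "miRNA_star",
                             ins, c, s, e, st, locus.locus_id))
            elif cat == "novel":
                loci = truth.true_hairpins or truth.all_loci
                locus = loci[rng.integers(len(loci))]
                which = ("mature" if rng.random() < profile.mature_star_ratio
                         else "star")
                ins, c, s, e, st = locus_read(locus, which)
                rows.append(("novel", "unannotated", ins, c, s, e, st,
                             locus.locus_id))
            elif cat == "unannotated":
                i = int(rng.choice(len(free), p=free_w))
                contig, fs, fe = free[i]
                L = min(draw_len(), fe - fs)
                s = int(rng.integers(fs, fe - L + 1))
                seg = reference.contigs[contig][s:s + L]
                st = "+-"[rng.integers(2)]
                rows.append(("unannotated", "unannotated",
                             seg if st == "+" else revcomp(seg),
                             contig, s, s + L, st, ""))
            elif cat == "random":
                rows.append(("random", "unannotated", _rand_seq(rng, draw_len()),
                             "", -1, -1, ".", ""))
            else:
                exp, ins, c, s, e, st, fid = feature_insert(cat)
                rows.append((cat, exp, ins, c, s, e, st, fid))

    for _ in range(n_polyA):
        rows.append(("polyA", "removed", "A" * draw_len(), "", -1, -1, ".", ""))
    for _ in range(n_contam):
        rows.append(("adapter5", "removed", None, "", -1, -1, ".", ""))

    # assemble fixed-length reads, apply errors, shuffle
    order = rng.permutation(len(rows))
    reads, table = [], []
    for rank, idx in enumerate(order):
        cat, exp, insert, c, s, e, st, locus = rows[idx]
        rid = f"r{rank + 1}"
        if cat == "adapter5":
            seq = (profile.adapter5
                   + _rand_seq(rng, profile.read_length))[:profile.read_length]
            nerr = 0
            ilen = 0
        else:
            ins, nerr = _mutate(rng, insert, profile.error_rate)
            seq = (ins + profile.adapter3
                   + "A" * profile.read_length)[:profile.read_length]
            ilen = len(ins)
        reads.append(RawRead(rid, seq, "I" * len(seq)))
        table.append((rid, cat, exp, c, s, e, st, locus, ilen, nerr))
    truth_table = pd.DataFrame(table, columns=[
        "read_id", "category", "expected", "contig", "start", "end",
        "strand", "locus_id", "insert_len", "n_errors"])
    return reads, truth_table
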