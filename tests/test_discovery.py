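"""Read-stack clustering, precursor extraction, hairpin criteria, base bias."""

import random

import pytest

from mitosrna._seq import revcomp, to_rna
from mitosrna.discovery import (HairpinCriteria, TagCluster,
                                cluster_unannotated, evaluate_hairpin,
                                extract_precursor, first_base_bias)
from mitosrna.mapping import Alignment
from oracles import union_find_clusters


def _aln(tid, start, end, strand="+", contig="c1"):
    return Alignment(tid, contig, start, end, strand, 0, 1)


class TestClustering:
    def test_shared_five_prime_adds_depth(self):
        alns = [_aln("a", 100, 122), _aln("b", 100, 124)]
        cl = cluster_unannotated(alns, {"a": 2, "b": 3})
        assert len(cl) == 1
        assert cl[0].dominant_5p == 100 and cl[0].depth_at_dominant == 5

    def test_distant_stacks_stay_separate(self):
        alns = [_aln("a", 100, 122), _aln("b", 1100, 1124)]
        assert len(cluster_unannotated(alns, {"a": 1, "b": 1})) == 2

    def test_strands_never_merge(self):
        alns = [_aln("a", 100, 122, "+"), _aln("b", 105, 127, "-")]
        assert len(cluster_unannotated(alns, {"a": 1, "b": 1})) == 2

    def test_minus_strand_dominant_is_right_end(self):
        alns = [_aln("a", 100, 122, "-"), _aln("b", 95, 122, "-")]
        cl = cluster_unannotated(alns, {"a": 3, "b": 1})
        assert cl[0].dominant_5p == 121
        assert cl[0].mature_len == 22

    def test_planted_stacks_match_union_find_oracle(self):
        """200 random stacks cluster exactly as the transitive union-find
        closure of the 30 nt adjacency relation."""
        rng = random.Random(55)
        spans = []
        alns = []
        for i in range(200):
            start = rng.randrange(0, 30_000)
            end = start + rng.randint(18, 30)
            spans.append((start, end))
            alns.append(_aln(f"t{i}", start, end))
        clusters = cluster_unannotated(alns, {f"t{i}": 1 for i in range(200)})
        got = sorted(sorted(int(m[0][1:]) for m in c.members) for c in clusters)
        assert got == union_find_clusters(spans, 30)


class TestExtraction:
    def test_windows_bounded_and_in_range(self):
        rng = random.Random(5)
        genome = {"c1": "".join(rng.choice("ACGT") for _ in range(5000))}
        cl = TagCluster("c1", "+", 2000, 2080, [("t", 2000, 2022, 3)],
                        dominant_5p=2000, depth_at_dominant=3, mature_len=22)
        wins = extract_precursor(genome, cl)
        assert 1 <= len(wins) <= 2
        for w in wins:
            assert 0 <= w.start < w.end <= 5000
            assert w.end - w.start <= 107
            assert w.seq == genome["c1"][w.start:w.end]

    def test_minus_strand_window_is_reverse_complement(self):
        rng = random.Random(6)
        genome = {"c1": "".join(rng.choice("ACGT") for _ in range(1000))}
        cl = TagCluster("c1", "-", 400, 480, [("t", 400, 422, 3)],
                        dominant_5p=479, depth_at_dominant=3, mature_len=22)
        for w in extract_precursor(genome, cl):
            assert w.seq == revcomp(genome["c1"][w.start:w.end])
            # local coordinates run 5'->3' along the transcript
            assert w.to_local(w.end - 1) == 0
            assert w.to_local(w.start) == w.end - w.start - 1

    def test_window_clipped_at_contig_start(self):
        rng = random.Random(7)
        genome = {"c1": "".join(rng.choice("ACGT") for _ in range(400))}
        cl = TagCluster("c1", "+", 5, 60, [("t", 5, 27, 3)],
                        dominant_5p=5, depth_at_dominant=3, mature_len=22)
        for w in extract_precursor(genome, cl):
            assert w.start >= 0

    def test_window_arithmetic_fixtures(self):
        """Hand-computed window bounds: cluster at 1000-1080 on a long
        contig gives [990, 1097) and [983, 1090)."""
        genome = {"c1": "A" * 3000}
        cl = TagCluster("c1", "+", 1000, 1080, [("t", 1000, 1022, 3)],
                        dominant_5p=1000, depth_at_dominant=3, mature_len=22)
        spans = {(w.start, w.end) for w in extract_precursor(genome, cl)}
        assert spans == {(990, 1097), (983, 1090)}


def _hairpin_cluster(mature, loop, star, depth=3, spacer="AAAAA"):
    """Build a window + cluster directly from a designed precursor."""
    seq = spacer + mature + loop + star + spacer
    genome = {"c1": seq}
    m0 = len(spacer)
    cl = TagCluster("c1", "+", m0, len(spacer) + len(mature) + len(loop) + len(star),
                    [("t", m0, m0 + len(mature), depth)],
                    dominant_5p=m0, depth_at_dominant=depth,
                    mature_len=len(mature))
    wins = extract_precursor(genome, cl)
    return wins[0], cl


class TestCriteria:
    def test_compliant_hairpin_accepted(self):
        rng = random.Random(8)
        mature = "T" + "".join(rng.choice("ACGT") for _ in range(21))
        win, cl = _hairpin_cluster(mature, "ACACACACAC", revcomp(mature))
        cand = evaluate_hairpin(win, cl, genome_copies=1)
        assert cand.accepted, cand.failure_reasons
        assert cand.mfe <= -18
        assert cand.duplex_pairs >= 14
        assert to_rna(mature) == cand.mature_seq

    def test_weak_stem_fails_energy_only(self):
        """An A/T stem keeps >= 14 duplex pairs but folds far above
        -18 kcal/mol: the only recorded reason is the energy cutoff."""
        stem = "ATTAATAATTATAAT"
        win, cl = _hairpin_cluster(stem + "CCC", "C" * 8, revcomp(stem),
                                   spacer="CCCCC")
        cand = evaluate_hairpin(win, cl, genome_copies=1)
        assert not cand.accepted
        assert cand.failure_reasons == ("max_free_energy",)

    def test_thirteen_pair_duplex_rejected(self):
        stem = "GCCGGCGCGGCCG"
        win, cl = _hairpin_cluster("A" * 9 + stem, "A" * 8, revcomp(stem))
        cand = evaluate_hairpin(win, cl, genome_copies=1)
        assert "min_duplex_pairs" in cand.failure_reasons
        assert cand.duplex_pairs == 13

    def test_depth_below_three_rejected(self):
        rng = random.Random(9)
        mature = "".join(rng.choice("ACGT") for _ in range(22))
        win, cl = _hairpin_cluster(mature, "ACACACAC", revcomp(mature), depth=2)
        cand = evaluate_hairpin(win, cl, genome_copies=1)
        assert "min_read_depth" in cand.failure_reasons

    def test_copy_number_above_twenty_rejected(self):
        rng = random.Random(10)
        mature = "".join(rng.choice("ACGT") for _ in range(22))
        win, cl = _hairpin_cluster(mature, "ACACACAC", revcomp(mature))
        cand = evaluate_hairpin(win, cl, genome_copies=21)
        assert "max_genome_copies" in cand.failure_reasons

    def test_acceptance_monotone_in_each_threshold(self):
        """Tightening any single criterion never accepts a previously
        rejected candidate."""
        rng = random.Random(11)
        cands = []
        for _ in range(30):
            mature = "".join(rng.choice("ACGT") for _ in range(22))
            win, cl = _hairpin_cluster(mature, "ACACACACAC", revcomp(mature))
            cands.append((win, cl))
        base = HairpinCriteria()
        tighter = [
            HairpinCriteria(min_pairs=base.min_pairs + 2),
            HairpinCriteria(max_mfe=base.max_mfe - 5),
            HairpinCriteria(max_bulge=base.max_bulge - 1),
            HairpinCriteria(max_asymmetry=base.max_asymmetry - 1),
            HairpinCriteria(max_space=base.max_space - 10),
            HairpinCriteria(min_depth=base.min_depth + 1),
            HairpinCriteria(max_copies=base.max_copies - 10),
            HairpinCriteria(mature_min=base.mature_min + 1,
                            mature_max=base.mature_max - 1),
        ]
        for win, cl in cands:
            before = evaluate_hairpin(win, cl, 1, criteria=base).accepted
            for crit in tighter:
                after = evaluate_hairpin(win, cl, 1, criteria=crit).accepted
                assert not (after and not before)


class TestBaseBias:
    def test_uniform_u_start(self):
        df = first_base_bias(["U" + "ACG" * 7] * 10)
        assert df.loc[22, "U"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        rng = random.Random(12)
        seqs = ["".join(rng.choice("ACGU") for _ in range(rng.randint(18, 30)))
                for _ in range(400)]
        df = first_base_bias(seqs)
        assert df.sum(axis=1).tolist() == pytest.approx([1.0] * len(df), abs=1e-9)

    def test_read_weighting(self):
        df = first_base_bias(["UAAAAAAAAAAAAAAAAAAAAA", "GAAAAAAAAAAAAAAAAAAAAA"],
                             counts=[9, 1])
        assert df.loc[22, "U"] == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            first_base_bias([])
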