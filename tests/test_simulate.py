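"""Synthetic reference, planted hairpin truth, and library simulation."""

import io

import pytest

from conftest import SMALL_CONFIG
from mitosrna import (LibraryProfile, ReferenceConfig, build_reference,
                      plant_hairpin_loci, simulate_library)
from mitosrna._seq import revcomp
from mitosrna.fold import fold_mfe
from mitosrna.simulate import ConfigurationError, _verify_locus
from mitosrna.discovery import HairpinCriteria


def _fasta_bytes(ref):
    buf = io.StringIO()
    for name in sorted(ref.contigs):
        buf.write(f">{name}\n{ref.contigs[name]}\n")
    return buf.getvalue()


class TestBuildReference:
    def test_deterministic_for_fixed_seed(self):
        a = build_reference(SMALL_CONFIG, seed=1)
        b = build_reference(SMALL_CONFIG, seed=1)
        assert _fasta_bytes(a) == _fasta_bytes(b)
        assert a.mature_refs == b.mature_refs
        for cat in a.tracks:
            assert a.tracks[cat] == b.tracks[cat]

    def test_seed_changes_sequence_not_schema(self):
        a = build_reference(SMALL_CONFIG, seed=1)
        b = build_reference(SMALL_CONFIG, seed=2)
        assert _fasta_bytes(a) != _fasta_bytes(b)
        assert {k: len(v) for k, v in a.tracks.items()} == \
               {k: len(v) for k, v in b.tracks.items()}
        assert set(a.contigs) == set(b.contigs)

    def test_infeasible_geometry_raises_naming_track(self):
        cfg = ReferenceConfig(
            contig_lengths={"c": 100}, mt_length=1000,
            feature_plan={"rRNA": (1, 500)}, repeat_plan={}, n_mirna_loci=0)
        with pytest.raises(ConfigurationError, match="rRNA"):
            build_reference(cfg, seed=0)

    def test_reference_invariants(self, ref_small):
        ref_small.validate()
        assert len(ref_small.contigs[ref_small.mt_contig]) >= 1000
        for mature in ref_small.mature_refs.values():
            assert any(mature in p for p in ref_small.precursor_refs.values())
        for star in ref_small.star_refs.values():
            assert any(star in p for p in ref_small.precursor_refs.values())

    def test_mature_u_start_quota(self, ref_small):
        u = sum(s.startswith("T") for s in ref_small.mature_refs.values())
        assert u == round(0.9 * len(ref_small.mature_refs))


class TestPlanting:
    def test_true_hairpins_fold_below_cutoff(self, planted_small):
        """Re-folding every planted true precursor yields MFE <= -18."""
        _, truth = planted_small
        for locus in truth.true_hairpins:
            _, mfe = fold_mfe(locus.precursor_seq)
            assert mfe <= -18.0

    def test_true_loci_verify_as_accepted(self, planted_small):
        ref, truth = planted_small
        for locus in truth.true_hairpins:
            ok, reasons = _verify_locus(ref, locus, HairpinCriteria())
            assert ok, (locus.locus_id, reasons)

    def test_each_decoy_fails_exactly_its_planted_criterion(self, planted_small):
        ref, truth = planted_small
        assert len({d.kind for d in truth.decoys}) == 8
        for d in truth.decoys:
            ok, reasons = _verify_locus(ref, d, HairpinCriteria())
            assert not ok
            assert reasons == {d.expected_reason}, (d.kind, reasons)

    def test_empty_truth_is_valid(self):
        ref = build_reference(SMALL_CONFIG, seed=3)
        truth = plant_hairpin_loci(ref, n_true=0, n_decoy=0, seed=1)
        assert truth.true_hairpins == [] and truth.decoys == []

    def test_loci_lie_in_unannotated_space(self, planted_small):
        ref, truth = planted_small
        for locus in truth.all_loci:
            for cat, feats in ref.tracks.items():
                for f in feats:
                    if f.contig == locus.contig:
                        assert locus.end <= f.start or locus.start >= f.end


@pytest.fixture(scope="module")
def sim(planted_small):
    ref, truth = planted_small
    profile = LibraryProfile(n_reads=25_000, error_rate=0.0)
    reads, table = simulate_library(ref, truth, profile, seed=42)
    return ref, truth, profile, reads, table


class TestSimulateLibrary:
    def test_read_count_conservation(self, sim):
        _, _, profile, reads, table = sim
        assert len(reads) == profile.n_reads
        assert len(table) == profile.n_reads
        assert set(table["read_id"]) == {r.id for r in reads}

    def test_deterministic_for_fixed_seed(self, planted_small):
        ref, truth = planted_small
        profile = LibraryProfile(n_reads=2000)
        r1, t1 = simulate_library(ref, truth, profile, seed=5)
        r2, t2 = simulate_library(ref, truth, profile, seed=5)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)
        r3, _ = simulate_library(ref, truth, profile, seed=6)
        assert [x.sequence for x in r1] != [x.sequence for x in r3]

    def test_noiseless_inserts_are_exact_genome_substrings(self, sim):
        ref, _, _, reads, table = sim
        genomic = table[table["contig"] != ""].sample(300, random_state=0)
        for row in genomic.itertuples():
            seg = ref.contigs[row.contig][row.start:row.end]
            ins = seg if row.strand == "+" else revcomp(seg)
            read = next(r for r in reads if r.id == row.read_id)
            assert read.sequence.startswith(ins)

    def test_length_mode_is_25(self, sim):
        _, _, _, _, table = sim
        counted = table[~table["expected"].eq("removed")]
        assert counted["insert_len"].value_counts().idxmax() == 25

    def test_planted_loci_get_guaranteed_depth(self, sim):
        _, truth, _, _, table = sim
        per_locus = table[table["category"] == "novel"].groupby("locus_id")
        for locus in truth.all_loci:
            n = len(per_locus.get_group(locus.locus_id))
            assert n >= locus.planned_depth

    def test_zero_reads_rejected(self, planted_small):
        ref, truth = planted_small
        with pytest.raises(ConfigurationError):
            simulate_library(ref, truth, LibraryProfile(n_reads=0), seed=1)

    def test_bad_mix_rejected(self, planted_small):
        ref, truth = planted_small
        profile = LibraryProfile(category_mix={"rRNA": 0.5, "tRNA": 0.4})
        with pytest.raises(ConfigurationError):
            simulate_library(ref, truth, profile, seed=1)

    def test_bad_error_rate_rejected(self, planted_small):
        ref, truth = planted_small
        with pytest.raises(ConfigurationError):
            simulate_library(ref, truth, LibraryProfile(error_rate=0.5), seed=1)


class TestWriters:
    def test_reference_roundtrip_through_files(self, tmp_path, ref_small):
        from mitosrna.io import read_fasta, read_gff3
        ref_small.write(tmp_path)
        contigs = read_fasta(tmp_path / "genome.fa")
        assert contigs == ref_small.contigs
        tracks = read_gff3(tmp_path / "tracks.gff3")
        assert {k: len(v) for k, v in tracks.items()} == \
               {k: len(v) for k, v in ref_small.tracks.items()}
        for cat in tracks:
            got = sorted((f.contig, f.start, f.end, f.strand) for f in tracks[cat])
            want = sorted((f.contig, f.start, f.end, f.strand)
                          for f in ref_small.tracks[cat])
            assert got == want

    def test_fastq_tags_roundtrip(self, tmp_path, planted_small):
        from mitosrna.io import (read_fastq, read_tags_fasta, write_fastq,
                                 write_tags_fasta)
        from mitosrna.preprocess import ReadTag
        ref, truth = planted_small
        reads, _ = simulate_library(ref, truth,
                                    LibraryProfile(n_reads=500), seed=9)
        write_fastq(reads, tmp_path / "lib.fastq")
        back = read_fastq(tmp_path / "lib.fastq")
        assert [(r.id, r.sequence) for r in back] == \
               [(r.id, r.sequence) for r in reads]
        tags = [ReadTag("ACGT" * 6, 7, "t1"), ReadTag("GGCC" * 5, 1, "t2")]
        write_tags_fasta(tags, tmp_path / "tags.fa")
        assert read_tags_fasta(tmp_path / "tags.fa") == tags
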