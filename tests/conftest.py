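import pytest

from mitosrna import ReferenceConfig, build_reference, plant_hairpin_loci

SMALL_CONFIG = ReferenceConfig(
    contig_lengths={"chr1": 12_000, "chr2": 12_000},
    mt_length=4_000,
    feature_plan={
        "rRNA": (10, 120), "tRNA": (10, 75), "snRNA": (4, 100),
        "snoRNA": (4, 80), "srpRNA": (2, 90), "scRNA": (2, 110),
        "piRNA": (8, 28), "exon": (6, 150), "intron": (4, 300)},
    repeat_plan={"LINE": (4, 200), "SINE/Alu": (4, 150), "LTR/ERVL": (2, 180)},
    n_mirna_loci=10,
)


@pytest.fixture(scope="session")
def ref_small():
    """Desk-scale reference shared by read-only tests (never planted into)."""
    return build_reference(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def planted_small():
    """A separate reference instance with hairpin loci planted into it.

    Kept apart from ``ref_small`` because planting mutates the genome.
    """
    ref = build_reference(SMALL_CONFIG, seed=11)
    truth = plant_hairpin_loci(ref, n_true=6, n_decoy=8, seed=5)
    return ref, truth
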