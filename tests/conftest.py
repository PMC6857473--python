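import pytest

from fracseq.catalog import TranscriptCatalog, TranscriptModel
from fracseq.simulate import GeneratorConfig, generate_study


def make_tx(tid, exons, strand="+", chrom="chr1", gene=None):
    return TranscriptModel(tid, gene or f"g_{tid}", chrom, strand, tuple(exons))


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down synthetic study used by most integration-level tests."""
    return GeneratorConfig(
        seed=1,
        n_genes=400,
        n_lncrna=80,
        n_housekeeping=60,
        n_tumor_pairs=10,
        planted_nuclear=30,
        planted_cytoplasmic=30,
        planted_de=20,
        n_candidates=5,
        n_patients=120,
        n_null_survival_genes=10,
        n_coexpr_samples=40,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture
def simple_reference():
    """Five reference transcripts spanning the geometries the class codes need."""
    return TranscriptCatalog(
        [
            # multi-exonic plus-strand gene: introns (200,300) and (400,500)
            make_tx("R1", [(100, 200), (300, 400), (500, 600)], "+"),
            # multi-exonic with a big intron (1200, 2200)
            make_tx("R2", [(1000, 1200), (2200, 2400)], "+"),
            # minus-strand gene
            make_tx("R3", [(3000, 3100), (3200, 3300)], "-"),
            # mono-exonic plus-strand gene
            make_tx("R4", [(4000, 4500)], "+"),
            # extended chain containing R1-like introns plus one more
            make_tx("R5", [(5000, 5100), (5200, 5300), (5400, 5500), (5600, 5700)], "+"),
        ]
    )
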