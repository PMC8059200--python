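import numpy as np
import pytest

from trgscout.genome_io import AnnotatedGenome, GeneModel, Interval
from trgscout.pipeline import PipelineConfig, run_pipeline
from trgscout.similarity_search import (
    default_nucleotide_scheme,
    default_protein_scheme,
)
from trgscout.synthetic_clade import default_study_events, simulate_clade


@pytest.fixture(scope="session")
def nt_scheme():
    return default_nucleotide_scheme()


@pytest.fixture(scope="session")
def prot_scheme():
    return default_protein_scheme()


@pytest.fixture
def tiny_genome():
    """One contig with a plus-strand two-exon gene and a minus-strand
    single-exon gene; CDS chosen so translations are stop-free."""
    # plus gene: exon1 = ATGAAA, intron = GTACAG (6nt), exon2 = TGCTAA
    plus_gene_seq = "ATGAAA" + "GTACAG" + "TGCTAA"
    # minus gene: protein on minus strand = ATG GAA TAA -> genomic plus = TTATTCCAT
    minus_gene_seq = "TTATTCCAT"
    seq = "ACGTACGTAC" + plus_gene_seq + "TTTTTTTTTT" + minus_gene_seq + "GGGGGGGGGG"
    g1_off = 10
    g2_off = 10 + len(plus_gene_seq) + 10
    genes = [
        GeneModel(
            gene_id="plus1",
            seq_region="chr1",
            strand="+",
            exons=[
                Interval(g1_off, g1_off + 6),
                Interval(g1_off + 12, g1_off + 18),
            ],
            cds_segments=[
                Interval(g1_off, g1_off + 6),
                Interval(g1_off + 12, g1_off + 18),
            ],
        ),
        GeneModel(
            gene_id="minus1",
            seq_region="chr1",
            strand="-",
            exons=[Interval(g2_off, g2_off + 9)],
            cds_segments=[Interval(g2_off, g2_off + 9)],
        ),
    ]
    return AnnotatedGenome(species_id="toy", sequences={"chr1": seq}, genes=genes)


@pytest.fixture(scope="session")
def sim_clade():
    """A simulated five-species clade with the default planted-event panel."""
    return simulate_clade(events=default_study_events(), seed=7)


@pytest.fixture(scope="session")
def funnel_report(sim_clade):
    genomes, _ = sim_clade
    return run_pipeline(genomes, PipelineConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
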