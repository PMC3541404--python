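import numpy as np
import pytest

from asmpath.io_formats import AsmPair, GeneRecord, Pathway, SnpRecord
from asmpath.synthetic_data import (
    EnrichedPathwaySpec,
    IntRangeDistribution,
    SyntheticStudyConfig,
    generate_study,
)


@pytest.fixture
def toy_snps():
    return [
        SnpRecord("rs1", 1, 1_000, 0.02),
        SnpRecord("rs2", 1, 12_000, 0.30),
        SnpRecord("rs3", 1, 15_000, 0.001),
        SnpRecord("rs4", 2, 5_000, 0.60),
        SnpRecord("rs5", 2, 6_000, 0.04),
    ]


@pytest.fixture
def toy_genes():
    return [
        GeneRecord("GENE1", 1, 10_000, 20_000),
        GeneRecord("GENE2", 2, 4_000, 8_000),
    ]


@pytest.fixture
def toy_asm_pairs():
    return [
        AsmPair("rs2", 1, 12_000, 1, 13_000, "GENE1", "cis", 0.01),
        AsmPair("rs5", 2, 6_000, 1, 500, "GENE1", "trans", 0.02),
    ]


@pytest.fixture(scope="session")
def small_null_bundle():
    """Null study reused across read-only tests (session scope for speed)."""
    config = SyntheticStudyConfig(
        n_genes=400,
        snps_per_gene=IntRangeDistribution(2, 15, 6.0),
        n_pathways=15,
        pathway_size=(10, 25),
        seed=42,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def small_signal_bundle():
    config = SyntheticStudyConfig(
        n_genes=400,
        snps_per_gene=IntRangeDistribution(2, 15, 6.0),
        n_pathways=15,
        pathway_size=(10, 25),
        asm_gene_fraction=0.25,
        enriched_pathways=[EnrichedPathwaySpec(0, 8.0, 0.7)],
        seed=11,
    )
    return generate_study(config)


def make_pathway(name, genes, source="GO"):
    return Pathway(name=name, source=source, gene_ids=frozenset(genes))
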