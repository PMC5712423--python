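import pytest

from sagqc.markers import MarkerSet
from sagqc.synthetic import (
    LineageModel,
    generate_lineage_pair,
    marker_family_ids,
)

SEED = 42


@pytest.fixture(scope="session")
def lineage_models():
    """Two class-level lineages: A matches the marker database, B is
    diverged 0.35 from it (below a 0.70 detection threshold)."""
    a = LineageModel("linA", genome_size_bp=300_000, gc_target=0.66,
                     n_markers=50, n_accessory_genes=150,
                     divergence_from_reference=0.0)
    b = LineageModel("linB", genome_size_bp=300_000, gc_target=0.70,
                     n_markers=50, n_accessory_genes=150,
                     divergence_from_reference=0.35)
    return a, b


@pytest.fixture(scope="session")
def small_pair(lineage_models):
    a, b = lineage_models
    genomes = generate_lineage_pair(a, b, between_lineage_divergence=0.35,
                                    n_genomes_per_lineage=2, seed=SEED)
    return genomes[:2], genomes[2:]


@pytest.fixture(scope="session")
def marker_db():
    return MarkerSet("universal-50", tuple(marker_family_ids(50)),
                     detection_identity_threshold=0.70)


@pytest.fixture(scope="session")
def calibration_genome():
    """One 100-marker, 1 Mbp genome for Monte-Carlo calibration checks."""
    a = LineageModel("calA", genome_size_bp=1_000_000, gc_target=0.66,
                     n_markers=100, n_accessory_genes=400)
    b = LineageModel("calB", genome_size_bp=1_000_000, gc_target=0.70,
                     n_markers=100, n_accessory_genes=400,
                     divergence_from_reference=0.35)
    return generate_lineage_pair(a, b, 0.35, 1, seed=SEED)[0]


@pytest.fixture(scope="session")
def marker_db_100():
    return MarkerSet("universal-100", tuple(marker_family_ids(100)),
                     detection_identity_threshold=0.70)
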